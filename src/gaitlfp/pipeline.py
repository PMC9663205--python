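"""End-to-end orchestration: simulate -> sync -> events -> spectra -> scan -> decode.

A single declarative config (YAML/dict) drives every stage; each stage
consumes only serialized outputs of earlier stages, so any stage can be
re-run individually.  All outputs carry provenance (config hash, seeds,
package version) and a fixed config reproduces bit-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .band_stats import (decoder_grid_edges, event_bin_powers, scan_bands,
                         scan_grid_edges)
from .decoder import DecoderReport, decode_toe_offs
from .gait_events import (build_cycles, detect_heel_strikes, detect_toe_offs,
                          events_from_table, events_to_table, included,
                          normalize_fsr)
from .io_sync import align_streams, apply_offset, crop_to_overlap, read_bundle, write_bundle
from .spectral import cwt_power, epoch_and_normalize, stft_spectrogram, wavelet_coherence
from .synth import (GaitTimelineSpec, ModulationSpec, SyncSpec, mirror_modulation,
                    plant_offset, simulate_fsr, simulate_lfp, simulate_timeline)

log = logging.getLogger("gaitlfp")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "scenario": {
        "n_cycles": 100,
        "mean_cycle_s": 1.1,
        "cycle_jitter_sd": 0.05,
        "turn_intervals": [],
        "noise_sd": 0.01,
        "offset_s": 1.25,
        "n_taps": 3,
        "modulations": [],  # list of ModulationSpec kwargs
        "mirror_right": [],  # labels whose modulations to mirror by +50%
    },
    "analysis": {
        "method": "stft",  # stft | cwt
        "fmin": 1.0,
        "fmax": 50.0,
        "n_freqs": 50,
        "scan_step_hz": 1.0,
        "alpha": 0.05,
        "decoder_channel": None,
        "n_perms": 200,
        "tuning_grid": {"n_trees": [100, 300], "features_per_split": ["sqrt"]},
    },
}


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Layered config: defaults <- file <- overrides."""
    def _merge(base, extra):
        out = dict(base)
        for k, v in (extra or {}).items():
            out[k] = _merge(base.get(k, {}), v) if isinstance(v, dict) else v
        return out

    cfg = DEFAULT_CONFIG
    if path is not None:
        cfg = _merge(cfg, yaml.safe_load(Path(path).read_text()) or {})
    return _merge(cfg, overrides or {})


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _provenance(config: dict) -> dict:
    return {"config_hash": config_hash(config), "seed": config["seed"],
            "version": __version__}


# -- stages -----------------------------------------------------------------

def stage_simulate(config: dict, outdir: Path) -> None:
    sc = config["scenario"]
    spec = GaitTimelineSpec(
        n_cycles=sc["n_cycles"], mean_cycle_s=sc["mean_cycle_s"],
        cycle_jitter_sd=sc["cycle_jitter_sd"],
        turn_intervals=tuple(tuple(t) for t in sc["turn_intervals"]),
        seed=config["seed"],
    )
    timeline = simulate_timeline(spec)
    kin = simulate_fsr(timeline, noise_sd=sc["noise_sd"], seed=config["seed"] + 1)
    mods = []
    for kw in sc["modulations"]:
        mods.append(ModulationSpec(**kw))
    for label in sc["mirror_right"]:
        for m in [m for m in list(mods) if m.channel == label]:
            mods.extend(mirror_modulation(m, channel=f"{label}_r"))
    neural = simulate_lfp(timeline, mods, seed=config["seed"] + 2,
                          extra_channels=("stn",) if not mods else ())
    neural, kin = plant_offset(neural, kin,
                               SyncSpec(offset_s=sc["offset_s"], n_taps=sc["n_taps"]),
                               seed=config["seed"] + 3)
    write_bundle(neural, outdir / "neural")
    write_bundle(kin, outdir / "kinematic")
    truth = events_to_table(timeline.events)
    truth.to_csv(outdir / "true_events.csv", index=False)
    log.info("simulate: %d cycles, %d neural channels", sc["n_cycles"],
             len(neural.traces) - 1)


def stage_sync(config: dict, outdir: Path) -> None:
    neural = read_bundle(outdir / "neural")
    kin = read_bundle(outdir / "kinematic")
    offset = align_streams(neural["accel"], kin["accel"])
    neural = apply_offset(neural, -offset)  # move neural onto the kinematic clock
    neural, kin = crop_to_overlap(neural, kin)
    write_bundle(neural, outdir / "neural_synced")
    write_bundle(kin, outdir / "kinematic_synced")
    (outdir / "sync.json").write_text(json.dumps(
        {"offset_s": offset, **_provenance(config)}, indent=1))
    log.info("sync: offset %.4f s", offset)


def stage_detect_events(config: dict, outdir: Path) -> None:
    kin = read_bundle(outdir / "kinematic_synced")
    det = config.get("detect", {})
    kw = {"threshold": det.get("threshold", 0.05),
          "refractory_s": det.get("refractory_s", 0.2)}
    events = []
    for side, prefix in (("left", "L"), ("right", "R")):
        events += detect_heel_strikes(normalize_fsr(kin[f"{prefix}_calcaneus"]),
                                      normalize_fsr(kin[f"{prefix}_5MT"]), side, **kw)
        events += detect_toe_offs(normalize_fsr(kin[f"{prefix}_hallux"]),
                                  normalize_fsr(kin[f"{prefix}_1MT"]), side, **kw)
    events = sorted(events)
    turns = [tuple(t) for t in config["scenario"]["turn_intervals"]]
    cycles = build_cycles(events, turns)
    events_to_table(events).to_csv(outdir / "events.csv", index=False)
    pd.DataFrame([dataclasses.asdict(c) for c in cycles]).to_csv(
        outdir / "cycles.csv", index=False)
    n_inc = len(included(cycles))
    log.info("detect-events: %d events, %d/%d cycles included (excl: %s)",
             len(events), n_inc, len(cycles),
             {r: sum(c.reason == r for c in cycles) for r in ("turn", "duration", "sequence")})


def _spectral_map(config: dict, trace):
    an = config["analysis"]
    if an["method"] == "cwt":
        freqs = np.linspace(an["fmin"], an["fmax"], an["n_freqs"])
        return cwt_power(trace, freqs)
    return stft_spectrogram(trace)


def _load_events_cycles(config: dict, outdir: Path):
    events = events_from_table(pd.read_csv(outdir / "events.csv"))
    turns = [tuple(t) for t in config["scenario"]["turn_intervals"]]
    return events, build_cycles(events, turns)


def stage_spectra(config: dict, outdir: Path) -> None:
    neural = read_bundle(outdir / "neural_synced")
    events, cycles = _load_events_cycles(config, outdir)
    turns = [tuple(t) for t in config["scenario"]["turn_intervals"]]
    (outdir / "maps").mkdir(exist_ok=True)
    for tr in neural.traces:
        if tr.label == "accel":
            continue
        tfmap = _spectral_map(config, tr)
        cnm = epoch_and_normalize(tfmap, cycles, turn_intervals=turns,
                                  provenance=_provenance(config))
        np.savez(outdir / "maps" / f"{tr.label}.npz", freqs=cnm.freqs,
                 values=cnm.values, cycle_values=cnm.cycle_values,
                 n_cycles=cnm.n_cycles)
    log.info("spectra: %d channels mapped", len(neural.traces) - 1)


def stage_coherence(config: dict, outdir: Path, pair: tuple[str, str] | None = None) -> None:
    neural = read_bundle(outdir / "neural_synced")
    labels = [t.label for t in neural.traces if t.label != "accel"]
    if pair is None:
        if len(labels) < 2:
            raise StageError("coherence", "need two neural channels")
        pair = (labels[0], labels[1])
    an = config["analysis"]
    freqs = np.geomspace(max(an["fmin"], 1.0), an["fmax"], an["n_freqs"])
    events, cycles = _load_events_cycles(config, outdir)
    coh = wavelet_coherence(neural[pair[0]], neural[pair[1]], freqs)
    cnm = epoch_and_normalize(coh, cycles, provenance=_provenance(config))
    (outdir / "maps").mkdir(exist_ok=True)
    np.savez(outdir / "maps" / f"coh_{pair[0]}_{pair[1]}.npz", freqs=cnm.freqs,
             values=cnm.values, cycle_values=cnm.cycle_values, n_cycles=cnm.n_cycles)
    log.info("coherence: %s-%s", *pair)


def stage_band_scan(config: dict, outdir: Path, channel: str | None = None) -> pd.DataFrame:
    neural = read_bundle(outdir / "neural_synced")
    channel = channel or config["analysis"].get("decoder_channel") or \
        next(t.label for t in neural.traces if t.label != "accel")
    events, cycles = _load_events_cycles(config, outdir)
    inc = included(cycles)
    keep = [e for e in events
            if any(c.start <= e.time_s <= c.end for c in inc)]
    tfmap = _spectral_map(config, neural[channel])
    an = config["analysis"]
    edges = scan_grid_edges(step=an["scan_step_hz"])
    edges = edges[edges <= tfmap.freqs.max() + 1e-9]
    P, kinds, _ = event_bin_powers(tfmap, keep, edges)
    table = scan_bands(P, kinds, edges, alpha=an["alpha"])
    table.to_csv(outdir / f"band_scan_{channel}.csv", index=False)
    log.info("band-scan[%s]: %d bands tested, %d significant", channel,
             len(table), int(table["significant"].sum()))
    return table


def stage_decode(config: dict, outdir: Path, channel: str | None = None) -> DecoderReport:
    neural = read_bundle(outdir / "neural_synced")
    channel = channel or config["analysis"].get("decoder_channel") or \
        next(t.label for t in neural.traces if t.label != "accel")
    events, cycles = _load_events_cycles(config, outdir)
    inc = included(cycles)
    toe_offs = [e for e in events if e.kind in ("LTO", "RTO")
                and any(c.start <= e.time_s <= c.end for c in inc)]
    tfmap = _spectral_map(config, neural[channel])
    an = config["analysis"]
    report = decode_toe_offs(
        tfmap, toe_offs,
        candidates={k: tuple(v) for k, v in an["tuning_grid"].items()},
        n_perms=an["n_perms"], seed=config["seed"] + 7,
        provenance={**_provenance(config), "channel": channel},
    )
    out = dataclasses.asdict(report)
    out["selected_bands"] = [[b.lo, b.hi] for b in report.selected_bands]
    (outdir / f"decoder_{channel}.json").write_text(json.dumps(out, indent=1))
    log.info("decode[%s]: accuracy %.3f auc %.3f p %s", channel,
             report.accuracy, report.auc, report.permutation_p)
    return report


def significance_stars(p: float) -> str:
    """Star convention: *p<0.05, **p<0.005, ***p<0.0005."""
    return "***" if p < 0.0005 else "**" if p < 0.005 else "*" if p < 0.05 else ""


def make_report(reports: list[DecoderReport]) -> pd.DataFrame:
    """Per-model accuracies/AUCs plus median and maximum summary rows."""
    if not reports:
        raise ValueError("need at least one decoder report")
    rows = []
    for r in reports:
        rows.append({
            "model": r.provenance.get("channel", r.feature_type),
            "feature_type": r.feature_type,
            "accuracy": r.accuracy,
            "auc": r.auc,
            "permutation_p": r.permutation_p,
            "stars": significance_stars(r.permutation_p)
            if r.permutation_p is not None else "",
        })
    df = pd.DataFrame(rows)
    summary = pd.DataFrame([
        {"model": "median", "accuracy": df["accuracy"].median(), "auc": df["auc"].median()},
        {"model": "maximum", "accuracy": df["accuracy"].max(), "auc": df["auc"].max()},
    ])
    return pd.concat([df, summary], ignore_index=True)


STAGES = ("simulate", "sync", "detect-events", "spectra", "band-scan", "decode")


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run every stage in order; returns a summary dict (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    stage_fns = {
        "simulate": stage_simulate, "sync": stage_sync,
        "detect-events": stage_detect_events, "spectra": stage_spectra,
        "band-scan": stage_band_scan, "decode": stage_decode,
    }
    results: dict = {"provenance": _provenance(config)}
    for name in STAGES:
        try:
            out = stage_fns[name](config, outdir)
        except Exception as e:  # noqa: BLE001 - abort with stage name
            raise StageError(name, str(e)) from e
        if name == "band-scan":
            results["bands_tested"] = len(out)
            results["bands_significant"] = int(out["significant"].sum())
        elif name == "decode":
            results["decoder"] = {
                "accuracy": out.accuracy, "auc": out.auc,
                "permutation_p": out.permutation_p,
                "selected_bands": [[b.lo, b.hi] for b in out.selected_bands],
            }
    (outdir / "summary.json").write_text(json.dumps(results, indent=1, sort_keys=True))
    return results
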