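"""Canonical synthetic study conditions.

These helpers freeze the scenarios exercised by the test-suite and the
reproduction script so that every entry point builds the same synthetic
subjects: walking bouts with the generator's default gait parameters and a
lateralized low-frequency (6-12 Hz) modulation during weight acceptance
through contralateral mid-swing, mirrored by half a gait cycle between
hemispheres — the structure reported for subthalamic recordings during
overground walking.  A ``gain`` of zero turns every scenario into its
matched null.
"""

from __future__ import annotations

import numpy as np

from .gait_events import GaitEvent
from .io_sync import RecordingBundle
from .synth import (GaitTimeline, GaitTimelineSpec, ModulationSpec,
                    mirror_modulation, simulate_lfp, simulate_timeline)

#: the planted biomarker band (Hz) and its left-hemisphere phase window
#: (percent of the LHS-anchored gait cycle: double support through
#: contralateral mid-swing)
PLANTED_BAND = (6.0, 12.0)
LEFT_PHASE_WINDOW = (0.0, 35.0)
PLANTED_GAIN = 1.5

#: per-subject included-cycle counts of the three-subject cohort
COHORT_CYCLES = (40, 67, 106)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def planted_subject(
    seed: int,
    n_cycles: int = 100,
    gain: float = PLANTED_GAIN,
    band: tuple[float, float] = PLANTED_BAND,
) -> tuple[GaitTimeline, RecordingBundle, list[GaitEvent]]:
    """One subject with a lateralized gait-locked modulation.

    The left-hemisphere channel ``stn_l`` carries the band-limited component
    gated to 0-35% of the cycle; ``stn_r`` carries the same modulation
    mirrored by +50% (the opposite hemisphere's weight acceptance).  Returns
    the ground-truth timeline, the neural bundle, and the toe-off events.
    """
    s_tl, s_lfp = _child_seeds(seed, 2)
    timeline = simulate_timeline(GaitTimelineSpec(n_cycles=n_cycles, seed=s_tl))
    left = ModulationSpec("stn_l", band[0], band[1], LEFT_PHASE_WINDOW, gain=gain)
    mods = [left] + mirror_modulation(left, channel="stn_r")
    neural = simulate_lfp(timeline, mods, seed=s_lfp)
    toe_offs = [e for e in timeline.events if e.kind in ("LTO", "RTO")]
    return timeline, neural, toe_offs


def null_subject(seed: int, n_cycles: int = 100):
    """Matched no-modulation subject (stationary channels)."""
    return planted_subject(seed, n_cycles=n_cycles, gain=0.0)


def cohort(seed: int, gain: float = PLANTED_GAIN,
           cycle_counts: tuple[int, ...] = COHORT_CYCLES):
    """Three synthetic subjects with the planted modulation (cycle counts
    matching the walking bouts retained per subject in the source study)."""
    out = []
    for child, n in zip(_child_seeds(seed, len(cycle_counts)), cycle_counts):
        out.append(planted_subject(child, n_cycles=n, gain=gain))
    return out
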