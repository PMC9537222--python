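"""Action-potential traces, biomarker extraction and stability screening.

Biomarkers follow the conventions used throughout atrial population-of-models
work: RMP is the diastolic potential immediately before the stimulus, APA is
peak minus RMP, and APDx is measured from the activation instant (maximum
upstroke velocity) to the first crossing of ``Vpeak - x% * APA``.
Triangulation, a proarrhythmia marker, is ``TRI = APD90 - APD50``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "APTrace",
    "BiomarkerSet",
    "StabilityReport",
    "BiomarkerError",
    "compute_biomarkers",
    "check_stability",
]


class BiomarkerError(ValueError):
    """Raised when a trace has no measurable AP (caller marks it unstable)."""


@dataclass
class APTrace:
    """Sampled membrane-potential trace for one beat (or a quiescent tail).

    ``stimulus_onset`` is in the same time base as ``times``; ``ok=False``
    flags a trace truncated by numerical blow-up.
    """

    times: np.ndarray
    voltages: np.ndarray
    stimulus_onset: float = 0.0
    ok: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.times.shape != self.voltages.shape:
            raise ValueError("times and voltages must have equal length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.voltages]),
                   delimiter=",", header="time_ms,V_mV", comments="")


@dataclass(frozen=True)
class BiomarkerSet:
    """RMP/APA in mV, durations in ms; TRI = APD90 - APD50 by construction."""

    RMP: float
    APA: float
    APD20: float
    APD50: float
    APD90: float
    TRI: float = field(default=np.nan)

    def __post_init__(self) -> None:
        object.__setattr__(self, "TRI", self.APD90 - self.APD50)

    NAMES = ("RMP", "APA", "APD20", "APD50", "APD90", "TRI")

    def as_array(self) -> np.ndarray:
        return np.array([self.RMP, self.APA, self.APD20,
                         self.APD50, self.APD90, self.TRI])


#: Exclusion-screen failure labels.
FAILURE_REASONS = (
    "spontaneous_depolarisation",
    "rmp_above_minus50",
    "apd_over_1s",
    "nonphysiological_peak",
    "peak_below_zero",
)


@dataclass(frozen=True)
class StabilityReport:
    failure_reasons: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = set(self.failure_reasons) - set(FAILURE_REASONS)
        if bad:
            raise ValueError(f"unknown failure reasons: {sorted(bad)}")

    @property
    def stable(self) -> bool:
        return not self.failure_reasons


def compute_biomarkers(trace: APTrace) -> BiomarkerSet:
    """Extract RMP, APA, APD20/50/90 and TRI from a single-AP trace.

    RMP is the last sample strictly before the stimulus onset; when the
    trace starts exactly at the onset the first sample is used (it is
    recorded before the stimulus current acts, hence diastolic).  The APD
    clock starts at maximum dV/dt on the upstroke.  Raises
    :class:`BiomarkerError` when a repolarisation crossing is missing.
    """
    t = trace.times
    v = trace.voltages
    if t.size < 3:
        raise BiomarkerError("trace too short")

    pre = np.flatnonzero(t < trace.stimulus_onset)
    rmp = v[pre[-1]] if pre.size else v[0]

    post = np.flatnonzero(t >= trace.stimulus_onset)
    if post.size < 3:
        raise BiomarkerError("no samples after stimulus onset")
    i0 = post[0]
    ipeak = i0 + int(np.argmax(v[i0:]))
    vpeak = v[ipeak]
    apa = vpeak - rmp
    if apa <= 0:
        raise BiomarkerError("no positive AP amplitude")

    # activation = maximum forward-difference velocity between onset and peak
    if ipeak == i0:
        iact = ipeak
    else:
        dv = np.diff(v[i0:ipeak + 1]) / np.diff(t[i0:ipeak + 1])
        iact = i0 + int(np.argmax(dv)) + 1
    t_act = t[iact]

    apds = {}
    for x in (20, 50, 90):
        thr = vpeak - (x / 100.0) * apa
        below = np.flatnonzero(v[ipeak:] <= thr)
        if below.size == 0:
            raise BiomarkerError(f"no {x}% repolarisation crossing in trace")
        i = ipeak + below[0]
        if i == ipeak:
            tc = t[i]
        else:  # linear interpolation of the crossing
            f = (thr - v[i - 1]) / (v[i] - v[i - 1])
            tc = t[i - 1] + f * (t[i] - t[i - 1])
        apds[x] = tc - t_act

    return BiomarkerSet(RMP=float(rmp), APA=float(apa),
                        APD20=float(apds[20]), APD50=float(apds[50]),
                        APD90=float(apds[90]))


def check_stability(last_beat: APTrace,
                    quiescent: APTrace,
                    biomarkers: BiomarkerSet | None,
                    rmp_cutoff: float = -50.0,
                    apd_cutoff: float = 1000.0,
                    peak_ceiling: float = 60.0,
                    spont_rise: float = 10.0) -> StabilityReport:
    """Exclusion screen for unstable, self-exciting or non-physiological APs.

    Flags: spontaneous depolarisation (any rise of more than ``spont_rise``
    mV above the running diastolic minimum during the quiescent tail), RMP
    less negative than ``rmp_cutoff``, APD90 beyond ``apd_cutoff``
    (``biomarkers=None``, i.e. no repolarisation within the beat, also
    counts), peak above ``peak_ceiling`` and peak below 0 mV.
    """
    reasons: set[str] = set()
    if not (last_beat.ok and quiescent.ok):
        reasons.add("spontaneous_depolarisation")  # numerical blow-up

    v = last_beat.voltages
    t = last_beat.times
    post = np.flatnonzero(t >= last_beat.stimulus_onset)
    vpeak = float(np.max(v[post])) if post.size else float(np.max(v))
    if vpeak > peak_ceiling:
        reasons.add("nonphysiological_peak")
    if vpeak < 0.0:
        reasons.add("peak_below_zero")

    if biomarkers is None:
        reasons.add("apd_over_1s")
    else:
        if biomarkers.RMP > rmp_cutoff:
            reasons.add("rmp_above_minus50")
        if biomarkers.APD90 > apd_cutoff:
            reasons.add("apd_over_1s")

    q = quiescent.voltages
    if q.size >= 2:
        cummin = np.minimum.accumulate(q)
        if np.any(q - cummin > spont_rise):
            reasons.add("spontaneous_depolarisation")

    return StabilityReport(frozenset(reasons))
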