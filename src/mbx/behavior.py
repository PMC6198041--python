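"""T-maze scoring, group statistics, and conditioning-protocol timelines.

The behavioral readout is the performance index (PI): flies choosing the
shock-paired odor arm minus flies choosing the unpaired arm, over the
total.  Negative PI means learned avoidance.  A biological replicate is
the mean PI of two reciprocally trained groups (the odors swap roles).

Protocols are declarative: a spec of named phases (training, rest,
re-exposures with an inter-trial interval, retraining, test) compiles into
a deterministic, serializable list of timed events.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TMazeCount",
    "PerformanceScore",
    "TimelineEvent",
    "ProtocolSpec",
    "ProtocolTimeline",
    "performance_index",
    "reciprocal_score",
    "build_protocol",
    "group_compare",
]


@dataclass(frozen=True)
class TMazeCount:
    """Arm counts from one T-maze test."""

    n_csplus_arm: int
    n_csminus_arm: int
    n_nonchoosers: int = 0

    def __post_init__(self) -> None:
        if min(self.n_csplus_arm, self.n_csminus_arm, self.n_nonchoosers) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_csplus_arm + self.n_csminus_arm + self.n_nonchoosers


@dataclass(frozen=True)
class PerformanceScore:
    pi: float
    reciprocal: bool = False

    def __post_init__(self) -> None:
        if abs(self.pi) > 1 + 1e-12:
            raise ValueError("|PI| cannot exceed 1")


def performance_index(count: TMazeCount, include_nonchoosers: bool = True) -> PerformanceScore:
    """PI = (CS+ arm − CS− arm) / total flies.

    Non-choosing flies sit in the denominator by default (the "total
    number of flies"); ``include_nonchoosers=False`` drops them.
    """
    denom = count.total if include_nonchoosers else count.n_csplus_arm + count.n_csminus_arm
    if denom == 0:
        raise ValueError("cannot score zero flies")
    return PerformanceScore((count.n_csplus_arm - count.n_csminus_arm) / denom)


def reciprocal_score(pi_a: PerformanceScore | float,
                     pi_b: PerformanceScore | float) -> PerformanceScore:
    """One biological n: the mean of two reciprocally trained groups."""
    a = pi_a.pi if isinstance(pi_a, PerformanceScore) else float(pi_a)
    b = pi_b.pi if isinstance(pi_b, PerformanceScore) else float(pi_b)
    return PerformanceScore((a + b) / 2.0, reciprocal=True)


# ---------------------------------------------------------------------------
# Protocol timelines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimelineEvent:
    """A single timed event; ``value`` carries e.g. shock voltage or °C."""

    label: str
    onset_s: float
    duration_s: float
    value: float | str | None = None


@dataclass
class ProtocolSpec:
    """Parameters of the aversive-conditioning / extinction protocol.

    Defaults are the standard regimen: 1-min CS+ with twelve 90-V shocks at
    5-s intervals (first shock 1.2 s after odor onset), 45 s clean air,
    1-min CS− without shock; test is a 2-min T-maze choice.  Re-exposures
    are unreinforced 1-min CS+ (or CS−) presentations separated by an ITI
    measured end-of-trial to start-of-next.
    """

    cs_plus_odor: str = "MCH"
    cs_minus_odor: str = "OCT"
    odor_duration_s: float = 60.0
    n_shocks: int = 12
    shock_voltage: float = 90.0
    inter_shock_interval_s: float = 5.0
    first_shock_delay_s: float = 1.2
    shock_duration_s: float = 1.25
    air_gap_s: float = 45.0
    rest_s: float = 0.0
    n_reexposures: int = 0
    reexposure_odor: str = "CS+"
    reexposure_iti_s: float = 900.0
    retrain: bool = False
    test_duration_s: float = 120.0
    temperature_shift: tuple[float, str] | None = None  # (°C, phase label)


@dataclass
class ProtocolTimeline:
    events: list[TimelineEvent]

    def by_label(self, label: str) -> list[TimelineEvent]:
        return [e for e in self.events if e.label == label]

    def to_json(self) -> str:
        return json.dumps([asdict(e) for e in self.events], indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ProtocolTimeline":
        return cls([TimelineEvent(**d) for d in json.loads(text)])


def _training_block(spec: ProtocolSpec, t: float, events: list[TimelineEvent],
                    phase: str) -> float:
    """Append one CS+(shock) / air / CS− block starting at time ``t``."""
    last_shock_end = (spec.first_shock_delay_s
                      + (spec.n_shocks - 1) * spec.inter_shock_interval_s
                      + spec.shock_duration_s)
    if spec.n_shocks > 0 and last_shock_end > spec.odor_duration_s:
        raise ValueError(
            f"shock train ({last_shock_end:.1f} s) exceeds the CS+ window "
            f"({spec.odor_duration_s:.1f} s)"
        )
    events.append(TimelineEvent(f"odor_CS+:{phase}", t, spec.odor_duration_s,
                                spec.cs_plus_odor))
    for k in range(spec.n_shocks):
        events.append(TimelineEvent(
            f"shock:{phase}", t + spec.first_shock_delay_s + k * spec.inter_shock_interval_s,
            spec.shock_duration_s, spec.shock_voltage))
    t_cs_minus = t + spec.odor_duration_s + spec.air_gap_s
    events.append(TimelineEvent(f"odor_CS-:{phase}", t_cs_minus, spec.odor_duration_s,
                                spec.cs_minus_odor))
    return t_cs_minus + spec.odor_duration_s


def build_protocol(spec: ProtocolSpec) -> ProtocolTimeline:
    """Compile a protocol spec into its deterministic event timeline.

    Standard training yields exactly ``n_shocks`` shock events starting at
    CS+ onset + first-shock delay; the CS− comes on 45 s (``air_gap_s``)
    after CS+ offset.  Each re-exposure trial starts one ITI after the end
    of the previous one.  Odor epochs never overlap by construction.
    """
    if spec.odor_duration_s <= 0 or spec.test_duration_s <= 0:
        raise ValueError("durations must be positive")
    if spec.reexposure_iti_s < 0:
        raise ValueError("ITI must be non-negative")
    events: list[TimelineEvent] = []
    t = _training_block(spec, 0.0, events, "train")
    t += spec.rest_s
    for trial in range(spec.n_reexposures):
        label = f"odor_{spec.reexposure_odor}:reexposure_{trial + 1}"
        events.append(TimelineEvent(label, t, spec.odor_duration_s,
                                    spec.cs_plus_odor if spec.reexposure_odor == "CS+"
                                    else spec.cs_minus_odor))
        t += spec.odor_duration_s
        if trial < spec.n_reexposures - 1:
            t += spec.reexposure_iti_s
    if spec.retrain:
        t += spec.reexposure_iti_s
        t = _training_block(spec, t, events, "retrain")
    if spec.temperature_shift is not None:
        celsius, phase = spec.temperature_shift
        anchors = [e for e in events if e.label.endswith(phase)] or events
        start = min(e.onset_s for e in anchors)
        stop = max(e.onset_s + e.duration_s for e in anchors)
        events.append(TimelineEvent("temperature", start, stop - start, celsius))
    events.append(TimelineEvent("test", t, spec.test_duration_s))
    events.sort(key=lambda e: (e.onset_s, e.label))
    _check_no_odor_overlap(events)
    return ProtocolTimeline(events)


def _check_no_odor_overlap(events: Sequence[TimelineEvent]) -> None:
    odor = sorted((e for e in events if e.label.startswith("odor_")),
                  key=lambda e: e.onset_s)
    for prev, nxt in zip(odor, odor[1:]):
        if nxt.onset_s < prev.onset_s + prev.duration_s - 1e-9:
            raise ValueError(f"overlapping odor epochs: {prev.label} / {nxt.label}")


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def group_compare(scores_by_group: dict[str, Sequence[float]],
                  alpha: float = 0.05, posthoc: bool = True) -> dict[str, object]:
    """Compare PI scores across genotype/treatment groups.

    Two groups: unpaired two-sided t test.  More: one-way ANOVA followed by
    Tukey's HSD pairwise table (skipped when ``posthoc`` is false, e.g. in
    large simulation sweeps that only need the omnibus p).  Every group
    needs n >= 3.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in scores_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if v.size < 3:
            raise ValueError(f"group {g!r} has n={v.size} < 3")
    names = list(groups)
    if len(groups) == 2:
        a, b = (groups[n] for n in names)
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            return {"test_used": "unpaired t", "statistic": 0.0, "p": 1.0,
                    "groups": names, "alpha": alpha}
        res = stats.ttest_ind(a, b)
        return {"test_used": "unpaired t", "statistic": float(res.statistic),
                "p": float(res.pvalue), "groups": names, "alpha": alpha}
    f_res = stats.f_oneway(*groups.values())
    pairwise = None
    if posthoc:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate(list(groups.values()))
        labels = np.concatenate([[g] * groups[g].size for g in names])
        tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
        pairwise = [
            {"group_a": str(r[0]), "group_b": str(r[1]), "mean_diff": float(r[2]),
             "p_adj": float(r[3]), "reject": bool(r[6])}
            for r in tukey.summary().data[1:]
        ]
    return {"test_used": "one-way ANOVA + Tukey HSD", "statistic": float(f_res.statistic),
            "p": float(f_res.pvalue), "pairwise": pairwise, "groups": names, "alpha": alpha}
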