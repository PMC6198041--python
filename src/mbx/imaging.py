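"""Quantification of odor- and light-evoked fluorescence responses.

Implements the two baseline conventions used for in-vivo GCaMP recordings
(a 2-s pre-odor window per stimulus for conditioning experiments; the
first 9 s of the record for optogenetic connectivity experiments), the
5-s odor-window area under the curve, per-fly normalization to the
novel-odor (IAA) response, and the normality-gated paired statistics used
to compare CS+ against CS− across a cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Epoch",
    "FluorescenceTrace",
    "OdorResponse",
    "PairedCohortResult",
    "compute_dff",
    "odor_response_auc",
    "normalize_to_novel",
    "odor_responses",
    "analyze_cohort",
    "paired_group_test",
    "optogenetic_response",
]

DEFAULT_SAMPLING_RATE_HZ = 5.92
EPOCH_LABELS = ("CS+", "CS-", "novel", "light", "shock")


@dataclass(frozen=True)
class Epoch:
    """A labelled stimulus window (seconds from record start)."""

    label: str
    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ValueError("epoch duration must be non-negative")


@dataclass
class FluorescenceTrace:
    """A single-ROI fluorescence time series with stimulus epochs.

    ``samples`` are raw fluorescence in arbitrary units on a uniform grid
    at ``sampling_rate`` (Hz; 5.92 by default, the native two-photon frame
    rate).  Epochs must lie within the record.
    """

    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ
    epochs: list[Epoch] = field(default_factory=list)
    fly_id: str = ""
    roi: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for ep in self.epochs:
            if ep.onset_s < 0 or ep.onset_s + ep.duration_s > self.duration_s + 1e-9:
                raise ValueError(f"epoch {ep} outside the record")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate

    def sample_index(self, t_s: float) -> int:
        """Nearest-sample index for a time point (onsets snap to the grid)."""
        return int(round(t_s * self.sampling_rate))

    def epoch(self, label: str) -> Epoch:
        for ep in self.epochs:
            if ep.label == label:
                return ep
        raise KeyError(f"no epoch labelled {label!r}")


def compute_dff(trace: FluorescenceTrace,
                baseline_mode: Literal["pre_odor_2s", "first_9s"] = "pre_odor_2s",
                epoch: Epoch | str | None = None) -> np.ndarray:
    """ΔF/F₀ for a trace under one of the two baseline conventions.

    ``pre_odor_2s``: F₀ is the mean F from 2 s before up to the stimulus
    onset of ``epoch`` (required).  ``first_9s``: F₀ is the mean F over the
    first 9 s of the record.  Returns (F − F₀)/F₀ per sample.
    """
    if baseline_mode == "first_9s":
        n = trace.sample_index(9.0)
        if n < 1:
            raise ValueError("record shorter than the 9-s baseline window")
        f0 = float(np.mean(trace.samples[:n]))
    elif baseline_mode == "pre_odor_2s":
        if epoch is None:
            raise ValueError("pre_odor_2s baseline requires a stimulus epoch")
        ep = trace.epoch(epoch) if isinstance(epoch, str) else epoch
        stop = trace.sample_index(ep.onset_s)
        start = max(0, trace.sample_index(ep.onset_s - 2.0))
        if stop - start < 1:
            raise ValueError("no samples in the 2-s pre-odor baseline window")
        f0 = float(np.mean(trace.samples[start:stop]))
    else:
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    if f0 <= 0:
        raise ValueError("non-positive baseline")
    return (trace.samples - f0) / f0


def odor_response_auc(dff_or_ff0: np.ndarray, sampling_rate: float,
                      odor_onset_s: float, duration_s: float = 5.0) -> float:
    """Trapezoidal integral of the response over the odor window.

    The integrand is whatever series is passed (F/F₀ by convention here,
    i.e. ΔF/F₀ + 1; ΔF/F₀ works identically).  The onset snaps to the
    nearest sample of the native grid.  Units: (dimensionless)·s.
    """
    y = np.asarray(dff_or_ff0, dtype=float)
    start = int(round(odor_onset_s * sampling_rate))
    stop = int(round((odor_onset_s + duration_s) * sampling_rate))
    if start < 0 or stop > len(y) - 1 or stop <= start:
        raise ValueError("odor window exceeds the record")
    # uniform grid: integrate with dx so equal responses anywhere in the
    # record integrate to bitwise-equal AUCs
    return float(np.trapezoid(y[start:stop + 1], dx=1.0 / sampling_rate))


@dataclass
class OdorResponse:
    """One fly's response to one odor: raw and novel-normalized AUC."""

    fly_id: str
    roi: str
    odor: str
    auc: float
    normalized_auc: float | None = None


def normalize_to_novel(auc_cs: float, auc_novel: float, eps: float = 1e-9) -> float:
    """Per-fly, per-trial normalization: AUC divided by the novel-odor
    (IAA) AUC of the same fly and trial.

    Near-zero novel responses (|AUC| < eps) cannot serve as a denominator;
    such flies are flagged for exclusion with a warning.
    """
    if abs(auc_novel) < eps:
        warnings.warn("novel-odor AUC ~ 0: fly excluded from normalization", stacklevel=2)
        return float("nan")
    return auc_cs / auc_novel


@dataclass
class PairedCohortResult:
    """Cohort-level CS+ vs CS− comparison with a normality-gated test."""

    n: int
    test_used: str
    statistic: float
    p: float
    pairs: np.ndarray
    boxplot: dict[str, dict[str, float]]


def _boxplot_summary(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"q1": float(q1), "median": float(med), "q3": float(q3),
            "min": float(values.min()), "max": float(values.max())}


def paired_group_test(cs_plus_values: Sequence[float],
                      cs_minus_values: Sequence[float],
                      alpha_normality: float = 0.05) -> PairedCohortResult:
    """Paired CS+ vs CS− comparison across flies.

    Shapiro-Wilk on the paired differences gates the test at
    ``alpha_normality``: normal differences get a paired t test, otherwise
    a Wilcoxon matched-pairs signed-rank test.  All-zero differences are a
    degenerate case reported with p = 1.
    """
    a = np.asarray(cs_plus_values, dtype=float)
    b = np.asarray(cs_minus_values, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = a.size
    if n < 5:
        raise ValueError("need at least 5 complete pairs")
    diffs = a - b
    pairs = np.column_stack([a, b])
    box = {"CS+": _boxplot_summary(a), "CS-": _boxplot_summary(b)}
    if np.all(diffs == 0):
        return PairedCohortResult(n, "degenerate", 0.0, 1.0, pairs, box)
    _, p_norm = stats.shapiro(diffs)
    if p_norm >= alpha_normality:
        res = stats.ttest_rel(a, b)
        test = "paired t"
    else:
        res = stats.wilcoxon(a, b)
        test = "Wilcoxon signed-rank"
    return PairedCohortResult(n, test, float(res.statistic), float(res.pvalue), pairs, box)


def odor_responses(trace: FluorescenceTrace,
                   odors: Sequence[str] = ("CS+", "CS-", "novel"),
                   integrand: Literal["f_over_f0", "dff"] = "f_over_f0",
                   ) -> dict[str, OdorResponse]:
    """Per-odor AUCs of one fly's trace, normalized to the novel odor.

    For each odor epoch, ΔF/F₀ is computed against its own 2-s pre-odor
    baseline and the response is integrated over the 5-s odor window
    (integrand F/F₀ by convention; ``"dff"`` integrates ΔF/F₀ instead).
    The CS+ and CS− AUCs are then divided by the novel-odor (IAA) AUC.
    """
    responses: dict[str, OdorResponse] = {}
    for odor in odors:
        ep = trace.epoch(odor)
        dff = compute_dff(trace, "pre_odor_2s", ep)
        series = dff + 1.0 if integrand == "f_over_f0" else dff
        auc = odor_response_auc(series, trace.sampling_rate, ep.onset_s, ep.duration_s)
        responses[odor] = OdorResponse(trace.fly_id, trace.roi, odor, auc)
    novel = responses.get("novel")
    if novel is not None:
        for odor, resp in responses.items():
            resp.normalized_auc = normalize_to_novel(resp.auc, novel.auc)
    return responses


def analyze_cohort(traces: Sequence[FluorescenceTrace],
                   integrand: Literal["f_over_f0", "dff"] = "f_over_f0",
                   ) -> PairedCohortResult:
    """Full pipeline over a cohort: per-fly normalized CS+/CS− AUCs, then
    the normality-gated paired test."""
    cs_plus, cs_minus = [], []
    for trace in traces:
        resp = odor_responses(trace, integrand=integrand)
        cs_plus.append(resp["CS+"].normalized_auc)
        cs_minus.append(resp["CS-"].normalized_auc)
    return paired_group_test(cs_plus, cs_minus)


def optogenetic_response(dff_traces: Sequence[np.ndarray], sampling_rate: float,
                         stim_onset_s: float) -> dict[str, object]:
    """Pre/post comparison around an optogenetic stimulus.

    Per preparation, mean ΔF/F₀ over [onset − 1 s, onset) is compared with
    [onset, onset + 1 s) and the cohort is tested with a paired t test.
    """
    pre_means, post_means = [], []
    for y in dff_traces:
        y = np.asarray(y, dtype=float)
        i_on = int(round(stim_onset_s * sampling_rate))
        i_pre = int(round((stim_onset_s - 1.0) * sampling_rate))
        i_post = int(round((stim_onset_s + 1.0) * sampling_rate))
        if i_pre < 0 or i_post > len(y):
            raise ValueError("need at least 1 s of record on each side of stimulation")
        pre_means.append(float(np.mean(y[i_pre:i_on])))
        post_means.append(float(np.mean(y[i_on:i_post])))
    pre = np.array(pre_means)
    post = np.array(post_means)
    if np.allclose(pre, post):
        statistic, p = 0.0, 1.0
    else:
        res = stats.ttest_rel(post, pre)
        statistic, p = float(res.statistic), float(res.pvalue)
    return {"pre_means": pre, "post_means": post, "n": len(pre),
            "statistic": statistic, "p": p, "test_used": "paired t"}
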