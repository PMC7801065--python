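"""H-scores from tissue-microarray cores and the validation statistics.

The H-score of a stained core is staining intensity (0-3) times the percent
of positive cells, giving a semiquantitative scale from 0 (no expression)
to 300 (uniform high expression).  A stratified reading — a list of
(intensity, percent) pairs — is also supported, scoring the weighted sum
over strata.  Per tumor, the H-score is the mean over its usable cores
(three per tumor by design); cores containing no tumor cells are excluded,
and a tumor whose cores are all excluded yields no score.

Two statistical checks compare the experimental H-scores with the
atlas-derived quasi H-scores: a one-sample t-test of the per-tumor H-scores
against the cohort quasi H-score, and the Pearson correlation of per-gene
scores with matched FPKM values within a tumor type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ValidationError


@dataclass(frozen=True)
class CoreReading:
    """One TMA core: a single dominant intensity with its percent positive,
    or a stratified list of (intensity, percent) pairs."""

    intensity: int | None = None
    percent_positive: float | None = None
    pairs: tuple[tuple[int, float], ...] | None = None
    has_tumor_cells: bool = True

    def __post_init__(self) -> None:
        if self.pairs is not None:
            total = 0.0
            for i, p in self.pairs:
                if i not in (0, 1, 2, 3):
                    raise ValidationError(f"intensity must be 0-3, got {i}")
                if not (0.0 <= p <= 100.0):
                    raise ValidationError(f"percent must be in [0, 100], got {p}")
                total += p
            if total > 100.0 + 1e-9:
                raise ValidationError(f"stratified percents sum to {total} > 100")
        else:
            if self.intensity not in (0, 1, 2, 3):
                raise ValidationError(f"intensity must be 0-3, got {self.intensity}")
            if self.percent_positive is None or not (0.0 <= self.percent_positive <= 100.0):
                raise ValidationError(
                    f"percent must be in [0, 100], got {self.percent_positive}"
                )


@dataclass(frozen=True)
class TumorHScore:
    tumor_id: str
    h_score: float
    n_cores_used: int


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        if self.n < 2:
            raise ValidationError("n must be >= 2")


@dataclass(frozen=True)
class TTestResult:
    mean_difference: float
    ci_low: float
    ci_high: float
    t_statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n_pairs: int
    dropped: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# H-scores


def core_h_score(core: CoreReading) -> float:
    """H-score of one core in [0, 300]; raises on a core without tumor cells."""
    if not core.has_tumor_cells:
        raise DegenerateDataError("core contains no tumor cells; excluded from analysis")
    if core.pairs is not None:
        return float(sum(i * p for i, p in core.pairs))
    return float(core.intensity * core.percent_positive)


def tumor_h_score(
    cores: Sequence[CoreReading], tumor_id: str = ""
) -> TumorHScore | None:
    """Mean H-score over the usable cores of one tumor.

    Returns None when every core is excluded (the tumor leaves the analysis).
    Tumors with fewer usable cores than drawn are averaged over what remains.
    """
    usable = [c for c in cores if c.has_tumor_cells]
    if not usable:
        return None
    scores = [core_h_score(c) for c in usable]
    return TumorHScore(tumor_id=tumor_id, h_score=float(np.mean(scores)),
                       n_cores_used=len(usable))


# ---------------------------------------------------------------------------
# one-sample t-test


def one_sample_t(summary: SummaryStats, mu0: float, alpha: float = 0.05) -> TTestResult:
    """Two-sided one-sample t-test of a summarized sample against mu0.

    The confidence interval is for the mean difference (mean - mu0).  A
    zero-variance sample equal to mu0 gives p = 1 by convention; one that
    differs from mu0 admits no t-test and raises.
    """
    diff = summary.mean - mu0
    df = summary.n - 1
    if summary.sd == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, 0.0, 0.0, 0.0, df, 1.0)
        raise DegenerateDataError("zero sample variance with mean != mu0: t undefined")
    se = summary.sd / math.sqrt(summary.n)
    t_stat = diff / se
    p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    half = float(stats.t.ppf(1.0 - alpha / 2.0, df)) * se
    return TTestResult(diff, diff - half, diff + half, t_stat, df, p)


def one_sample_t_raw(scores: Sequence[float], mu0: float, alpha: float = 0.05) -> TTestResult:
    """Same test from raw per-tumor H-scores (sample SD with n-1 denominator)."""
    if len(scores) < 2:
        raise ValidationError("need at least 2 scores for a t-test")
    x = np.asarray(scores, dtype=float)
    if float(np.std(x, ddof=1)) == 0.0:
        return one_sample_t(SummaryStats(float(x.mean()), 0.0, len(x)), mu0, alpha)
    res = stats.ttest_1samp(x, popmean=mu0)
    ci = res.confidence_interval(confidence_level=1.0 - alpha)
    diff = float(x.mean()) - mu0
    return TTestResult(
        mean_difference=diff,
        ci_low=float(ci.low) - mu0,
        ci_high=float(ci.high) - mu0,
        t_statistic=float(res.statistic),
        df=len(x) - 1,
        p_value=float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# score-FPKM correlation


def score_fpkm_correlation(
    scores: Mapping[str, float], fpkm: Mapping[str, float]
) -> CorrelationResult:
    """Pearson correlation of per-gene scores vs FPKM within one tumor type.

    Genes missing either value are dropped pairwise (and reported); a
    constant vector leaves the correlation undefined and raises.
    """
    shared = sorted(set(scores) & set(fpkm))
    dropped = tuple(sorted((set(scores) | set(fpkm)) - set(shared)))
    if len(shared) < 3:
        raise ValidationError(f"need >= 3 paired values, got {len(shared)}")
    xs = np.array([scores[g] for g in shared], dtype=float)
    ys = np.array([fpkm[g] for g in shared], dtype=float)
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        raise DegenerateDataError("constant input: Pearson correlation undefined")
    res = stats.pearsonr(xs, ys)
    return CorrelationResult(
        r=float(res.statistic), p_value=float(res.pvalue),
        n_pairs=len(shared), dropped=dropped,
    )
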