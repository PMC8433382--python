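"""Dependence-corrected inference.

Units recorded on consecutive days are not independent samples (the same
neuron can stay on a tungsten electrode for up to a week), so every
seventh unit is conservatively treated as independent: t-tests, Pearson
tests and ANOVAs compute their degrees of freedom from n // 7, and
bootstrap standard deviations are inflated by √7.  The factor is a policy
parameter; factor 1 reproduces the classical tests exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import InvalidConfigError

__all__ = [
    "CorrectionPolicy",
    "corrected_ttest",
    "corrected_anova",
    "corrected_pearson",
    "segment_bootstrap",
    "bonferroni",
]


@dataclass(frozen=True)
class CorrectionPolicy:
    """How strongly samples are assumed to be dependent.

    ``dependence_factor`` k means only every k-th observation counts as
    independent: df uses n // k and bootstrap SDs are scaled by √k.
    """

    dependence_factor: int = 7

    def __post_init__(self) -> None:
        if self.dependence_factor < 1:
            raise InvalidConfigError("dependence_factor must be ≥ 1")

    def effective_n(self, n: int) -> int:
        return n // self.dependence_factor

    @property
    def sd_scale(self) -> float:
        return float(np.sqrt(self.dependence_factor))


DEFAULT_POLICY = CorrectionPolicy()


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    df: float


def corrected_ttest(
    sample_a: np.ndarray,
    sample_b: np.ndarray | None = None,
    policy: CorrectionPolicy = DEFAULT_POLICY,
    paired: bool = False,
) -> TestResult:
    """Two-sample (or paired / one-sample) t-test with corrected df.

    The statistic is the classical pooled-variance t; only the degrees of
    freedom shrink to the effective counts (n // factor per group), which
    makes the p-value conservative.  With factor 1 this is exactly the
    classical test.
    """
    a = np.asarray(sample_a, dtype=float)
    if paired:
        if sample_b is None:
            raise InvalidConfigError("paired test needs two samples")
        a = a - np.asarray(sample_b, dtype=float)
        sample_b = None
    if sample_b is None:
        n = a.size
        df = policy.effective_n(n) - 1
        if df < 1:
            raise InvalidConfigError("effective df < 1; too few independent samples")
        se = a.std(ddof=1) / np.sqrt(n)
        t = float(a.mean() / se) if se > 0 else 0.0
    else:
        b = np.asarray(sample_b, dtype=float)
        na, nb = a.size, b.size
        df = policy.effective_n(na) + policy.effective_n(nb) - 2
        if df < 1:
            raise InvalidConfigError("effective df < 1; too few independent samples")
        sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
               / (na + nb - 2))
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        t = float((a.mean() - b.mean()) / se) if se > 0 else 0.0
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(statistic=t, pvalue=p, df=float(df))


def corrected_anova(
    *samples: np.ndarray, policy: CorrectionPolicy = DEFAULT_POLICY
) -> TestResult:
    """One-way ANOVA with denominator df from the effective counts."""
    groups = [np.asarray(s, dtype=float) for s in samples]
    if len(groups) < 2:
        raise InvalidConfigError("ANOVA needs at least two groups")
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = k - 1
    df2 = sum(policy.effective_n(g.size) for g in groups) - k
    if df2 < 1:
        raise InvalidConfigError("effective df < 1; too few independent samples")
    ms_between = ss_between / df1
    ms_within = ss_within / max(sum(g.size for g in groups) - k, 1)
    f = float(ms_between / ms_within) if ms_within > 0 else 0.0
    p = float(sps.f.sf(f, df1, df2))
    return TestResult(statistic=f, pvalue=p, df=float(df2))


def corrected_pearson(
    x: np.ndarray, y: np.ndarray, policy: CorrectionPolicy = DEFAULT_POLICY
) -> TestResult:
    """Pearson correlation with df from the effective sample count."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    df = policy.effective_n(x.size) - 2
    if df < 1:
        raise InvalidConfigError("effective df < 1; too few independent samples")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return TestResult(statistic=r, pvalue=0.0, df=float(df))
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(statistic=r, pvalue=p, df=float(df))


def segment_bootstrap(
    values: np.ndarray,
    statistic=np.mean,
    n_segments: int = 100,
    n_reps: int = 100,
    policy: CorrectionPolicy | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Block bootstrap over contiguous equal-size segments of a series.

    The series is cut into ``n_segments`` contiguous blocks; each rep
    resamples blocks with replacement, concatenates them and recomputes
    the statistic.  Returns (distribution, SD), with the SD multiplied by
    √dependence_factor when a policy is given.
    """
    if n_segments < 2:
        raise InvalidConfigError("n_segments must be ≥ 2")
    if n_reps < 10:
        raise InvalidConfigError("n_reps must be ≥ 10")
    values = np.asarray(values, dtype=float)
    if values.size < n_segments:
        raise InvalidConfigError("series shorter than the number of segments")
    bounds = np.linspace(0, values.size, n_segments + 1).astype(int)
    blocks = [values[bounds[i]:bounds[i + 1]] for i in range(n_segments)]
    rng = np.random.default_rng(seed)
    dist = np.empty(n_reps)
    for r in range(n_reps):
        pick = rng.integers(0, n_segments, size=n_segments)
        dist[r] = statistic(np.concatenate([blocks[i] for i in pick]))
    sd = float(dist.std())
    if policy is not None:
        sd *= policy.sd_scale
    return dist, sd


def bonferroni(pvalue: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted p-value (capped at 1)."""
    return float(min(1.0, pvalue * n_comparisons))
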