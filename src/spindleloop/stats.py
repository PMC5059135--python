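"""Nonparametric inference for small-n electrophysiology.

Paired comparisons use the exact Wilcoxon signed-rank test (n < 10 per
animal group, so exact distributions matter: n = 6 uniformly signed
pairs give the recurring two-sided p = 0.03125). Event-duration
distributions are compared with the two-sample Kolmogorov-Smirnov test,
reported together with 95% Dvoretzky-Kiefer-Wolfowitz confidence bands
around each empirical CDF. Spectra are compared frequency-wise with a
paired sign-flip permutation test whose familywise error is controlled
by the pixel-based max-statistic method: the corrected threshold is the
(1 - alpha) quantile of the null distribution of the maximum absolute
statistic across all frequency bins.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    flags: dict = field(default_factory=dict)


def wilcoxon_signed_rank(pre, post) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped (Wilcoxon's rule); the exact null
    distribution is used for n <= 25 effective pairs. All-zero
    differences return p = 1 with a flag rather than an error.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be paired 1-d arrays")
    d = post - pre
    nz = d[d != 0]
    if nz.size == 0:
        return TestResult(0.0, 1.0, 0, "wilcoxon-exact", {"all_zero": True})
    method = "exact" if nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size else "approx"
    res = sps.wilcoxon(nz, alternative="two-sided", method=method, zero_method="wilcox")
    return TestResult(
        float(res.statistic), float(res.pvalue), int(nz.size), f"wilcoxon-{method}"
    )


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H test across independent groups (thin contract
    over the standard implementation)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    res = sps.kruskal(*groups)
    return TestResult(
        float(res.statistic), float(res.pvalue), int(sum(len(g) for g in groups)), "kruskal-wallis"
    )


@dataclass
class CdfBand:
    """Empirical CDF with a DKW confidence band at level 1 - alpha."""

    x: np.ndarray
    cdf: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    epsilon: float


def _dkw_band(sample: np.ndarray, alpha: float) -> CdfBand:
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    cdf = np.arange(1, n + 1) / n
    eps = np.sqrt(np.log(2.0 / alpha) / (2.0 * n))
    return CdfBand(x=x, cdf=cdf, lower=np.clip(cdf - eps, 0, 1), upper=np.clip(cdf + eps, 0, 1), epsilon=float(eps))


@dataclass
class KsResult:
    statistic: float
    p_value: float
    n_x: int
    n_y: int
    band_x: CdfBand
    band_y: CdfBand
    alpha: float


def ks_two_sample_with_ci(x, y, alpha: float = 0.05) -> KsResult:
    """Two-sample KS test with per-sample DKW 1-alpha CDF bands
    (epsilon = sqrt(ln(2/alpha) / 2n))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test requires non-empty samples")
    res = sps.ks_2samp(x, y)
    return KsResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_x=int(x.size),
        n_y=int(y.size),
        band_x=_dkw_band(x, alpha),
        band_y=_dkw_band(y, alpha),
        alpha=alpha,
    )


# --------------------------------------------------------------------------
# frequency-wise permutation test with max-statistic correction
# --------------------------------------------------------------------------

#: exhaustive sign-flip enumeration is used up to this many subjects
EXHAUSTIVE_MAX_N = 12


@dataclass
class PermutationSpectrumResult:
    """Per-frequency paired-difference statistic with the pixel-based
    (max-statistic) corrected significance mask and its maximal
    contiguous frequency ranges."""

    freq_hz: np.ndarray
    observed_stat: np.ndarray
    corrected_threshold: float
    significant_mask: np.ndarray
    significant_ranges_hz: list[tuple[float, float]]
    n_permutations: int
    alpha: float
    seed: Optional[int]
    exhaustive: bool
    correction: str = "pixel"

    def __post_init__(self) -> None:
        if self.correction == "pixel":
            # pixel invariant: mask true iff |stat| exceeds the corrected
            # threshold (cluster masks obey a cluster-mass rule instead)
            expect = np.abs(self.observed_stat) > self.corrected_threshold
            if not np.array_equal(expect, self.significant_mask):
                raise ValueError("mask inconsistent with threshold")


def _contiguous_ranges(freq: np.ndarray, mask: np.ndarray) -> list[tuple[float, float]]:
    ranges = []
    i = 0
    while i < mask.size:
        if mask[i]:
            j = i
            while j + 1 < mask.size and mask[j + 1]:
                j += 1
            ranges.append((float(freq[i]), float(freq[j])))
            i = j + 1
        else:
            i += 1
    return ranges


def permutation_spectrum_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    freq_hz: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 10000,
    seed: Optional[int] = None,
    correction: str = "pixel",
) -> PermutationSpectrumResult:
    """Paired, frequency-wise permutation test between two spectrum
    populations on a common grid.

    The per-frequency statistic is the mean paired difference
    ``mean(cond_a - cond_b)``. The null is built by random sign flips of
    each subject's difference spectrum — exhaustive (2^n) when
    n <= 12, Monte Carlo with ``n_perm`` draws otherwise. The corrected
    threshold is the (1 - alpha) quantile of the null max-|statistic|
    across frequencies (``correction="pixel"``); ``"cluster"`` instead
    thresholds at the per-frequency uncorrected quantile and compares
    cluster masses (sum of |statistic|) with the null max cluster mass.
    """
    a = np.atleast_2d(np.asarray(cond_a, dtype=float))
    b = np.atleast_2d(np.asarray(cond_b, dtype=float))
    freq_hz = np.asarray(freq_hz, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"condition shapes differ: {a.shape} vs {b.shape}")
    if a.shape[1] != freq_hz.size:
        raise ValueError("spectra and frequency grid have mismatched lengths")
    n, n_freq = a.shape
    if n < 2:
        raise ValueError("need at least 2 paired subjects")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; threshold will be unstable", RuntimeWarning)

    diffs = a - b
    observed = diffs.mean(axis=0)

    exhaustive = n <= EXHAUSTIVE_MAX_N
    if exhaustive:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))
        signs[0] = 1.0  # include the identity so the observed stat is in its own null
    null_stats = signs @ diffs / n  # (n_perm, n_freq)

    if correction == "pixel":
        null_max = np.abs(null_stats).max(axis=1)
        threshold = float(np.quantile(null_max, 1.0 - alpha, method="higher"))
        mask = np.abs(observed) > threshold
    elif correction == "cluster":
        form_thr = np.quantile(np.abs(null_stats), 1.0 - alpha, axis=0, method="higher")
        null_masses = np.empty(signs.shape[0])
        for i, row in enumerate(null_stats):
            masses = _cluster_masses(np.abs(row) > form_thr, np.abs(row))
            null_masses[i] = max(masses) if masses else 0.0
        mass_thr = float(np.quantile(null_masses, 1.0 - alpha, method="higher"))
        sup = np.abs(observed) > form_thr
        mask = np.zeros(n_freq, dtype=bool)
        i = 0
        while i < n_freq:
            if sup[i]:
                j = i
                while j + 1 < n_freq and sup[j + 1]:
                    j += 1
                if np.abs(observed[i : j + 1]).sum() > mass_thr:
                    mask[i : j + 1] = True
                i = j + 1
            else:
                i += 1
        threshold = mass_thr  # a cluster-mass threshold, not a per-bin one
    else:
        raise ValueError(f"unknown correction {correction!r}")

    return PermutationSpectrumResult(
        freq_hz=freq_hz,
        observed_stat=observed,
        corrected_threshold=threshold,
        significant_mask=mask,
        significant_ranges_hz=_contiguous_ranges(freq_hz, mask),
        n_permutations=int(signs.shape[0]),
        alpha=alpha,
        seed=seed,
        exhaustive=exhaustive,
        correction=correction,
    )


def _cluster_masses(sup: np.ndarray, absstat: np.ndarray) -> list[float]:
    masses = []
    i = 0
    while i < sup.size:
        if sup[i]:
            j = i
            while j + 1 < sup.size and sup[j + 1]:
                j += 1
            masses.append(float(absstat[i : j + 1].sum()))
            i = j + 1
        else:
            i += 1
    return masses
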