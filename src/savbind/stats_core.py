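"""Statistical kernel: Fisher's exact test, odds ratios, two-sample KS, bootstrap.

The four statistics used throughout the variant/interface enrichment analysis
are implemented here directly rather than delegated, so that their exact
conventions (two-sided tail definition, confidence-interval construction,
tie handling, resampling scheme) are pinned down and testable against
independent oracles:

* the two-sided Fisher p-value sums the hypergeometric mass of every table
  with the observed margins whose point probability does not exceed that of
  the observed table (the convention of R's ``fisher.test``), evaluated in
  log-space so that tables with cell counts in the tens of millions remain
  finite;
* the odds ratio is the *sample* odds ratio ``(n_cb/n_cn)/(n_rb/n_rn)``, not
  the conditional maximum-likelihood estimate, with a Woolf (log-OR) normal
  interval;
* the Kolmogorov–Smirnov D is the exact supremum of the ECDF difference over
  the pooled sample points (ties allowed — scores are bounded and discrete),
  with the asymptotic Kolmogorov p-value at effective size ``nm/(n+m)``;
* the bootstrap follows a subsampling scheme: ``n_replicates`` draws of a
  fixed fraction of the data *without replacement*, the standard error being
  the standard deviation of the replicate statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "KSResult",
    "BootstrapEstimate",
    "odds_ratio",
    "fisher_exact_two_sided",
    "or_confidence_interval",
    "enrichment_result",
    "ks_two_sample",
    "bootstrap",
    "Z_95",
    "MACHINE_EPS_P",
]

#: two-sided 97.5% normal quantile used for every 95% interval in the package
Z_95 = 1.959964

#: double-precision floor below which p-values are reported as "< 2.2e-16"
MACHINE_EPS_P = 2.220446e-16


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of (common/rare) x (binding/other) single amino-acid variants.

    Cells: ``n_cb`` common-binding, ``n_cn`` common-other, ``n_rb``
    rare-binding, ``n_rn`` rare-other.
    """

    n_cb: int
    n_cn: int
    n_rb: int
    n_rn: int

    def __post_init__(self) -> None:
        for name in ("n_cb", "n_cn", "n_rb", "n_rn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.n_cb + self.n_cn + self.n_rb + self.n_rn

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_cb, self.n_cn, self.n_rb, self.n_rn)

    def scaled(self, k: int) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.n_cb * k, self.n_cn * k, self.n_rb * k, self.n_rn * k)


@dataclass(frozen=True)
class EnrichmentResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class KSResult:
    """Two-sample KS outcome.

    ``d_signed`` is the (signed) ECDF difference ``ECDF_a - ECDF_b`` at the
    point where its absolute value is maximal: negative when sample *a* is
    shifted toward higher values than *b*.
    """

    d_statistic: float
    p_value: float
    d_signed: float

    @property
    def below_machine_eps(self) -> bool:
        return self.p_value < MACHINE_EPS_P


@dataclass(frozen=True)
class BootstrapEstimate:
    point: float
    std_error: float
    ci_low: float
    ci_high: float
    n_replicates: int
    n_dropped: int = 0


def odds_ratio(t: ContingencyTable2x2) -> float:
    """Sample odds ratio ``(n_cb/n_cn) / (n_rb/n_rn)``.

    Raises ``ZeroDivisionError`` naming the offending margin when a
    denominator cell is zero.
    """
    for name in ("n_cn", "n_rn", "n_rb"):
        if getattr(t, name) == 0:
            raise ZeroDivisionError(f"odds ratio undefined: margin {name} is zero")
    return (t.n_cb / t.n_cn) / (t.n_rb / t.n_rn)


def _log_binom(n: np.ndarray | float, k: np.ndarray | float) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(np.asarray(n) - np.asarray(k) + 1)


def fisher_exact_two_sided(t: ContingencyTable2x2, rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher exact p by hypergeometric probability ordering.

    Sums P(table) over all tables sharing the observed margins with
    ``P <= P_obs * (1 + rel_tol)`` — the relative tolerance mirrors the tie
    handling of R's ``fisher.test``. Computed entirely in log-space, so it
    stays finite for tables with totals of order 1e8.
    """
    a, b, c, d = t.as_tuple()
    n = t.total
    if n < 1:
        raise ValueError("contingency table is empty")
    row1 = a + b
    col1 = a + c
    amin = max(0, col1 - (n - row1))
    amax = min(row1, col1)
    ks = np.arange(amin, amax + 1)
    log_pmf = _log_binom(col1, ks) + _log_binom(n - col1, row1 - ks) - _log_binom(n, row1)
    log_obs = log_pmf[a - amin]
    mask = log_pmf <= log_obs + math.log1p(rel_tol)
    # renormalize by the total mass to cancel the common-mode rounding of the
    # log-gamma evaluations; the exact total is 1 by construction
    pmf = np.exp(log_pmf - log_pmf.max())
    p = float(pmf[mask].sum() / pmf.sum())
    return min(p, 1.0)


def or_confidence_interval(
    t: ContingencyTable2x2, level: float = 0.95, haldane: bool = False
) -> tuple[float, float]:
    """Woolf interval: ``exp(ln OR ± z * sqrt(sum of reciprocal cells))``.

    All four cells must be positive; with ``haldane=True`` the
    Haldane–Anscombe continuity correction (+0.5 to every cell) is applied
    instead of raising.
    """
    cells = [float(x) for x in t.as_tuple()]
    if any(x == 0 for x in cells):
        if not haldane:
            raise ValueError(
                "Woolf interval undefined for a zero cell; "
                "pass haldane=True for the +0.5 continuity correction"
            )
        cells = [x + 0.5 for x in cells]
    a, b, c, d = cells
    log_or = math.log((a / b) / (c / d))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    if level == 0.95:
        z = Z_95
    else:
        from scipy.stats import norm

        z = float(norm.ppf(0.5 + level / 2))
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def enrichment_result(t: ContingencyTable2x2, haldane: bool = False) -> EnrichmentResult:
    """Convenience bundle: sample OR, Woolf 95% CI and two-sided Fisher p."""
    lo, hi = or_confidence_interval(t, haldane=haldane)
    return EnrichmentResult(
        odds_ratio=odds_ratio(t),
        ci_low=lo,
        ci_high=hi,
        p_value=fisher_exact_two_sided(t),
    )


def _kolmogorov_sf(x: float) -> float:
    # survival function of the Kolmogorov distribution, Q(x) = 2 sum (-1)^{k-1} e^{-2k^2x^2};
    # for small x the dual Jacobi-theta series converges faster and is accurate
    if x <= 0:
        return 1.0
    if x < 1.0:
        # 1 - sqrt(2*pi)/x * sum_{k odd} exp(-k^2 pi^2 / (8 x^2))
        s = 0.0
        for k in range(1, 20, 2):
            term = math.exp(-(k * k) * math.pi * math.pi / (8 * x * x))
            s += term
            if term < 1e-300:
                break
        return min(1.0, max(0.0, 1.0 - math.sqrt(2 * math.pi) / x * s))
    s = 0.0
    for k in range(1, 201):
        term = (-1) ** (k - 1) * math.exp(-2.0 * k * k * x * x)
        s += term
        if abs(term) < 1e-300:
            break
    return min(1.0, max(0.0, 2.0 * s))


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> KSResult:
    """Exact two-sample KS D over the pooled sample points, asymptotic p.

    D is ``sup_t |ECDF_a(t) - ECDF_b(t)|`` evaluated at every distinct pooled
    value (sufficient for right-continuous step ECDFs, ties included). The
    p-value uses the Kolmogorov asymptotic distribution at effective size
    ``nm/(n+m)``; values underflow to 0.0 and callers may render them as
    "< 2.2e-16".
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    n, m = a.size, b.size
    if n == 0 or m == 0:
        raise ValueError("ks_two_sample requires non-empty samples")
    vals = np.unique(np.concatenate([a, b]))
    cdf_a = np.searchsorted(a, vals, side="right") / n
    cdf_b = np.searchsorted(b, vals, side="right") / m
    diff = cdf_a - cdf_b
    i = int(np.argmax(np.abs(diff)))
    d = float(abs(diff[i]))
    en = n * m / (n + m)
    p = _kolmogorov_sf(math.sqrt(en) * d)
    return KSResult(d_statistic=d, p_value=p, d_signed=float(diff[i]))


def _replicate_rng(seed: int, i: int) -> np.random.Generator:
    # counter-based substream: replicate i is reproducible regardless of how
    # many replicates are requested
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))


def bootstrap(
    metric: Callable,
    data,
    n_replicates: int = 1000,
    fraction: float = 0.5,
    seed: int = 0,
) -> BootstrapEstimate:
    """Subsampling bootstrap: ``n_replicates`` draws of ``fraction`` of the
    data without replacement; SE = std-dev of the replicate statistics.

    ``data`` may be a numpy array, a pandas Series/DataFrame (positional
    subsetting) or any sequence convertible to an array. A replicate on which
    ``metric`` raises is dropped (logged in ``n_dropped``); more than 10%
    drops is an error.
    """
    import pandas as pd

    n = len(data)
    if n < 2:
        raise ValueError("bootstrap requires at least 2 data items")
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    m = int(math.floor(fraction * n))
    if m < 1:
        raise ValueError("subsample size is zero; increase fraction or data size")

    if isinstance(data, (pd.Series, pd.DataFrame)):
        take = lambda idx: data.iloc[idx]  # noqa: E731
    else:
        data = np.asarray(data)
        take = lambda idx: data[idx]  # noqa: E731

    point = float(metric(data))
    values = []
    dropped = 0
    for i in range(n_replicates):
        rng = _replicate_rng(seed, i)
        idx = rng.choice(n, size=m, replace=False)
        try:
            values.append(float(metric(take(idx))))
        except Exception:
            dropped += 1
    if dropped > 0.1 * n_replicates:
        raise RuntimeError(
            f"bootstrap: {dropped}/{n_replicates} replicates failed (>10%)"
        )
    se = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    # replicate values that differ only by summation rounding are identical
    if se < 1e-13 * max(1.0, abs(point)):
        se = 0.0
    return BootstrapEstimate(
        point=point,
        std_error=se,
        ci_low=point - Z_95 * se,
        ci_high=point + Z_95 * se,
        n_replicates=len(values),
        n_dropped=dropped,
    )
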