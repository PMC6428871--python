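"""Degree-distribution classification: power law vs exponential vs Poisson.

The classification cascade operates on a vector of node degrees (zero-degree
nodes are excluded first — an unconnected clone carries no similarity
information):

1. Fit a discrete power law ``p(k) ∝ k^-alpha`` for ``k >= x_min``.  The
   lower threshold ``x_min`` minimizes the Kolmogorov–Smirnov distance
   between the empirical tail and the fitted model.  Inside the scan the
   exponent is estimated with the standard approximate discrete MLE,
   ``alpha = 1 + n [sum ln(x_i / (x_min - 1/2))]^-1``, constrained to the
   conventional discrete search range (default 1.5–3.5, the reference-
   implementation default; steeper decays are not meaningful power laws).
   The exponent *reported* for the chosen ``x_min`` is the exact discrete
   MLE (Hurwitz-zeta normalization) on that range.
2. Assess goodness of fit by a semi-parametric bootstrap: each replicate
   draws from the fitted power law above ``x_min`` and resamples the
   empirical body below it, refits from scratch with the identical scan,
   and compares KS statistics.  The p-value is the fraction of replicates
   whose KS statistic is at least the observed one; ``p >= 0.1`` accepts
   the power law.
3. Otherwise a Vuong-style normalized log-likelihood-ratio test compares a
   discrete exponential (geometric) and a truncated Poisson model on the
   same support.  A small two-sided p-value means the models are
   discriminable; the one-sided p-value is Phi(z) where z > 0 favours the
   exponential, so p ≈ 1 picks exponential and p ≈ 0 picks Poisson.

All randomness flows through explicit seeds; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

#: Minimal tail size and distinct-value count for a feasible power-law fit.
MIN_TAIL_SIZE = 4
MIN_DISTINCT = 2

#: Default exponent search range of the x_min scan (reference plfit default
#: for discrete data).
DEFAULT_ALPHA_RANGE = (1.5, 3.5)

_PMF_TABLE_MAX = 1 << 20  # cap on the exact inverse-CDF sampling table


class InfeasibleFitError(ValueError):
    """Degree data too degenerate for a tail fit (the 'NA' outcome)."""


def cumulative_distribution(degrees) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative degree distribution P_k = fraction of nodes with degree
    >= k, evaluated at every observed degree.  P at the minimum degree is 1
    and the sequence is non-increasing."""
    d = np.asarray(degrees, dtype=np.int64)
    if d.size == 0:
        raise ValueError("empty degree vector")
    if (d < 1).any():
        raise ValueError(
            "cumulative distribution expects positive degrees (zeros removed)"
        )
    ks, counts = np.unique(d, return_counts=True)
    below = np.concatenate([[0], np.cumsum(counts)[:-1]])
    pk = 1.0 - below / d.size
    return ks, pk


@dataclass(frozen=True)
class PowerLawFit:
    """Two channels of one discrete power-law fit.

    ``x_min``/``alpha`` are the reported parameters, from the canonical scan
    with the exact discrete MLE at every candidate threshold.  The
    goodness-of-fit channel (``gof_*`` and ``ks_statistic``) uses the fast
    approximate estimator instead — the bootstrap refits every synthetic
    replicate with that same estimator, so the observed KS statistic and its
    null distribution are computed by an identical procedure and the test
    stays calibrated.
    """

    x_min: int
    alpha: float          # exact discrete MLE at x_min (reported exponent)
    n_tail: int
    log_likelihood: float
    gof_x_min: int
    gof_alpha: float      # approximate estimate used by the bootstrap null
    gof_n_tail: int
    ks_statistic: float   # KS distance of the goodness-of-fit channel


def _exact_alpha_mle(
    tail_sum_log: float, n_tail: int, x_min: int, alpha_range: tuple[float, float]
) -> tuple[float, float]:
    """Exact discrete power-law MLE on [alpha_range]; returns (alpha, loglik)."""

    def negloglik(alpha: float) -> float:
        return n_tail * np.log(special.zeta(alpha, x_min)) + alpha * tail_sum_log

    res = optimize.minimize_scalar(
        negloglik, bounds=alpha_range, method="bounded", options={"xatol": 1e-6}
    )
    return float(res.x), -float(res.fun)


def _power_law_cdf(k: np.ndarray, alpha: float, x_min: int) -> np.ndarray:
    """CDF of the discrete power law at integer points k >= x_min."""
    return 1.0 - special.zeta(alpha, k + 1) / special.zeta(alpha, x_min)


def _scan(
    d_sorted: np.ndarray,
    alpha_range: tuple[float, float],
    estimator: str = "approximate",
) -> tuple[int, float, float, int] | None:
    """KS-minimizing x_min scan over the observed degree values.

    ``d_sorted`` must be sorted positive integers.  The per-candidate
    exponent comes either from the fast approximate discrete MLE
    (``estimator="approximate"``) or from the exact zeta-normalized MLE
    (``"exact"``), both constrained to ``alpha_range``.  Returns
    (x_min, alpha, ks, n_tail) or None when no candidate is feasible.
    """
    n = d_sorted.size
    uniq, counts = np.unique(d_sorted, return_counts=True)
    cum = np.cumsum(counts)                       # obs <= uniq[j]
    log_d = np.log(d_sorted)
    suffix_logsum = np.concatenate([np.cumsum(log_d[::-1])[::-1], [0.0]])
    starts = np.searchsorted(d_sorted, uniq, side="left")
    n_tails = n - starts
    with np.errstate(divide="ignore", invalid="ignore"):
        approx_alphas = 1.0 + n_tails / (
            suffix_logsum[starts] - n_tails * np.log(uniq - 0.5)
        )
    approx_alphas = np.clip(approx_alphas, alpha_range[0], alpha_range[1])
    best: tuple[int, float, float, int] | None = None
    n_uniq = uniq.size
    for i in range(n_uniq):
        n_tail = int(n_tails[i])
        if n_tail < MIN_TAIL_SIZE or (n_uniq - i) < MIN_DISTINCT:
            continue
        x_min = int(uniq[i])
        if estimator == "approximate":
            alpha = float(approx_alphas[i])
        else:
            alpha, _ = _exact_alpha_mle(
                float(suffix_logsum[starts[i]]), n_tail, x_min, alpha_range
            )
        if not np.isfinite(alpha):
            continue
        tail_vals = uniq[i:]
        below = cum[i - 1] if i else 0
        cdf_emp = (cum[i:] - below) / n_tail
        cdf_fit = _power_law_cdf(tail_vals, alpha, x_min)
        ks = float(np.abs(cdf_emp - cdf_fit).max())
        if best is None or ks < best[2]:
            best = (x_min, alpha, ks, n_tail)
    return best


def fit_power_law(
    degrees, alpha_range: tuple[float, float] = DEFAULT_ALPHA_RANGE
) -> PowerLawFit:
    """Discrete power-law fit with x_min chosen by KS minimization.

    Candidates are the observed degree values; a candidate is admissible
    only if its tail keeps at least ``MIN_TAIL_SIZE`` observations spanning
    at least ``MIN_DISTINCT`` distinct values.  Raises
    :class:`InfeasibleFitError` when no candidate qualifies.

    Two scans are run: the exact-MLE scan supplies the reported parameters
    (``x_min``, ``alpha``) and the approximate-estimator scan supplies the
    goodness-of-fit channel consumed by :func:`bootstrap_pvalue` (see
    :class:`PowerLawFit`).
    """
    d = np.asarray(degrees, dtype=np.int64)
    d = np.sort(d[d > 0])
    if d.size == 0:
        raise InfeasibleFitError("no positive degrees to fit")
    gof = _scan(d, alpha_range, estimator="approximate")
    if gof is None:
        raise InfeasibleFitError(
            f"power-law fit infeasible: need a tail of >= {MIN_TAIL_SIZE} points "
            f"with >= {MIN_DISTINCT} distinct degree values"
        )
    exact = _scan(d, alpha_range, estimator="exact")
    x_min, alpha, _, n_tail = exact
    start = np.searchsorted(d, x_min, side="left")
    _, loglik = _exact_alpha_mle(
        float(np.log(d[start:]).sum()), n_tail, x_min, alpha_range
    )
    gof_x_min, gof_alpha, gof_ks, gof_n_tail = gof
    return PowerLawFit(
        x_min=int(x_min),
        alpha=float(alpha),
        n_tail=int(n_tail),
        log_likelihood=float(loglik),
        gof_x_min=int(gof_x_min),
        gof_alpha=float(gof_alpha),
        gof_n_tail=int(gof_n_tail),
        ks_statistic=float(gof_ks),
    )


class _PowerLawSampler:
    """Exact inverse-CDF sampler for the discrete power law (CDF table up to
    ~1e6 above x_min; the negligible remaining mass falls back to the
    continuous-approximation transform)."""

    def __init__(self, alpha: float, x_min: int):
        self.alpha = float(alpha)
        self.x_min = int(x_min)
        ks = np.arange(x_min, x_min + _PMF_TABLE_MAX, dtype=np.float64)
        pmf = ks ** (-self.alpha) / special.zeta(self.alpha, self.x_min)
        self._cdf = np.cumsum(pmf)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random(size)
        idx = np.searchsorted(self._cdf, u, side="left")
        out = self.x_min + idx
        overflow = idx >= self._cdf.size
        if overflow.any():
            uo = u[overflow]
            out[overflow] = np.floor(
                (self.x_min - 0.5) * (1.0 - uo) ** (-1.0 / (self.alpha - 1.0)) + 0.5
            ).astype(np.int64)
        return out.astype(np.int64)


def sample_power_law(
    alpha: float, x_min: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``size`` values from the discrete power law p(k) ∝ k^-alpha,
    k >= x_min."""
    return _PowerLawSampler(alpha, x_min).sample(size, rng)


def bootstrap_pvalue(
    degrees,
    n_boot: int = 100,
    seed: int | np.random.Generator | None = None,
    fit: PowerLawFit | None = None,
    alpha_range: tuple[float, float] = DEFAULT_ALPHA_RANGE,
) -> tuple[float, PowerLawFit]:
    """Semi-parametric bootstrap goodness-of-fit p-value for the power law.

    Each replicate draws, for every observation, either from the fitted
    power law above x_min (with the empirical tail probability) or uniformly
    from the empirical body below x_min, then re-runs the x_min scan from
    scratch.  Returns (p, fit) where p is the fraction of replicates with a
    refitted KS statistic >= the observed one.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = np.asarray(degrees, dtype=np.int64)
    d = d[d > 0]
    if fit is None:
        fit = fit_power_law(d, alpha_range)
    sampler = _PowerLawSampler(fit.gof_alpha, fit.gof_x_min)
    body = d[d < fit.gof_x_min]
    p_tail = (d >= fit.gof_x_min).sum() / d.size
    n = d.size
    exceed = 0
    for _ in range(n_boot):
        n_t = int((rng.random(n) < p_tail).sum())
        parts = []
        if n_t:
            parts.append(sampler.sample(n_t, rng))
        if n - n_t:
            parts.append(rng.choice(body, size=n - n_t, replace=True))
        synth = np.sort(np.concatenate(parts))
        refit = _scan(synth, alpha_range)
        # a degenerate replicate cannot beat the observed fit
        ks_synth = refit[2] if refit is not None else np.inf
        if ks_synth >= fit.ks_statistic:
            exceed += 1
    return exceed / n_boot, fit


# ---------------------------------------------------------------------------
# Alternative discrete models on the same support k >= x_min


def _exponential_loglik(tail: np.ndarray, x_min: int) -> tuple[np.ndarray, float]:
    """Pointwise log-likelihood of the discrete exponential (geometric on
    the shifted support): p(k) = (1-q) q^(k - x_min).  The MLE is closed
    form: q = m / (1 + m) with m the mean excess over x_min.  Returns
    (per-point loglik, rate lambda = -log q)."""
    m = float(tail.mean() - x_min)
    if m <= 0:
        # all mass at x_min: degenerate, rate -> inf
        ll = np.where(tail == x_min, 0.0, -np.inf)
        return ll, np.inf
    q = m / (1.0 + m)
    ll = np.log1p(-q) + (tail - x_min) * np.log(q)
    return ll, float(-np.log(q))


def _poisson_loglik(tail: np.ndarray, x_min: int) -> tuple[np.ndarray, float]:
    """Pointwise log-likelihood of the Poisson truncated to k >= x_min,
    with the mean fitted by 1-d maximum likelihood."""
    kbar = float(tail.mean())

    def negloglik(mu: float) -> float:
        log_tail_mass = stats.poisson.logsf(x_min - 1, mu)
        return -float(
            (tail * np.log(mu) - mu - special.gammaln(tail + 1) - log_tail_mass).mean()
        )

    hi = max(3.0 * kbar, 10.0)
    res = optimize.minimize_scalar(
        negloglik, bounds=(1e-9, hi), method="bounded", options={"xatol": 1e-8}
    )
    mu = float(res.x)
    ll = (
        tail * np.log(mu)
        - mu
        - special.gammaln(tail + 1)
        - stats.poisson.logsf(x_min - 1, mu)
    )
    return ll, mu


@dataclass(frozen=True)
class ModelComparison:
    """Vuong-style normalized log-likelihood-ratio test between two fitted
    models on the same data.  z > 0 favours the first model."""

    z: float
    two_sided_p: float   # small => models discriminable
    one_sided_p: float   # Phi(z): ~1 => first model best, ~0 => second


def compare_exponential_poisson(
    tail, x_min: int
) -> tuple[ModelComparison, float, float]:
    """Fit exponential and Poisson on k >= x_min and compare likelihoods.

    Returns (comparison, exponential rate, Poisson mean).
    """
    tail = np.asarray(tail, dtype=np.int64)
    if tail.size < 2:
        raise InfeasibleFitError("model comparison needs >= 2 tail points")
    ll_exp, rate = _exponential_loglik(tail, x_min)
    ll_poi, mu = _poisson_loglik(tail, x_min)
    diff = ll_exp - ll_poi
    sd = diff.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        z = 0.0 if np.allclose(diff.sum(), 0) else float(np.sign(diff.sum()) * np.inf)
    else:
        z = float(diff.sum() / (sd * np.sqrt(tail.size)))
    two_sided = float(special.erfc(abs(z) / np.sqrt(2))) if np.isfinite(z) else 0.0
    one_sided = (
        float(stats.norm.cdf(z)) if np.isfinite(z) else (1.0 if z > 0 else 0.0)
    )
    return ModelComparison(z=z, two_sided_p=two_sided, one_sided_p=one_sided), rate, mu


@dataclass
class DegreeDistributionFit:
    """Outcome of the full classification cascade for one degree vector."""

    family: str                     # power_law | exponential | poisson | undetermined
    x_min: int
    alpha: float | None             # power-law exponent
    exponential_rate: float | None  # lambda in P(k) ~ e^(-lambda k)
    poisson_mean: float | None
    ks_statistic: float
    bootstrap_p: float
    comparison_two_sided_p: float | None
    comparison_one_sided_p: float | None
    n_excluded_zero_degree: int
    n_tail: int

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "x_min": self.x_min,
            "alpha": self.alpha,
            "exponential_rate": self.exponential_rate,
            "poisson_mean": self.poisson_mean,
            "ks_statistic": self.ks_statistic,
            "bootstrap_p": self.bootstrap_p,
            "comparison_two_sided_p": self.comparison_two_sided_p,
            "comparison_one_sided_p": self.comparison_one_sided_p,
            "n_excluded_zero_degree": self.n_excluded_zero_degree,
            "n_tail": self.n_tail,
        }


def classify_distribution(
    degrees,
    n_boot: int = 100,
    seed: int | np.random.Generator | None = None,
    power_law_threshold: float = 0.1,
    two_sided_threshold: float = 0.05,
    comparison_support: str = "xmin",
    alpha_range: tuple[float, float] = DEFAULT_ALPHA_RANGE,
) -> DegreeDistributionFit:
    """Classify a degree vector as power_law / exponential / poisson.

    Zero degrees are dropped first.  The power law wins when its bootstrap
    goodness-of-fit p-value reaches ``power_law_threshold``; otherwise the
    exponential-vs-Poisson likelihood-ratio test decides, with
    ``undetermined`` when the two models cannot be discriminated (two-sided
    p above ``two_sided_threshold``).

    ``comparison_support`` places the exponential/Poisson comparison either
    on the power-law tail k >= x_min (``"xmin"``, default, keeps the three
    models comparable) or on all positive degrees (``"full"``).
    """
    d = np.asarray(degrees, dtype=np.int64)
    n_zero = int((d == 0).sum())
    d = d[d > 0]
    if d.size == 0:
        raise InfeasibleFitError(
            "all degrees are zero; zero-degree nodes are excluded before fitting"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    boot_p, fit = bootstrap_pvalue(d, n_boot=n_boot, seed=rng, alpha_range=alpha_range)
    if boot_p >= power_law_threshold:
        return DegreeDistributionFit(
            family="power_law",
            x_min=fit.x_min,
            alpha=fit.alpha,
            exponential_rate=None,
            poisson_mean=None,
            ks_statistic=fit.ks_statistic,
            bootstrap_p=boot_p,
            comparison_two_sided_p=None,
            comparison_one_sided_p=None,
            n_excluded_zero_degree=n_zero,
            n_tail=fit.n_tail,
        )
    if comparison_support == "full":
        cmp_x_min = int(d.min())
    elif comparison_support == "xmin":
        # the tail on which the power law was tested (and just rejected)
        cmp_x_min = fit.gof_x_min
    else:
        raise ValueError(f"unknown comparison_support {comparison_support!r}")
    tail = d[d >= cmp_x_min]
    comp, rate, mu = compare_exponential_poisson(tail, cmp_x_min)
    if comp.two_sided_p < two_sided_threshold:
        family = "exponential" if comp.z > 0 else "poisson"
    else:
        family = "undetermined"
    return DegreeDistributionFit(
        family=family,
        x_min=cmp_x_min,
        alpha=fit.alpha,
        exponential_rate=rate,
        poisson_mean=mu,
        ks_statistic=fit.ks_statistic,
        bootstrap_p=boot_p,
        comparison_two_sided_p=comp.two_sided_p,
        comparison_one_sided_p=comp.one_sided_p,
        n_excluded_zero_degree=n_zero,
        n_tail=fit.n_tail,
    )
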