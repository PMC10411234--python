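"""Ideal-observer mathematics for 2-AFC realism evaluation.

The ideal observer computes the likelihood ratio Lambda = q2(f)/q1(f)
between the real-image class (H2) and the synthetic-image class (H1) and,
in a two-alternative forced-choice trial, declares the image with the
larger statistic to be real.  Its proportion of correct decisions equals
the area under its ROC curve.  The key quantitative link implemented here
is the approximation

    AUC ~= 1/2 + 1/2 * erf( sqrt(2 * D_B) ),

where D_B is the Bhattacharyya distance between the two image
distributions, obtained by truncating the Maclaurin expansion of the
likelihood-generating function at its value at the origin,
G(0) = 4 * D_B = -4 log <Lambda^(1/2)>_1.  The approximation is exact
whenever the log-likelihood ratio is Gaussian — in particular for
equal-covariance Gaussian classes — and its floor AUC = 0.5 at D_B = 0
means the synthetic distribution exactly matches the real one.

All likelihood ratios are computed and stored in log space; Lambda is
materialized only inside exp(lambda/2)-style reductions, because
image-scale densities underflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.special import erf

from .distributions import (
    BhattacharyyaResult,
    DensityModel,
    _bhattacharyya_from_lambda,
)
from .exceptions import (
    DomainError,
    EvaluationError,
    ParameterError,
    ShapeError,
)

__all__ = [
    "AUCResult",
    "log_likelihood_ratio",
    "ideal_statistic",
    "auc_2afc_mc",
    "auc_empirical_roc",
    "bhattacharyya_from_lr_samples",
    "auc_approx_from_db",
    "MomentIdentityReport",
    "moment_identity_check",
    "LambdaDensityReport",
    "lambda_density_identity_check",
]


@dataclass
class AUCResult:
    """AUC estimate with estimator provenance.

    ``estimator`` is one of ``two_afc_mc``, ``empirical_roc``,
    ``bhattacharyya_approx``.  Monte-Carlo estimators carry ``n_pairs``,
    ``mc_std_error`` and ``tie_fraction``; the Bhattacharyya-based
    approximation is deterministic and carries none of them.
    """

    auc: float
    estimator: str
    n_pairs: Optional[int] = None
    mc_std_error: Optional[float] = None
    tie_fraction: Optional[float] = None


def log_likelihood_ratio(
    q1: DensityModel, q2: DensityModel, x: np.ndarray
) -> Union[float, np.ndarray]:
    """lambda = log q2(x) - log q1(x), evaluated in log space.

    Accepts a single image vector (M,) or a batch (n, M).
    """
    if q1.dimension != q2.dimension:
        raise ShapeError(
            f"models have different dimensions: {q1.dimension} vs {q2.dimension}"
        )
    return np.asarray(q2.log_density(x)) - np.asarray(q1.log_density(x))


def ideal_statistic(q1: DensityModel, q2: DensityModel) -> Callable[[np.ndarray], np.ndarray]:
    """The ideal observer's test statistic theta(f) = lambda(f), vectorized.

    The returned callable maps a batch of image vectors (n, M) to (n,)
    log-likelihood-ratio values.
    """

    def statistic(x: np.ndarray) -> np.ndarray:
        return np.atleast_1d(log_likelihood_ratio(q1, q2, x))

    return statistic


def _rank_auc(scores_h1: np.ndarray, scores_h2: np.ndarray) -> tuple[float, float]:
    """Tie-corrected rank-sum AUC and tie fraction, O((n1+n2) log)."""
    from scipy.stats import rankdata

    n1, n2 = scores_h1.size, scores_h2.size
    ranks = rankdata(np.concatenate([scores_h1, scores_h2]))
    r2 = ranks[n1:].sum()
    auc = (r2 - n2 * (n2 + 1) / 2.0) / (n1 * n2)
    # tied cross-pairs: for each value shared by both arrays, c1*c2 pairs tie
    v1, c1 = np.unique(scores_h1, return_counts=True)
    v2, c2 = np.unique(scores_h2, return_counts=True)
    common, i1, i2 = np.intersect1d(v1, v2, return_indices=True)
    n_ties = int((c1[i1] * c2[i2]).sum())
    return float(auc), n_ties / (n1 * n2)


def _hanley_mcneil_se(auc: float, n1: int, n2: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n1 - 1) * (q1 - auc**2)
        + (n2 - 1) * (q2 - auc**2)
    ) / (n1 * n2)
    return float(np.sqrt(max(var, 0.0)))


def auc_2afc_mc(
    q1: DensityModel,
    q2: DensityModel,
    statistic: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    n_pairs: int = 10000,
    seed: int = 0,
    pairing: str = "cross",
    tie_break: str = "half",
) -> AUCResult:
    """Monte-Carlo 2-AFC AUC: Pr[theta(real) > theta(synthetic)].

    Draws ``n_pairs`` synthetic images from ``q1`` (H1) and ``n_pairs``
    real images from ``q2`` (H2), applies ``statistic`` (default: the
    ideal log-likelihood-ratio statistic) and scores comparisons with
    ties counted one half (step(0) := 1/2).

    ``pairing='cross'`` scores every synthetic-real combination via the
    tie-corrected rank-sum — the draws are exchangeable, so every
    pairing is a valid trial and the U-statistic form has lower variance;
    it also coincides exactly with :func:`auc_empirical_roc` on the same
    scores.  ``pairing='paired'`` scores only the ``n_pairs`` drawn
    couples, matching a physical trial sequence; with
    ``tie_break='random'`` tied couples are decided by a fair coin
    instead of scoring one half, emulating a forced choice.
    """
    if n_pairs < 1:
        raise ParameterError("n_pairs must be >= 1")
    if pairing not in ("cross", "paired"):
        raise ParameterError(f"unknown pairing {pairing!r}")
    if tie_break not in ("half", "random"):
        raise ParameterError(f"unknown tie_break {tie_break!r}")
    if pairing == "cross" and tie_break == "random":
        raise ParameterError("tie_break='random' applies to pairing='paired' only")
    if statistic is None:
        statistic = ideal_statistic(q1, q2)
    rng = np.random.default_rng(seed)
    xs = q1.sample(n_pairs, rng)
    xr = q2.sample(n_pairs, rng)
    ts = np.atleast_1d(np.asarray(statistic(xs), dtype=float))
    tr = np.atleast_1d(np.asarray(statistic(xr), dtype=float))
    for name, arr in (("H1", ts), ("H2", tr)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise EvaluationError(
                f"statistic returned a non-finite value for {name} sample index {bad[0]}"
            )
    if pairing == "cross":
        auc, tie_frac = _rank_auc(ts, tr)
        se = _hanley_mcneil_se(auc, n_pairs, n_pairs)
    else:
        diff = tr - ts
        ties = diff == 0
        wins = (diff > 0).astype(float)
        if tie_break == "half":
            wins[ties] = 0.5
        else:
            wins[ties] = rng.integers(0, 2, size=int(ties.sum())).astype(float)
        auc = float(wins.mean())
        tie_frac = float(ties.mean())
        se = float(np.sqrt(auc * (1.0 - auc) / n_pairs))
    return AUCResult(
        auc=float(auc),
        estimator="two_afc_mc",
        n_pairs=int(n_pairs),
        mc_std_error=se,
        tie_fraction=float(tie_frac),
    )


def auc_empirical_roc(
    scores_h1: Sequence[float], scores_h2: Sequence[float]
) -> AUCResult:
    """Rank-sum (Mann-Whitney) AUC with tie correction.

    auc = [#(pairs with s2 > s1) + 1/2 #(ties)] / (n1 * n2), computed by
    sorting rather than the O(n1*n2) double loop.
    """
    s1 = np.asarray(scores_h1, dtype=float)
    s2 = np.asarray(scores_h2, dtype=float)
    if s1.size == 0 or s2.size == 0:
        raise ParameterError("score sequences must be non-empty")
    auc, tie_frac = _rank_auc(s1, s2)
    return AUCResult(
        auc=auc,
        estimator="empirical_roc",
        n_pairs=int(s1.size * s2.size),
        mc_std_error=_hanley_mcneil_se(auc, s1.size, s2.size),
        tie_fraction=tie_frac,
    )


def bhattacharyya_from_lr_samples(lambda_h1: Sequence[float]) -> BhattacharyyaResult:
    """Bhattacharyya estimate from log-likelihood-ratio draws under H1.

    Uses BC = <Lambda^(1/2)>_1: the coefficient is the sample mean of
    exp(lambda/2), the distance is -log BC with a delta-method standard
    error, and g0 = 4 * distance.  A noisy estimate can exceed BC = 1;
    the result is flagged (``bc_exceeds_one``) when it does so by more
    than three standard errors.
    """
    return _bhattacharyya_from_lambda(np.asarray(lambda_h1, dtype=float))


def auc_approx_from_db(distance: float) -> float:
    """Ideal-observer AUC approximated from the Bhattacharyya distance.

    AUC = 1/2 + 1/2 erf(sqrt(2 * distance)); strictly increasing, with
    range [0.5, 1).  The floor 0.5 at distance 0 means the synthetic and
    real image distributions exactly match.
    """
    if distance < 0:
        raise DomainError(f"Bhattacharyya distance must be >= 0, got {distance}")
    return float(0.5 + 0.5 * erf(np.sqrt(2.0 * distance)))


# ---------------------------------------------------------------------------
# Derivation identities, testable by Monte Carlo
# ---------------------------------------------------------------------------

@dataclass
class MomentIdentityReport:
    """MC check of the moment identity <Lambda^k>_2 = <Lambda^(k+1)>_1."""

    k: int
    lhs: float          # <Lambda^k>_2
    lhs_std_error: float
    rhs: float          # <Lambda^(k+1)>_1
    rhs_std_error: float
    n: int
    agrees: bool        # within 3 combined standard errors


def moment_identity_check(
    q1: DensityModel, q2: DensityModel, k: int, n: int, seed: int
) -> MomentIdentityReport:
    """Estimate both sides of <Lambda^k>_2 = <Lambda^(k+1)>_1 by MC.

    Draws n samples under each hypothesis; moments are computed as
    exp(k*lambda) reductions in log space.
    """
    if k not in (0, 1, 2):
        raise ParameterError("k must be in {0, 1, 2}")
    if n < 1000:
        raise ParameterError("n must be >= 1000 for a meaningful MC check")
    rng = np.random.default_rng(seed)
    x1 = q1.sample(n, rng)
    x2 = q2.sample(n, rng)
    lam1 = np.atleast_1d(log_likelihood_ratio(q1, q2, x1))
    lam2 = np.atleast_1d(log_likelihood_ratio(q1, q2, x2))
    lhs_vals = np.exp(k * lam2)
    rhs_vals = np.exp((k + 1) * lam1)
    lhs, rhs = float(lhs_vals.mean()), float(rhs_vals.mean())
    lhs_se = float(lhs_vals.std(ddof=1) / np.sqrt(n))
    rhs_se = float(rhs_vals.std(ddof=1) / np.sqrt(n))
    combined = np.hypot(lhs_se, rhs_se)
    return MomentIdentityReport(
        k=k, lhs=lhs, lhs_std_error=lhs_se, rhs=rhs, rhs_std_error=rhs_se,
        n=n, agrees=bool(abs(lhs - rhs) <= 3.0 * combined),
    )


@dataclass
class LambdaDensityReport:
    """MC check of the density identity p2(lambda) = exp(lambda) p1(lambda).

    Per shared bin, ``mass_h2`` is the empirical probability of lambda|H2
    and ``mass_h1_weighted`` the exp(lambda)-weighted empirical mass of
    lambda|H1; both estimate the same integral of p2 over the bin.
    Bins with fewer than ``min_bin_count`` samples under either hypothesis
    (including empty bins) are flagged as sparse and reported rather than
    scored: the exp-weighted estimator is heavy-tailed there and its
    empirical standard error is unreliable.
    """

    bin_edges: np.ndarray
    mass_h2: np.ndarray
    mass_h1_weighted: np.ndarray
    discrepancy: np.ndarray
    tolerance: np.ndarray       # 3 combined standard errors per bin
    max_discrepancy: float      # over scored (non-sparse) bins
    n_sparse_bins: int
    sparse_bins: np.ndarray
    passes: bool


def lambda_density_identity_check(
    q1: DensityModel, q2: DensityModel, n: int, bins: int, seed: int,
    min_bin_count: int = 10,
) -> LambdaDensityReport:
    """Histogram comparison of lambda|H2 against exp(lambda)-weighted lambda|H1."""
    if n < 10000:
        raise ParameterError("n must be >= 10000")
    if bins < 10:
        raise ParameterError("bins must be >= 10")
    rng = np.random.default_rng(seed)
    lam1 = np.atleast_1d(log_likelihood_ratio(q1, q2, q1.sample(n, rng)))
    lam2 = np.atleast_1d(log_likelihood_ratio(q1, q2, q2.sample(n, rng)))
    lo = min(lam1.min(), lam2.min())
    hi = max(lam1.max(), lam2.max())
    if hi == lo:  # identical models: lambda is a point mass at 0
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, bins + 1)

    counts2, _ = np.histogram(lam2, bins=edges)
    mass_h2 = counts2 / n
    se2 = np.sqrt(mass_h2 * (1.0 - mass_h2) / n)

    w = np.exp(lam1)
    idx = np.clip(np.digitize(lam1, edges) - 1, 0, bins - 1)
    mass_h1w = np.zeros(bins)
    se1 = np.zeros(bins)
    for b in range(bins):
        contrib = np.where(idx == b, w, 0.0)
        mass_h1w[b] = contrib.mean()
        se1[b] = contrib.std(ddof=1) / np.sqrt(n)

    disc = np.abs(mass_h2 - mass_h1w)
    tol = 3.0 * np.hypot(se1, se2)
    counts1 = np.bincount(idx, minlength=bins)
    sparse = (counts2 < min_bin_count) | (counts1 < min_bin_count)
    ok = disc <= np.maximum(tol, 1e-12)
    scored = disc[~sparse]
    return LambdaDensityReport(
        bin_edges=edges,
        mass_h2=mass_h2,
        mass_h1_weighted=mass_h1w,
        discrepancy=disc,
        tolerance=tol,
        max_discrepancy=float(scored.max()) if scored.size else 0.0,
        n_sparse_bins=int(sparse.sum()),
        sparse_bins=sparse,
        passes=bool(np.all(ok | sparse)),
    )
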