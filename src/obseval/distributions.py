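"""Parametric probability models for real and synthetic image classes.

An image is treated as a flat M-dimensional vector of pixel values.  The
class of synthetic images is conventionally called H1 and the class of
real images H2; each is described by a :class:`DensityModel` supporting
sampling and log-density evaluation.  The distance between the two
classes is measured by the Bhattacharyya coefficient

    BC = integral of sqrt(q1(f) * q2(f)) df,   BC in (0, 1],

and the Bhattacharyya distance D_B = -log BC.  The likelihood-generating
function of the log-likelihood ratio, evaluated at the origin, equals
G(0) = 4 * D_B, which is the quantity that drives the ideal-observer AUC
approximation in :mod:`obseval.ideal_observer`.

Three families are provided: multivariate Gaussian, Gaussian mixture, and
independent per-pixel Poisson.  These cover the closed-form, quadrature,
and Monte-Carlo estimation paths and are sufficient for two-pixel
illustration studies and count-data (photon-limited) images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import integrate, stats
from scipy.special import logsumexp

from .exceptions import (
    DomainError,
    ParameterError,
    ShapeError,
    UnsupportedMethodError,
)

__all__ = [
    "DensityModel",
    "Gaussian",
    "GaussianMixture",
    "IndependentPoisson",
    "BhattacharyyaResult",
    "sample",
    "log_density",
    "bhattacharyya",
    "model_to_dict",
    "model_from_dict",
    "model_to_json",
    "model_from_json",
    "load_model",
    "save_model",
]


def _as_matrix(a, name: str) -> np.ndarray:
    m = np.asarray(a, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ParameterError(f"{name} must be a square matrix, got shape {m.shape}")
    return m


def _check_spd(cov: np.ndarray, name: str) -> np.ndarray:
    """Validate symmetric positive definiteness; return the Cholesky factor."""
    if not np.all(np.isfinite(cov)):
        raise ParameterError(f"{name} contains non-finite entries")
    if not np.allclose(cov, cov.T, rtol=0.0, atol=1e-12):
        raise ParameterError(f"{name} is not symmetric")
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ParameterError(f"{name} is not positive definite") from None


class DensityModel:
    """Abstract probability model q(f) over M-pixel image vectors."""

    family: str = ""

    @property
    def dimension(self) -> int:  # pragma: no cover - overridden
        raise NotImplementedError

    def sample(self, n: int, seed: Union[int, np.random.Generator]) -> np.ndarray:
        """Draw ``n`` image vectors; shape (n, M).

        Identical (seed, model, n) reproduces identical output bit-for-bit;
        the generator is an explicitly seeded PCG64 with no global state.
        """
        raise NotImplementedError

    def log_density(self, x: np.ndarray) -> Union[float, np.ndarray]:
        """log q(x) for one vector (M,) or a batch (n, M)."""
        raise NotImplementedError

    # first two moments, used to bound quadrature domains
    def mean_vector(self) -> np.ndarray:
        raise NotImplementedError

    def marginal_std(self) -> np.ndarray:
        raise NotImplementedError

    @property
    def is_discrete(self) -> bool:
        return False

    def _check_x(self, x: np.ndarray) -> tuple[np.ndarray, bool]:
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 1
        x = np.atleast_2d(x)
        if x.shape[-1] != self.dimension:
            raise ShapeError(
                f"input has dimension {x.shape[-1]}, model has dimension {self.dimension}"
            )
        return x, squeeze

    @staticmethod
    def _rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
        if isinstance(seed, np.random.Generator):
            return seed
        return np.random.default_rng(seed)


@dataclass
class Gaussian(DensityModel):
    """Multivariate normal q(f) = N(mean, cov)."""

    mean: np.ndarray
    cov: np.ndarray
    family: str = field(default="gaussian", init=False)

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        if self.mean.ndim != 1 or not np.all(np.isfinite(self.mean)):
            raise ParameterError("mean must be a finite 1-D vector")
        self.cov = _as_matrix(self.cov, "cov")
        if self.cov.shape[0] != self.mean.shape[0]:
            raise ParameterError(
                f"cov shape {self.cov.shape} incompatible with mean length {self.mean.shape[0]}"
            )
        self._chol = _check_spd(self.cov, "cov")

    @property
    def dimension(self) -> int:
        return self.mean.shape[0]

    def sample(self, n: int, seed: Union[int, np.random.Generator]) -> np.ndarray:
        if n < 1:
            raise ParameterError("n must be >= 1")
        rng = self._rng(seed)
        z = rng.standard_normal((n, self.dimension))
        return self.mean + z @ self._chol.T

    def log_density(self, x: np.ndarray) -> Union[float, np.ndarray]:
        x, squeeze = self._check_x(x)
        out = stats.multivariate_normal.logpdf(x, mean=self.mean, cov=self.cov)
        out = np.atleast_1d(out)
        return float(out[0]) if squeeze else out

    def mean_vector(self) -> np.ndarray:
        return self.mean

    def marginal_std(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


@dataclass
class GaussianMixture(DensityModel):
    """Finite mixture of Gaussians with weights summing to one."""

    weights: np.ndarray
    means: np.ndarray  # (k, M)
    covs: np.ndarray  # (k, M, M)
    family: str = field(default="gaussian_mixture", init=False)

    def __post_init__(self) -> None:
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covs = np.asarray(self.covs, dtype=float)
        if self.covs.ndim == 2:
            self.covs = self.covs[None, :, :]
        k = self.weights.shape[0]
        if np.any(self.weights < 0):
            raise ParameterError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ParameterError("weights must sum to 1 within 1e-12")
        if self.means.shape[0] != k or self.covs.shape[0] != k:
            raise ParameterError("weights, means, covs must share the component count")
        self._chols = np.empty_like(self.covs)
        for i in range(k):
            self._chols[i] = _check_spd(_as_matrix(self.covs[i], f"covs[{i}]"), f"covs[{i}]")

    @property
    def dimension(self) -> int:
        return self.means.shape[1]

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    def sample(self, n: int, seed: Union[int, np.random.Generator]) -> np.ndarray:
        if n < 1:
            raise ParameterError("n must be >= 1")
        rng = self._rng(seed)
        comps = rng.choice(self.n_components, size=n, p=self.weights)
        z = rng.standard_normal((n, self.dimension))
        out = self.means[comps] + np.einsum("nij,nj->ni", self._chols[comps], z)
        return out

    def log_density(self, x: np.ndarray) -> Union[float, np.ndarray]:
        x, squeeze = self._check_x(x)
        parts = np.empty((self.n_components, x.shape[0]))
        for i in range(self.n_components):
            parts[i] = np.atleast_1d(
                stats.multivariate_normal.logpdf(x, mean=self.means[i], cov=self.covs[i])
            )
        out = logsumexp(parts + np.log(self.weights)[:, None], axis=0)
        return float(out[0]) if squeeze else out

    def mean_vector(self) -> np.ndarray:
        return self.weights @ self.means

    def marginal_std(self) -> np.ndarray:
        mu = self.mean_vector()
        second = np.zeros(self.dimension)
        for w, m, c in zip(self.weights, self.means, self.covs):
            second += w * (np.diag(c) + m**2)
        return np.sqrt(second - mu**2)


@dataclass
class IndependentPoisson(DensityModel):
    """Independent Poisson counts per pixel (photon-limited imaging)."""

    rates: np.ndarray
    family: str = field(default="independent_poisson", init=False)

    def __post_init__(self) -> None:
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        if self.rates.ndim != 1 or not np.all(np.isfinite(self.rates)):
            raise ParameterError("rates must be a finite 1-D vector")
        if np.any(self.rates <= 0):
            raise ParameterError("rates must be strictly positive")

    @property
    def dimension(self) -> int:
        return self.rates.shape[0]

    @property
    def is_discrete(self) -> bool:
        return True

    def sample(self, n: int, seed: Union[int, np.random.Generator]) -> np.ndarray:
        if n < 1:
            raise ParameterError("n must be >= 1")
        rng = self._rng(seed)
        return rng.poisson(self.rates, size=(n, self.dimension)).astype(float)

    def log_density(self, x: np.ndarray) -> Union[float, np.ndarray]:
        x, squeeze = self._check_x(x)
        if np.any(x < 0) or np.any(x != np.floor(x)):
            raise DomainError("poisson log-density requires nonnegative integer counts")
        out = stats.poisson.logpmf(x, self.rates).sum(axis=-1)
        return float(out[0]) if squeeze else out

    def mean_vector(self) -> np.ndarray:
        return self.rates

    def marginal_std(self) -> np.ndarray:
        return np.sqrt(self.rates)


# ---------------------------------------------------------------------------
# Bhattacharyya machinery
# ---------------------------------------------------------------------------

@dataclass
class BhattacharyyaResult:
    """Overlap between two image-class models.

    ``coefficient`` is BC = integral sqrt(q1 q2); ``distance`` is
    D_B = -log BC; ``g0`` is the likelihood-generating function at the
    origin, G(0) = 4 D_B.  For ``sample_mc`` the fields carry Monte-Carlo
    uncertainty: ``mc_std_error`` is the delta-method standard error of the
    distance and ``coefficient_std_error`` that of the coefficient.  A
    sample estimate of BC can exceed 1 by chance; ``bc_exceeds_one`` is set
    when it does so by more than three standard errors, which indicates a
    mis-specified log-likelihood ratio or severe undersampling.
    """

    coefficient: float
    distance: float
    g0: float
    method: str
    mc_std_error: Optional[float] = None
    coefficient_std_error: Optional[float] = None
    n_samples: Optional[int] = None
    bc_exceeds_one: bool = False


def _bhattacharyya_from_lambda(lams: np.ndarray) -> BhattacharyyaResult:
    """BC estimated as the sample mean of exp(lambda/2), lambda drawn under H1.

    Uses the identity BC = <Lambda^(1/2)>_1.  Works entirely from
    log-likelihood-ratio values, so image-scale densities never underflow.
    """
    lams = np.asarray(lams, dtype=float)
    if lams.size == 0:
        raise ParameterError("lambda sample sequence must be non-empty")
    w = np.exp(0.5 * lams)
    bc = float(np.mean(w))
    n = int(lams.size)
    se_bc = float(np.std(w, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    flagged = bc > 1.0 + 3.0 * se_bc
    dist = -float(np.log(bc))
    se_dist = se_bc / bc
    return BhattacharyyaResult(
        coefficient=bc,
        distance=dist,
        g0=4.0 * dist,
        method="sample_mc",
        mc_std_error=se_dist,
        coefficient_std_error=se_bc,
        n_samples=n,
        bc_exceeds_one=bool(flagged),
    )


def _gaussian_closed_form(m1: Gaussian, m2: Gaussian) -> float:
    """Closed-form D_B for two Gaussians.

    D_B = 1/8 dmu' Sbar^-1 dmu + 1/2 log( det Sbar / sqrt(det S1 det S2) )
    with Sbar = (S1 + S2)/2.  Identical parameters give exactly 0.0.
    """
    dmu = m2.mean - m1.mean
    sbar = 0.5 * (m1.cov + m2.cov)
    term1 = 0.125 * float(dmu @ np.linalg.solve(sbar, dmu))
    s, ld_bar = np.linalg.slogdet(sbar)
    _, ld1 = np.linalg.slogdet(m1.cov)
    _, ld2 = np.linalg.slogdet(m2.cov)
    term2 = 0.5 * (ld_bar - 0.5 * (ld1 + ld2))
    return term1 + term2


_QUAD_SPAN = 10.0  # integration half-width in combined standard deviations
_QUAD_ATOL = 1e-10


def _quadrature_bc(m1: DensityModel, m2: DensityModel) -> float:
    """BC by adaptive quadrature (continuous, M <= 2) or lattice sum (Poisson)."""
    if m1.is_discrete != m2.is_discrete:
        raise UnsupportedMethodError(
            "quadrature requires both models continuous or both discrete"
        )
    mu1, mu2 = m1.mean_vector(), m2.mean_vector()
    sd1, sd2 = m1.marginal_std(), m2.marginal_std()
    lo = np.minimum(mu1 - _QUAD_SPAN * sd1, mu2 - _QUAD_SPAN * sd2)
    hi = np.maximum(mu1 + _QUAD_SPAN * sd1, mu2 + _QUAD_SPAN * sd2)

    if m1.is_discrete:
        # sum sqrt(p1 p2) over the integer lattice covering both supports
        axes = [np.arange(max(0, np.floor(l)), np.ceil(h) + 1) for l, h in zip(lo, hi)]
        grids = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([g.ravel() for g in grids], axis=-1)
        lp = 0.5 * (np.atleast_1d(m1.log_density(pts)) + np.atleast_1d(m2.log_density(pts)))
        return float(np.exp(logsumexp(lp)))

    def integrand1(x):
        v = np.array([x])
        return np.exp(0.5 * (m1.log_density(v) + m2.log_density(v)))

    if m1.dimension == 1:
        val, _ = integrate.quad(integrand1, lo[0], hi[0], epsabs=_QUAD_ATOL, limit=200)
        return float(val)

    def integrand2(y, x):
        v = np.array([x, y])
        return np.exp(0.5 * (m1.log_density(v) + m2.log_density(v)))

    val, _ = integrate.dblquad(
        integrand2, lo[0], hi[0], lo[1], hi[1], epsabs=_QUAD_ATOL
    )
    return float(val)


def bhattacharyya(
    model1: DensityModel,
    model2: DensityModel,
    method: str = "closed_form",
    n_samples: Optional[int] = None,
    seed: Optional[int] = None,
) -> BhattacharyyaResult:
    """Bhattacharyya coefficient/distance between two models.

    Parameters
    ----------
    method
        ``closed_form`` — Gaussian/Gaussian only, exact.
        ``quadrature`` — dimension M <= 2; adaptive integration over
        +/- 10 combined standard deviations per axis (lattice summation
        for Poisson models).
        ``sample_mc`` — any family; Monte-Carlo mean of exp(lambda/2)
        with lambda drawn under model1 (H1); requires ``n_samples`` and
        ``seed`` and reports a standard error.
    """
    if model1.dimension != model2.dimension:
        raise ShapeError(
            f"models have different dimensions: {model1.dimension} vs {model2.dimension}"
        )
    if method == "closed_form":
        if not (isinstance(model1, Gaussian) and isinstance(model2, Gaussian)):
            raise UnsupportedMethodError(
                "closed_form is only available for gaussian/gaussian pairs"
            )
        dist = _gaussian_closed_form(model1, model2)
        # guard tiny negative round-off
        if dist < 0 and dist > -1e-12:
            dist = 0.0
        return BhattacharyyaResult(
            coefficient=float(np.exp(-dist)), distance=dist, g0=4.0 * dist,
            method="closed_form",
        )
    if method == "quadrature":
        if model1.dimension > 2:
            raise ShapeError("quadrature supports dimension M <= 2 only")
        bc = _quadrature_bc(model1, model2)
        bc = min(bc, 1.0)
        dist = -float(np.log(bc))
        if dist < 0 and dist > -1e-12:
            dist = 0.0
        return BhattacharyyaResult(
            coefficient=bc, distance=dist, g0=4.0 * dist, method="quadrature"
        )
    if method == "sample_mc":
        if n_samples is None or seed is None:
            raise ParameterError("sample_mc requires n_samples and seed")
        x = model1.sample(n_samples, seed)
        lams = np.atleast_1d(model2.log_density(x)) - np.atleast_1d(model1.log_density(x))
        return _bhattacharyya_from_lambda(lams)
    raise UnsupportedMethodError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Module-level functional interface
# ---------------------------------------------------------------------------

def sample(model: DensityModel, n: int, seed: Union[int, np.random.Generator]) -> np.ndarray:
    """Draw ``n`` image vectors from ``model``; deterministic per seed."""
    return model.sample(n, seed)


def log_density(model: DensityModel, x: np.ndarray) -> Union[float, np.ndarray]:
    """Evaluate log q(x) under ``model``."""
    return model.log_density(x)


# ---------------------------------------------------------------------------
# JSON serialization: {family, dimension, parameters}, matrices row-major
# ---------------------------------------------------------------------------

def model_to_dict(model: DensityModel) -> dict:
    if isinstance(model, Gaussian):
        params = {"mean": model.mean.tolist(), "cov": model.cov.tolist()}
    elif isinstance(model, GaussianMixture):
        params = {
            "weights": model.weights.tolist(),
            "means": model.means.tolist(),
            "covs": model.covs.tolist(),
        }
    elif isinstance(model, IndependentPoisson):
        params = {"rates": model.rates.tolist()}
    else:
        raise ParameterError(f"cannot serialize model of type {type(model).__name__}")
    return {"family": model.family, "dimension": model.dimension, "parameters": params}


def model_from_dict(d: dict) -> DensityModel:
    family = d.get("family")
    params = d.get("parameters", {})
    if family == "gaussian":
        model: DensityModel = Gaussian(mean=params["mean"], cov=params["cov"])
    elif family == "gaussian_mixture":
        model = GaussianMixture(
            weights=params["weights"], means=params["means"], covs=params["covs"]
        )
    elif family == "independent_poisson":
        model = IndependentPoisson(rates=params["rates"])
    else:
        raise ParameterError(f"unknown model family {family!r}")
    if "dimension" in d and int(d["dimension"]) != model.dimension:
        raise ParameterError(
            f"declared dimension {d['dimension']} != parameter dimension {model.dimension}"
        )
    return model


def model_to_json(model: DensityModel) -> str:
    return json.dumps(model_to_dict(model), indent=2)


def model_from_json(text: str) -> DensityModel:
    return model_from_dict(json.loads(text))


def save_model(model: DensityModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(model_to_json(model))


def load_model(path) -> DensityModel:
    with open(path, "r", encoding="utf-8") as fh:
        return model_from_json(fh.read())
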