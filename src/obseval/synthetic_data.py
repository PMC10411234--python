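"""Generators for every input the evaluation machinery consumes.

Three families of fixtures:

* two-pixel Gaussian image pairs — the minimal setting in which the
  relationship between the Bhattacharyya distance of the two image
  classes and the ideal-observer AUC can be visualized and checked
  against closed forms;
* small 2D lesion-phantom image pairs (warm elliptical background,
  disk lesions, Gaussian blur, Poisson noise) — a deliberately simple
  emission-tomography-like generator whose ``realism_gap`` knob shifts
  the synthetic arm away from the real arm, so realism-evaluation
  pipelines can be exercised end to end without clinical data;
* virtual readers — stochastic or exact-count response-log generators
  standing in for human observers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from . import distributions as dists
from .distributions import BhattacharyyaResult, Gaussian
from .exceptions import ParameterError, StudyError
from .ideal_observer import AUCResult, auc_approx_from_db
from .two_afc import ResponseRecord, TrialPair

__all__ = [
    "TwoPixelSpec",
    "TwoPixelDataset",
    "two_pixel_dataset",
    "two_pixel_sweep",
    "PhantomSpec",
    "phantom_pairs",
    "VirtualReaderSpec",
    "virtual_reader_log",
    "reader_accuracy_logs",
    "pooled_outcome_logs",
    "make_dummy_session",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# Two-pixel Gaussian illustration
# ---------------------------------------------------------------------------

@dataclass
class TwoPixelSpec:
    """Two-pixel image classes: N(mu1, sigma) synthetic vs N(mu2, sigma) real."""

    mu1: np.ndarray
    mu2: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu1 = np.asarray(self.mu1, dtype=float)
        self.mu2 = np.asarray(self.mu2, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu1.shape != (2,) or self.mu2.shape != (2,):
            raise ParameterError("mu1 and mu2 must be 2-vectors")
        if self.sigma.shape != (2, 2):
            raise ParameterError("sigma must be a 2x2 matrix")

    def models(self) -> tuple[Gaussian, Gaussian]:
        return Gaussian(self.mu1, self.sigma), Gaussian(self.mu2, self.sigma)


@dataclass
class TwoPixelDataset:
    samples_synthetic: np.ndarray  # (n, 2), drawn from H1
    samples_real: np.ndarray       # (n, 2), drawn from H2
    bhattacharyya: BhattacharyyaResult
    auc_approx: AUCResult


def two_pixel_dataset(spec: TwoPixelSpec, n_per_class: int, seed: int) -> TwoPixelDataset:
    """Draw both two-pixel classes and attach the exact distance and AUC.

    Delegates all math to the distributions and ideal-observer modules:
    closed-form Bhattacharyya distance for the shared-covariance Gaussian
    pair, and the erf-based AUC approximation (exact in this family).
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    q1, q2 = spec.models()
    rng = np.random.default_rng(seed)
    xs = q1.sample(n_per_class, rng)
    xr = q2.sample(n_per_class, rng)
    bc = dists.bhattacharyya(q1, q2, method="closed_form")
    auc = AUCResult(auc=auc_approx_from_db(bc.distance), estimator="bhattacharyya_approx")
    return TwoPixelDataset(
        samples_synthetic=xs, samples_real=xr, bhattacharyya=bc, auc_approx=auc
    )


def two_pixel_sweep(
    separations: Sequence[float],
    sigma: Optional[np.ndarray] = None,
    direction: Optional[np.ndarray] = None,
) -> list[tuple[float, float]]:
    """(Bhattacharyya coefficient, AUC) curve as the class means converge.

    Moves mu2 away from mu1 = 0 along ``direction`` by each separation;
    as the separation shrinks the coefficient rises to 1 and the AUC
    falls to its floor of 0.5.
    """
    sigma = np.eye(2) if sigma is None else np.asarray(sigma, dtype=float)
    direction = np.array([1.0, 0.0]) if direction is None else np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    out = []
    for s in separations:
        spec = TwoPixelSpec(mu1=np.zeros(2), mu2=s * direction, sigma=sigma)
        q1, q2 = spec.models()
        bc = dists.bhattacharyya(q1, q2, method="closed_form")
        out.append((bc.coefficient, auc_approx_from_db(bc.distance)))
    return out


# ---------------------------------------------------------------------------
# Lesion phantom pairs
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Simplified emission-phantom generator parameters.

    Each image is an elliptical warm background (mean ``background_activity``
    counts per pixel inside the ellipse) with randomly placed disk lesions
    of sampled radius and contrast, blurred by a Gaussian point-spread
    function of the given FWHM (reflective boundaries), then corrupted by
    per-pixel Poisson noise.  ``realism_gap`` = 0 makes the "real" and
    "synthetic" arms draws from one generative process; larger values
    scale the synthetic arm's background activity and lesion contrast by
    (1 + realism_gap), making the arms separable.
    """

    image_size: tuple = (64, 64)
    background_activity: float = 50.0
    lesion_count_range: tuple = (1, 3)
    lesion_radius_range: tuple = (3.0, 6.0)
    lesion_contrast_range: tuple = (2.0, 4.0)
    psf_fwhm: float = 2.0
    realism_gap: float = 0.0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ParameterError("image_size must be at least 8x8")
        if self.background_activity <= 0:
            raise ParameterError("background_activity must be > 0")
        if self.realism_gap < 0:
            raise ParameterError("realism_gap must be >= 0")
        if self.lesion_contrast_range[0] < 1.0:
            raise ParameterError("lesion contrast must be > 1 (warm lesions)")
        if 2.0 * self.lesion_radius_range[1] >= min(h, w):
            raise ParameterError("lesion radius too large for the image size")


def _render_phantom(
    spec: PhantomSpec, rng: np.random.Generator, background: float, contrast_scale: float
) -> tuple[np.ndarray, dict]:
    h, w = spec.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay, ax = 0.42 * h, 0.42 * w
    yy, xx = np.mgrid[0:h, 0:w]
    inside = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    activity = np.where(inside, background, 0.05 * background)

    n_lesions = int(rng.integers(spec.lesion_count_range[0], spec.lesion_count_range[1] + 1))
    lesions = []
    placed = 0
    attempts = 0
    while placed < n_lesions and attempts < 200:
        attempts += 1
        r = float(rng.uniform(*spec.lesion_radius_range))
        ly = float(rng.uniform(0, h - 1))
        lx = float(rng.uniform(0, w - 1))
        # reject lesions crossing the background-ellipse boundary
        margin = ((ly - cy) / (ay - r)) ** 2 + ((lx - cx) / (ax - r)) ** 2
        if ay - r <= 0 or ax - r <= 0 or margin > 1.0:
            continue
        contrast = float(rng.uniform(*spec.lesion_contrast_range)) * contrast_scale
        disk = (yy - ly) ** 2 + (xx - lx) ** 2 <= r**2
        activity = np.where(disk, background * contrast, activity)
        lesions.append({"y": ly, "x": lx, "radius": r, "contrast": contrast})
        placed += 1

    sigma = spec.psf_fwhm * _FWHM_TO_SIGMA
    blurred = gaussian_filter(activity, sigma=sigma, mode="reflect")
    noisy = rng.poisson(blurred).astype(np.uint16)
    truth = {
        "background_activity": background,
        "lesions": lesions,
        "psf_fwhm": spec.psf_fwhm,
        "boundary_mode": "reflect",
    }
    return noisy, truth


def phantom_pairs(
    spec: PhantomSpec, n_pairs: int, seed: int, out_dir
) -> dict:
    """Generate paired phantom images and write them as 16-bit PNGs.

    Returns the manifest (also written to ``out_dir/manifest.json``):
    per-image ground-truth parameters, the spec echo, and the seed.
    Identical (spec, n_pairs, seed) reproduces byte-identical PNGs.
    """
    if n_pairs < 1:
        raise ParameterError("n_pairs must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    gap = 1.0 + spec.realism_gap
    entries = []
    for i in range(n_pairs):
        real_img, real_truth = _render_phantom(spec, rng, spec.background_activity, 1.0)
        syn_img, syn_truth = _render_phantom(
            spec, rng, spec.background_activity * gap, gap
        )
        real_path = out_dir / f"pair{i:04d}_real.png"
        syn_path = out_dir / f"pair{i:04d}_synthetic.png"
        Image.fromarray(real_img).save(real_path)
        Image.fromarray(syn_img).save(syn_path)
        entries.append(
            {
                "pair": i,
                "real": {"path": real_path.name, "truth": real_truth},
                "synthetic": {"path": syn_path.name, "truth": syn_truth},
            }
        )
    manifest = {
        "spec": asdict(spec),
        "seed": seed,
        "n_pairs": n_pairs,
        "pairs": entries,
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# Virtual readers
# ---------------------------------------------------------------------------

@dataclass
class VirtualReaderSpec:
    """Parametric stand-in for a human 2-AFC reader.

    In ``stochastic`` mode each trial is correct with probability
    ``accuracy`` and the confidence level is drawn from the matching
    conditional distribution.  In ``exact_counts`` mode the generated log
    reproduces target tallies exactly: ``round(accuracy * n)`` correct
    decisions, with per-confidence counts either given explicitly
    (``exact_confidence_correct`` / ``exact_confidence_incorrect``,
    length-5 count vectors) or apportioned from the conditional
    probabilities by largest remainder.
    """

    accuracy: float
    confidence_given_correct: np.ndarray = field(
        default_factory=lambda: np.array([0.1, 0.2, 0.3, 0.25, 0.15])
    )
    confidence_given_incorrect: np.ndarray = field(
        default_factory=lambda: np.array([0.2, 0.3, 0.25, 0.15, 0.1])
    )
    mode: str = "stochastic"
    exact_confidence_correct: Optional[Sequence[int]] = None
    exact_confidence_incorrect: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ParameterError("accuracy must lie in [0, 1]")
        if self.mode not in ("stochastic", "exact_counts"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        for name in ("confidence_given_correct", "confidence_given_incorrect"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (5,) or np.any(v < 0) or abs(v.sum() - 1.0) > 1e-12:
                raise ParameterError(
                    f"{name} must be a length-5 probability vector summing to 1"
                )
            setattr(self, name, v)


def _apportion(pmf: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder integer apportionment of ``total`` over a pmf."""
    raw = pmf * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def virtual_reader_log(
    spec: VirtualReaderSpec,
    session: Sequence[TrialPair],
    reader_id: str,
    seed: int,
) -> list[ResponseRecord]:
    """Generate one reader's response log for a session."""
    n = len(session)
    if n == 0:
        raise ParameterError("session must be non-empty")
    rng = np.random.default_rng(seed)
    if spec.mode == "stochastic":
        correct = rng.random(n) < spec.accuracy
        confs = np.where(
            correct,
            rng.choice(5, size=n, p=spec.confidence_given_correct) + 1,
            rng.choice(5, size=n, p=spec.confidence_given_incorrect) + 1,
        )
    else:
        n_correct = int(round(spec.accuracy * n))
        cc = (
            np.asarray(spec.exact_confidence_correct, dtype=int)
            if spec.exact_confidence_correct is not None
            else _apportion(spec.confidence_given_correct, n_correct)
        )
        ci = (
            np.asarray(spec.exact_confidence_incorrect, dtype=int)
            if spec.exact_confidence_incorrect is not None
            else _apportion(spec.confidence_given_incorrect, n - n_correct)
        )
        if cc.sum() != n_correct or ci.sum() != n - n_correct:
            raise StudyError(
                f"exact counts infeasible: need {n_correct} correct and "
                f"{n - n_correct} incorrect, got {int(cc.sum())} and {int(ci.sum())}"
            )
        correct = np.zeros(n, dtype=bool)
        correct[rng.permutation(n)[:n_correct]] = True
        confs = np.empty(n, dtype=int)
        conf_pool_c = np.repeat(np.arange(1, 6), cc)
        conf_pool_i = np.repeat(np.arange(1, 6), ci)
        confs[correct] = rng.permutation(conf_pool_c)
        confs[~correct] = rng.permutation(conf_pool_i)
    return [
        ResponseRecord(
            reader_id=reader_id,
            trial_id=t.trial_id,
            chose_real=bool(correct[i]),
            confidence=int(confs[i]),
        )
        for i, t in enumerate(session)
    ]


def make_dummy_session(n_trials: int, seed: int = 0) -> list[TrialPair]:
    """Session with placeholder image references, for log-only fixtures."""
    rng = np.random.default_rng(seed)
    coins = rng.integers(0, 2, size=n_trials).astype(bool)
    return [
        TrialPair(
            trial_id=i + 1,
            left_is_real=bool(coins[i]),
            synthetic_ref=f"synthetic_{i + 1:03d}.png",
            real_ref=f"real_{i + 1:03d}.png",
        )
        for i in range(n_trials)
    ]


# ---------------------------------------------------------------------------
# Worked-example study fixtures
# ---------------------------------------------------------------------------

def reader_accuracy_logs(seed: int = 0) -> tuple[list[TrialPair], list[ResponseRecord]]:
    """Six-reader, 50-trial fixture with per-reader accuracies of
    44, 58, 50, 58, 44 and 58 percent and median confidence levels
    2, 4, 2, 3, 4 and 4 — the outcome profile of a six-expert PET
    realism study.  All of a reader's confidences are set to the target
    median, which pins the (lower) median exactly."""
    session = make_dummy_session(50, seed=seed)
    corrects = [22, 29, 25, 29, 22, 29]
    medians = [2, 4, 2, 3, 4, 4]
    log: list[ResponseRecord] = []
    for j, (k, m) in enumerate(zip(corrects, medians)):
        cc = np.zeros(5, dtype=int)
        ci = np.zeros(5, dtype=int)
        cc[m - 1] = k
        ci[m - 1] = 50 - k
        spec = VirtualReaderSpec(
            accuracy=k / 50.0,
            mode="exact_counts",
            exact_confidence_correct=cc,
            exact_confidence_incorrect=ci,
        )
        log.extend(virtual_reader_log(spec, session, f"reader{j + 1}", seed=seed + 100 + j))
    return session, log


def pooled_outcome_logs(seed: int = 0) -> tuple[list[TrialPair], list[ResponseRecord]]:
    """Six-reader, 50-trial fixture whose pooled tallies are 164/300
    correct, 71 of the correct decisions at confidence >= 4, and 34 of
    the 136 incorrect decisions at confidence >= 4."""
    session = make_dummy_session(50, seed=seed)
    corrects = [28, 27, 27, 27, 27, 28]          # sums to 164
    high_correct = [12, 12, 12, 12, 12, 11]      # sums to 71, all at level 4
    high_incorrect = [6, 6, 6, 6, 5, 5]          # sums to 34, all at level 4
    log: list[ResponseRecord] = []
    for j in range(6):
        k, hc, hi = corrects[j], high_correct[j], high_incorrect[j]
        cc = np.array([0, k - hc, 0, hc, 0])
        ci = np.array([0, (50 - k) - hi, 0, hi, 0])
        spec = VirtualReaderSpec(
            accuracy=k / 50.0,
            mode="exact_counts",
            exact_confidence_correct=cc,
            exact_confidence_incorrect=ci,
        )
        log.extend(virtual_reader_log(spec, session, f"reader{j + 1}", seed=seed + 200 + j))
    return session, log
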