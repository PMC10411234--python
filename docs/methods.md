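# Methods

## Problem and model

Synthetic medical images are only useful for developing and evaluating
imaging methods if they are drawn from (approximately) the same
distribution as real clinical images. `obseval` quantifies that
similarity two ways: with an *ideal observer* — a numerical decision
strategy whose performance admits exact analysis — and with tooling for
*expert-human* two-alternative forced-choice (2-AFC) studies.

Write an M-pixel image as a vector **f**. Synthetic images are drawn
from q₁(**f**) (hypothesis H₁), real images from q₂(**f**) (H₂). In a
2-AFC trial the observer sees one draw from each, computes a test
statistic θ for both, and calls the larger one real; the probability of
a correct decision equals the observer's AUC. The ideal observer uses
θ = λ = log[q₂(**f**)/q₁(**f**)], the log-likelihood ratio, and
upper-bounds every other observer.

The central quantitative link: expanding the likelihood-generating
function G(β) of λ around the origin and keeping only G(0) gives

    AUC ≈ ½ + ½ erf( √(2 D_B(q₁, q₂)) ),

where D_B = −log BC is the Bhattacharyya distance and
BC = ∫√(q₁ q₂) the Bhattacharyya coefficient, using
G(0) = −4 log⟨Λ^½⟩₁ = 4 D_B. The approximation is *exact* whenever λ is
Gaussian — in particular for two Gaussian classes with a shared
covariance, where it reduces to Φ(d_A/√2) with
d_A² = Δμᵀ Σ⁻¹ Δμ (a ≤1e-12 identity asserted in the tests). Its floor,
AUC = 0.5 at D_B = 0, means the synthetic distribution exactly matches
the real one. The truncation drops higher derivatives G⁽ⁿ⁾(0); no
correction is applied. Instead the Monte-Carlo 2-AFC estimator serves as
the empirical oracle for the approximation gap (the unequal-covariance
tests probe it and stay within Monte-Carlo tolerance at the separations
exercised; no analytic bound on the gap is claimed).

## Estimators and numerical choices

**Log space throughout.** Densities of image-sized vectors underflow;
λ is always computed as a difference of log-densities and Λ is
materialized only inside reductions such as the BC estimator
mean(exp(λ/2)), whose standard error is propagated to the distance by
the delta method (se_D = se_BC / BC). A sample BC can exceed 1; the
result is flagged when it does so by more than 3 standard errors rather
than silently clamped.

**Bhattacharyya methods.** `closed_form` (Gaussian pairs) uses
D_B = ⅛ Δμᵀ Σ̄⁻¹ Δμ + ½ log(det Σ̄ / √(det Σ₁ det Σ₂)), Σ̄ = (Σ₁+Σ₂)/2,
via `slogdet`/`solve`; identical parameters give exactly 0.
`quadrature` (M ≤ 2) integrates √(q₁q₂) adaptively over ±10 combined
standard deviations per axis at absolute tolerance 1e-10; Poisson pairs
are summed over the corresponding integer lattice instead. Higher
dimensions use `sample_mc`.

**Tie handling and pairing.** step(0) := ½ — tied comparisons score one
half — so the Monte-Carlo 2-AFC estimator coincides with the
tie-corrected rank-sum (Mann–Whitney) AUC. The default MC estimator
scores *all* synthetic×real combinations of the drawn samples via ranks
(O(n log n)): the draws are i.i.d., so every pairing is a valid trial,
the U-statistic form has lower variance, and it equals the empirical ROC
AUC on the same scores exactly. `pairing="paired"` instead scores only
the n drawn couples — the physical trial sequence — and
`tie_break="random"` there resolves ties with a fair coin, emulating a
true forced choice (used for the matched-distribution chance-level
check, where λ ≡ 0 and every couple ties). Standard errors: binomial
√(p(1−p)/n) for paired; Hanley–McNeil for the rank form.

**Derivation identity checks.** Two consequences of the derivation are
testable by simulation and are exposed as report-producing operations:
the moment identity ⟨Λᵏ⟩₂ = ⟨Λᵏ⁺¹⟩₁ (k ≤ 2; both sides estimated under
their own hypotheses, agreement judged at 3 combined standard errors)
and the density identity p₂(λ) = e^λ p₁(λ) (shared-bin histogram of
λ|H₂ against the e^λ-weighted histogram of λ|H₁). In the density check,
bins receiving fewer than `min_bin_count` (default 10) samples under
either hypothesis are flagged as sparse and reported but not scored:
the e^λ-weighted estimator is heavy-tailed in the far tails and its
empirical standard error there is unreliable (often exactly zero),
which would turn an analytically true identity into false alarms.

**Uniform stochastic rule.** All Monte-Carlo acceptance comparisons use
a 3-standard-error band. Every random draw flows from an explicit
PCG64 generator (`numpy.random.default_rng(seed)`); there is no global
random state, and identical (model, n, seed) reproduces samples
bit-for-bit.

## 2-AFC study toolkit

Sessions are built from an investigator config (title, 4-digit
passcode, instructions, ordered image pairs, contact): an optional
seeded shuffle permutes pair order and a seeded fair coin places the
real image left or right per trial. Side randomization is standard
2-AFC hygiene — without it, position bias contaminates accuracy — and
the truth side is recorded per trial. Display conveniences of a reading
workstation (contrast, inversion, result delivery) are carried as
metadata only.

Scoring: per-reader percent accuracy (exact fraction retained; the
integer-rounded value is what study tables print), a 2×5 tally of
correct/incorrect decisions by confidence level 1–5, the *lower-median*
confidence (deterministic and integer-valued on a 5-point scale with
even counts), an exact two-sided binomial p-value against chance ½ and
a Clopper–Pearson 95% interval (exact machinery because typical
per-reader trial counts are ~50). Accuracy far below 50% usually means
an untrained or confused observer; summaries carry a flag when the CI
upper bound is below 0.5 instead of excluding data. Pooling sums counts
across readers and recomputes inference on the pooled counts as given —
it does not attempt to reconcile per-reader percentages with an
independently reported pooled count.

SUS questionnaires (10 items, 5 response levels) are scored with the
alternating rule — odd items map strongly-disagree→0 … strongly-agree→4,
even items the reverse — summed and multiplied by 2.5 onto 0–100.
Flip-symmetry (score + flipped-score = 100) and single-item
monotonicity are asserted as properties.

## Synthetic data: what it emulates, and what it does not

**Two-pixel Gaussian pairs** (shared covariance, different means) are
the minimal setting where every route to the AUC — closed form,
quadrature, MC sampling, and the erf approximation — can be compared;
the sweep helper traces (BC, AUC) as the means converge, showing the
monotone fall to the 0.5 floor.

**Lesion phantoms** stand in for an emission-tomography synthesis
pipeline: an elliptical warm background (default 64×64 px, 50 mean
counts/px inside the ellipse, 5% outside), 1–3 disk lesions of radius
3–6 px and contrast 2–4× placed fully inside the ellipse (placement
rejects boundary overlap; lesion–lesion overlap is allowed and fully
recorded in the manifest), a Gaussian PSF of FWHM 2 px with reflective
boundaries (avoids dark-frame artifacts in small images), then
per-pixel Poisson noise, written as 16-bit PNGs plus a ground-truth
JSON manifest. `realism_gap` scales the synthetic arm's background and
lesion contrast by (1+gap): gap = 0 makes the arms exchangeable draws
from one process (any fixed scalar statistic scores AUC ≈ 0.5), larger
gaps make them separable. These defaults are a deliberately simple,
photon-noise-dominated caricature: no anatomy, attenuation, scatter,
scanner geometry, or reconstruction. Passing tests therefore
demonstrate that the *evaluation machinery* behaves correctly on
distribution pairs with a controllable gap — not that any particular
clinical synthesis method is realistic.

**Virtual readers** generate response logs either stochastically
(per-trial correctness Bernoulli(accuracy), confidence from conditional
distributions over levels 1–5) or with exact counts (largest-remainder
apportionment, or explicit per-confidence count vectors) so that any
target tally — e.g. a six-reader study with pooled 164/300 correct —
can be reproduced exactly for worked examples. A virtual reader that
applies the likelihood-ratio rule per trial attains accuracy converging
to the ideal-observer AUC, which is the study-level counterpart of the
proportion-correct = AUC equivalence.

## Problem sizes

Default simulation sizes were chosen so every stochastic check has
comfortable resolution at the 3-SE rule: 10⁵ pairs for chance-level and
distance-recovery checks (binomial SE ≈ 0.0016), 2×10⁴–5×10⁴ pairs for
per-pair AUC comparisons, 10⁵ draws for the moment/density identities,
500 phantom pairs at 24×24 px for the exchangeability property, and
50-trial sessions (the conventional scale of an expert reading session)
for study fixtures.

## Known limitations

* Attaching an *empirical* image set to a `DensityModel` (density
  estimation from images) is intentionally out of scope; clinical image
  distributions have no known analytic form, and the package evaluates
  models, samples, or user-supplied scores instead.
* The erf approximation's error beyond the Gaussian-λ family is checked
  empirically, not bounded analytically.
* Quadrature is limited to M ≤ 2; higher dimensions rely on `sample_mc`
  whose error grows with the distance (exp(λ/2) becomes heavy-tailed
  when the classes are far apart).
* The 2-AFC toolkit is a local data model: no web hosting,
  authentication flows, or alternative designs (n-AFC, rating ROC).
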