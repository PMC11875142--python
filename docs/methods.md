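# Methods

This note documents the models, estimators and numerical choices behind
`fermstab`, and what the synthetic-data tests do and do not establish.

## Steady-state metrics

A chemostat at dilution rate `D` (h⁻¹) dilutes every extensive quantity at
rate `D`; at steady state the specific growth rate equals `D`. From window
averages of product titre `C_P`, dry-cell-weight biomass `C_X` and consumed
substrate `C_S = C_feed − C_residual` (all g L⁻¹) the five performance
parameters are

    q_P = C_P · D / C_X        specific productivity   (g g_DCW⁻¹ h⁻¹)
    q_S = C_S · D / C_X        specific uptake rate    (g g_DCW⁻¹ h⁻¹)
    Y_P/S = C_P / C_S,  Y_P/X = C_P / C_X,  Y_X/S = C_X / C_S

Both specific rates are normalised by biomass. This choice is forced by
unit consistency (the printed units of both rates are per g DCW) and by the
reference table itself, which satisfies `q_P = Y_P/X · D` row by row; it
also closes the algebra (`q_P/q_S = Y_P/S`, `Y_P/X · Y_X/S = Y_P/S`), which
the validator exploits. The validator checks those redundancies at the
table's printed precision by interval propagation (each printed value is
true ±half a printed unit), so rounding can never raise a false alarm; a
flat-tolerance check would misflag one marginal row (ratio off by 0.023)
besides the genuinely inconsistent one.

**Steady-state detection.** The stable production period is not defined
operationally in most fermentation reports. We use the earliest window of
3 residence times (3/D hours) in which both titre and biomass have a
coefficient of variation below 10%, extended while the criterion holds;
both thresholds are parameters. Stability duration is the last sampled
time minus the window start.

**Stability calls.** Patch plating of `n` colonies (default 50) onto
selective and non-selective media gives a binomial estimate of the
plasmid-bearing fraction with an exact Clopper–Pearson 95% interval.
Structural instability is inferred, not observed: a titre staying ≥20%
below the steady-state mean for at least one residence time while the
nearest plasmid-fraction observations are ≥0.9 is called structural; the
same drop with plasmid loss is segregational; with no plasmid observations
the call is indeterminate. The 20%/0.9 defaults are package choices (no
community standard exists) and are recorded in output metadata.

## PCA and clustering

The five parameters have incommensurate units, so the PCA operates on the
correlation structure: columns are z-scored (sample sd, ddof = 1) and the
sample correlation matrix is eigendecomposed (`numpy.linalg.eigh`).
Variance fractions are eigenvalues over the total (5). Eigenvector signs
are fixed by making each component's largest-magnitude loading positive,
so loadings are platform-reproducible. k-means (Lloyd's with k-means++
initialisation, 50 restarts, seeded, via scikit-learn) runs on the first
three component scores; with near-tied local optima the best-of-restarts
solution can depend on the seed, which is why the cluster-vs-condition
association is asserted distributionally over seeds in the tests.

## Linear regression

Stability duration is regressed on dilution rate, plasmid size and
temperature, all standardised (the response is back-transformed to hours
for reporting). The fit is ordinary least squares via `lstsq`, with a rank
check that names collinear predictor pairs. Contribution weights are
`|β_i| / Σ|β_j|` on the standardised scale.

Two 95% bands at significance level α = 0.05 are provided:

* `band="mean"` (default): the confidence band for the mean response,
  half-width `t_{1−α/2,dof} · RSE · sqrt(x'(X'X)⁻¹x)`. With the weak fits
  this data supports (R² ≈ 0.2), this band spans roughly 150–250 h and most
  held-out observations fall outside it — the diagnostic that the three
  design factors cannot explain stability duration.
* `band="constant"`: half-width `t_{1−α/2,dof} · RSE`, independent of the
  query point. With a weak fit the constant band is ≈ ±2 response standard
  deviations and covers nearly everything; it is kept for its simple
  t-quantile arithmetic and for callers who want a prediction-scale band.

The 70/30 split uses banker's rounding of `n·fraction` (33 rows → 23
train / 10 test) and a seeded permutation. The printed coverage of any one
split is split-dependent; the package therefore reports the coverage
distribution over 100 seeded splits rather than a single number.

## RBF network with reliability detection

**Predictive model.** Inputs and response are standardised; the network is

    y(x) = b + Σ_h w_h · exp(−‖x − c_h‖² / (2σ_h²)),   h = 1..H  (default 3)

with centres `c_h` from seeded k-means (50 restarts) on the standardised
training inputs. Widths are `σ_h = 0.75 ×` the RMS distance of the node's
cluster members from its centre, floored at 0.1 standardised units. The
scale factor matters: widths of the order of the *between*-centre distances
(≈2–2.5 here) make every activation, and hence the membership density,
nearly flat across the whole operating envelope, and extrapolation becomes
undetectable; widths at ≈0.5–0.8 of the within-cluster spread resolve the
gaps in the training design while leaving the regression accurate. Output
weights and bias are linear least squares.

**Confidence limits** are node-local, in the spirit of networks that carry
their own local error statistics. With residuals `r_k`, activation mass
`n_h = Σ_k a_h(x_k)` and weighted error `SSE_h = Σ_k a_h(x_k) r_k²`,

    CL_h = t_{1−α/2, ν_h} · sqrt(SSE_h / (n_h − 1)),   ν_h = max(n_h − 1, 2)

and the half-width at a query is the activation-weighted mix
`Σ_h a_h CL_h / Σ_h a_h`. Using the node's own effective degrees of freedom
(rather than the global dof) widens bands over sparsely populated nodes;
Monte-Carlo calibration on homoscedastic synthetic data gives training-set
coverage ≈0.96 at α = 0.05.

**Membership density.** Per node over the `K` training inputs and per
query:

    ρ_h = (1/K) Σ_k a_h(x_k),        ρ(x) = Σ_h a_h(x)·ρ_h / Σ_h ρ_h

Both lie in [0, 1]; with one hidden node ρ(x) reduces to the activation
itself.

**Reliability model.** A second model predicts the training density and
carries its own confidence band; a query is *reliable* when its actual
density ρ(x) lies inside that band. A structural point dictates the
model's form: ρ(x) is an exact linear combination of the predictive
network's basis functions, so a least-squares RBF on the same basis
reproduces it with zero residual everywhere — zero-width bands centred on
the very quantity being checked, which can never flag anything. The
reliability model is therefore a *normalised* RBF (a Gaussian-kernel
weighted mean) with one kernel per training input, width 0.5× the parent
node's width:

    ρ̂(x) = Σ_k a_k(x)·ρ(x_k) / Σ_k a_k(x)

with node-local confidence half-widths `t_{1−α/2,dof} · max(s_k, 0.05)`
where `s_k` is the kernel-weighted dispersion of the training densities
about the smoothed surface, and dof is the predictive fit's residual dof.
The 0.05 floor (density units) prevents zero-width bands where replicate
runs share identical inputs. A query activating no kernel at all (numerical
underflow far outside the training support) is unreliable by definition.
Predictions can optionally be capped (default 500 h in the surface report,
the longest experiment the protocol supports).

On the packaged dataset this machinery reproduces the expected behaviour:
all training observations inside the band; queries at the three trained
conditions reliable; queries ≥5 °C or ≥0.05 h⁻¹ from every trained
condition flagged; and along plasmid size, reliable spans over the sampled
3,000–4,800 bp range and around the isolated 6,104 bp construct, with an
unreliable gap over the unsampled interior. The exact span edges depend on
the width constants and should be read qualitatively.

## Synthetic chemostat generator

The generator is a test harness, not a calibrated process model. Two
populations (plasmid-bearing `Xp`, plasmid-free `Xf`) grow Monod-limited on
a scarce feed nutrient (a phosphate proxy — glucose is fed in excess,
mirroring phosphate-limited operation at ≈1 g DCW L⁻¹); a fraction θ of
plasmid-bearing divisions yields plasmid-free offspring; product forms at
`q·Xp` and every species dilutes at `D`. Structural instability is a
seeded exponential onset time after which `q` drops stepwise (default
−70%; a gradual exponential mode exists). At 37 °C a slow sinusoid
(default period 90 h) modulates `q`, a phenomenological stand-in for the
long-period oscillations seen at that temperature — no mechanism is
claimed. Measurement noise is multiplicative unit-mean log-normal;
plasmid fractions can be observed through binomial patch plating.

Integration is fixed-step RK4 with step = sample interval / 10 (halving
the step changes sampled titres by <10⁻⁵ relative), chosen over adaptive
steppers for bitwise reproducibility under a seed. Closed-form fixed
points (`S* = K_s D/(μmax−D)`, `X* = Y(S_feed−S*)`, `P* = qX*/D`) serve as
oracles; sampled steady states match them to <1%.

`generate_steady_state_dataset` turns a design (condition × strain cells,
optionally with programmed expected stability, which sets the structural
event rate to its reciprocal) into a summary table by running the *same*
detection and metric code used on real data. A run whose collapse precedes
any steady window is recorded with zero stability rather than dropped —
dropping such runs censors short-stability cells asymmetrically across
dilution rates (the detection window is 3/D hours long) and biases
regression recovery studies. Simulated runs are likewise truncated a few
residence times after a collapse, as an operator would stop them. The
sign-recovery study uses effect sizes well separated from the exponential
onset noise (whose sd equals its mean); it demonstrates that the pipeline
recovers programmed signs, not that effects of any magnitude are
detectable.

What passing synthetic tests shows: the estimators, detectors and models
compute what they claim on data with the assumed structure. What it does
not show: that real fermentations follow Monod kinetics, that structural
decay is a single multiplicative event, or that the oscillation surrogate
captures the real 37 °C dynamics — cross-feeding between subpopulations
and mechanistic nutrient dynamics are deliberately out of scope.

## Problem sizes and seeds

All stochastic steps take explicit seeds (default 0) and record them in
output manifests. The resampling studies use 100 splits; Monte-Carlo
calibrations use 200–500 replicates; the sign-recovery study uses 200
seeded datasets of 60 runs at a 5 h sampling interval over a 900 h
horizon — sizes at which the checked quantities' Monte-Carlo error is
comfortably below the asserted margins.

## Known limitations

* The reliability decision compares the *actual* Eq.-type density at a
  query against the reliability band; comparing the reliability model's
  own prediction instead is meaningless under the exact-representation
  degeneracy above, which is why that variant is not offered.
* The RBF confidence combination is one defensible reading of
  local-error-based limits; no published closed form exists for this
  architecture, and the band edges (±200 h scale) should be read
  qualitatively.
* With three centres the k-means geometry follows the three operating
  conditions; the reliability surface along plasmid size is shaped by the
  kernel-per-training-point reliability model, not by the three predictive
  nodes.
* The packaged table's plasmid sizes for the two benchmark strains are the
  full vector sizes; regression weights involving plasmid size are
  sensitive to that convention (they carry no addiction-system gene, and
  assigning them size 0 shrinks the plasmid-size weight markedly).
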