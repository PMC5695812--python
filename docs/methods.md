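# Methods

## Inactivation mechanism

The package models two-step covalent inactivation: reversible association
(`K_I`, μM) followed by irreversible chemistry (`k_inact`, min⁻¹), with the
observed pseudo-first-order rate `kobs(I) = k_inact·I/(K_I + I)` and
residual activity `exp(−kobs·t)` after pre-incubation. Assumptions:

- Free inhibitor is in large excess over enzyme, so [I] is constant during
  pre-incubation (unless a scavenger is active, below).
- Dilution into the assay mix arrests inactivation instantaneously: the
  post-dilution inhibitor concentration is treated as negligible during the
  activity read. This mirrors the experimental design, which uses 3- to
  20-fold dilution precisely to stop the reaction, and avoids modeling a
  second inactivation phase whose contribution is second-order small.
- No reversibility of the covalent step and no enzyme recovery.

With a thiol scavenger (glutathione) present, free inhibitor decays as
`I(s) = I·exp(−k₂·[GSH]·s)` — pseudo-first-order because GSH is in vast
excess (mM vs μM); GSH depletion is ignored. The survival fraction is then
`exp(−k_inact·∫₀ᵗ I(s)/(K_I+I(s)) ds)`, evaluated with adaptive quadrature
(scipy `quad`, relative tolerance 1e-8). The integral has a closed form for
exponentially decaying I, which the test suite uses as an independent
oracle against the quadrature path. No literature value exists for the
GSH–electrophile second-order rate constant of this compound class in our
scope, so `k₂` is a free exploration parameter and deliberately carries no
reference value.

## Coupled-assay signal model

The activity readout is an NADPH-coupled spectrophotometric assay (0.2 mM
NADPH, 0.5 mM GSH, 2 U/ml coupling reductase, 0.1 mM cysteinyl-glutathione
disulfide substrate; defaults in `AssayMix`). Design choices:

- ε₃₄₀(NADPH) = 6220 M⁻¹cm⁻¹, the standard literature value; path length
  1 cm by default.
- The coupling reductase is in excess and never limiting; coupling is
  instantaneous and 1:1 (one NADPH per disulfide reduced), so the NADPH
  consumption rate equals the enzyme's operational activity (milliunits =
  nmol/min).
- A340 falls linearly until the limiting species (NADPH or the disulfide,
  whichever is smaller in moles) is exhausted, then stays flat apart from
  an optional blank drift; absorbance is clipped at zero. A curve that
  leaves the linear regime before its second sample point triggers
  `NonLinearCurveWarning`.
- No Michaelis–Menten treatment of the enzyme's ping-pong mechanism:
  activity is an operational rate, as in the assay's unit definition. No
  temperature dependence.

Rates are ordinary least-squares slopes of A340 vs time (a two-point curve
degenerates to the secant). Percent inhibition is
`100·(1 − (r_treated − r_blank)/(r_control − r_blank))`, unclipped — values
outside [0, 100] are meaningful diagnostics of noise and belong to the
reporting layer to clip.

## Parameter estimation

**Kitz–Wilson.** The default method is the double-reciprocal regression
(unweighted OLS of 1/y on 1/I; `k_inact = 1/intercept`,
`K_I = slope/intercept`), matching the linear-plot presentation convention
and its y-intercept interpretation. The literature is ambiguous about which
axes a "modified" plot uses (y vs I, or 1/y vs 1/I); both are available —
the reciprocal regression and the direct nonlinear hyperbola fit
(initialized from the reciprocal solution) — and agree to well under 0.1%
on noiseless data. The reciprocal transform is known to inflate the
influence of low-y noise: at 5% multiplicative activity noise over nine
concentrations the reciprocal estimator's median |relative error| on K_I is
roughly 19%, while the nonlinear estimator's is about 8% (and ~3% on
k_inact). The stochastic-quality checks therefore use the nonlinear
estimator; the reciprocal method remains the default for deterministic
plot-faithful analysis. Observations with `Et ≥ E0` transform to `y ≤ 0`,
which the hyperbola cannot produce; they are retained and flagged by
`kw_transform` but excluded from fits. `Et = 0` (infinite y) is rejected
with an error naming the observation. A non-positive reciprocal intercept
is reported as "no saturation detected" with NaN parameters rather than an
exception. Duplicate concentrations are legitimate replicates; an
all-identical design is an error.

**IC50.** The concentration–response model is log-linear
(`% = a + b·log10 I`), fitted by OLS over points inside a configurable
response window (default 10–90%) and inverted at 50%. A 4-parameter
logistic is deliberately out of scope: the log-linear relationship is the
model the assay design validates, and a 4PL's extra parameters are not
identifiable from the 6–8 point curves this workflow produces. The used
points must bracket 50% — extrapolated IC50s are refused, not silently
returned. The fit is covariant under concentration rescaling (IC50 rescales,
slope unchanged).

## Screening

Plates are 384-well (A1–P24). Scoring computes per-well slopes, averages
control and blank wells **within each plate** (plate-wise normalization is
robust to plate effects), and converts compound wells to percent
inhibition. Ranking at the reference concentration (default 40 μM) breaks
ties by the secondary concentration and then compound id, so output order
is deterministic. The hit threshold (≥50% at 40 μM) is advisory and
configurable: screening campaigns of this kind pick follow-ups by rank, and
the characterized lead showed ~50% inhibition near 32–40 μM, which
motivates the default. Slope scoring is the default; an endpoint mode
(first-vs-last read secant) is available for single-read workflows.

## Interactome triage

Input tables carry integer spectral counts for 2 treated and 2 control
replicates per protein (configurable prefixes `t_rep*`/`c_rep*`). The
upstream search-engine FDR filtering is a property of the input, not
recomputed; an `fdr_pass` column is honored when present. The filter keeps
proteins with mean treated counts ≥ 10 (boundary inclusive; control counts
not consulted), then ranks by `mean(treated)/max(mean(control), floor)`
descending. The control floor (1.0 count) resolves division by zero for
proteins absent in controls while keeping the ordering finite and monotone
in treated counts — the source procedure is silent on zero-control
proteins, so this is a package decision. Ties break by treated mean then
protein id; counts are averaged with equal weights and no cross-run
normalization. Panel flagging is case-insensitive substring matching by
default (exact-match option available) against a default panel of
glutaredoxin-1 and the NF-κB members p100, p105/p50, IKKβ and MyD88.

## Synthetic data

Generators are pure functions of (spec, seed). A global seed expands into
fixed per-generator substreams (numpy `SeedSequence` spawn keys), so adding
a generator never perturbs another's draws. Defaults:

- Activity and rate noise: multiplicative lognormal with CV 5% (mean-one
  factors), the standard model for positive-valued assay readouts whose
  published error bars give no explicit noise model. Additive Gaussian
  noise is available for per-read absorbance perturbations.
- Spectral counts: independent Poisson draws per replicate (the standard
  counting model); adducted proteins draw treated counts at λ_T, control
  at λ_C; decoys draw λ_C in both conditions. The benchmark setting
  (50 adducted + 450 decoys, λ_T = 30, λ_C = 3, 2+2 replicates) emulates a
  ~500-protein pulldown with strong enrichment.
- Screening library: 504 compounds, two concentrations (40/120 μM), 30 min
  pre-incubation. The potency background treats most library electrophiles
  as far weaker than an optimized lead: 80% effectively inactive
  (k_inact = 0) and the rest drawing lognormal parameters
  (K_I median 150 μM, geometric SD 2; k_inact median 0.02 min⁻¹, geometric
  SD 2.5). Planted compounds override the draw with exact parameters.
  Control wells run at 0.2 milliunits in 50 μl with reads every 4 min
  (6 reads), keeping curves in the linear regime.

What the generators do **not** emulate — and therefore what passing tests
cannot certify about real data: plate edge effects and liquid-handling
carryover, instrument drift and read-to-read correlation, spectral-count
saturation and shared-peptide protein inference, and any systematic (rather
than stochastic) deviation of real curves from the linear signal model.

## Mass arithmetic conventions

Atomic, proton and residue masses are pinned constants
(`covkit._masstables`); masses are plain sums with no electron-mass
correction anywhere, matching the "calcd" convention of small-molecule HRMS
reports (sodiated and protonated calcd values reproduce with neutral-atom
masses). A bare-proton carrier ("H+") is available for strict peptide m/z
arithmetic; it differs from the H-atom carrier by one electron mass
(~0.00055 Da), far below the 0.0005–0.5 Da tolerances relevant here. One
reference value in the synthesis record labels a neutral monoisotopic mass
(198.0560, C9H11N2OCl) as a sodiated ion; the number is the neutral mass
and is treated as such. Peptide modifications given as raw deltas are used
verbatim; formula deltas are evaluated under the requested mass-type. The
parent-ion m/z of the doubly modified active-site peptide is reported under
both monoisotopic (≈654.0) and average (≈654.5) conventions; the observed
654.3 lies between them and no attempt is made to force one convention to
match, since the observation's isotopologue/centroid convention is
unstated.

## Problem sizes

The simulation studies run at sizes chosen to estimate their quantities
stably while staying interactive: 200 replicates for the noisy-recovery
study (median errors are stable to ~1 point at this size), 100 replicates
for the count-table precision benchmark, and one full 504-compound,
3-plate screen per scenario.
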