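# Methods

## Gas model

All pressure→amount conversions use the ideal gas law, n = PV/RT, with
R = 8.314 J mol⁻¹ K⁻¹ and 1 bar = 10⁵ Pa. Two pressure conventions are
supported. The default, `paper_gauge`, feeds recorded gauge (relative)
pressures straight into the gas law; this is how lab pressure transducers
are commonly read and it makes the one-fifth residual rule hold exactly on
gauge values (2 bar from 10 bar, 10 bar from 50 bar). `absolute_corrected`
adds 1.013 bar first for physically exact work. No compressibility
correction is applied even at 50 bar: the mixture is H₂-rich (Z ≈ 1.02 at
50 bar, 65 °C), and the error is below the other uncertainties in the
chain. Water vapor is neglected by default; at thermophilic and
hyperthermophilic temperatures (80–98 °C) the vapor partial pressure is
not negligible in absolute terms, but the gauge-convention arithmetic the
one-fifth rule relies on does not include it either, so the default stays
off and exact work should pass an explicit temperature and convention.

Stoichiometry: 4 H₂ + CO₂ → CH₄ + 2 H₂O with water condensed means 5 mol
of gas become 1 per mol CH₄ formed — a net loss of 4 mol of gas. Hence
ξ = Δn/4, and turnover (fraction of supplied substrate converted) maps
linearly onto the relative pressure drop: X = (p₀ − p)/(4·f·p₀) where
f = min(x_H₂/4, x_CO₂) is the limiting-reagent extent per mole of
headspace (0.2 for the 4:1 mixture). The dissolved-H₂ fold change between
two operating pressures is the pressure ratio (Henry proportionality at
fixed composition and temperature): 5× for 10 vs 2 bar, 25× for 50 vs 2.

Temperatures: online reactor traces use the incubation temperature;
offline point measurements (bottles equilibrated to room temperature
before reading) default to 298.15 K.

## Pressure-trace kinetics

The chain is resample → differentiate → smooth → window → summarize.

- **Resampling**: linear interpolation onto a regular grid, default 0.5 h
  (raw 5-min logs are denser than the kinetics warrant).
- **Derivative**: central differences, one-sided at the ends. The choice
  is the standard second-order estimator; no Savitzky–Golay machinery is
  needed at this smoothness.
- **Smoothing**: centered moving average, default 5 points (2.5 h span),
  window shrinking symmetrically at the edges so length is preserved.
- **Active window**: x_start is the first up-crossing and x_end the last
  down-crossing of the smoothed MER at the threshold (default
  0.1 mmol L⁻¹ h⁻¹), linearly interpolated between grid points; a curve
  that starts or ends above the threshold uses the span boundary, and a
  curve that never crosses it raises a "no active phase" error (a strain
  that does not grow). The threshold semantics — a horizontal cut in rate
  units — is one reading of an ambiguous convention ("shifting the x-axis
  to low points of the curve"); it is a documented choice, not an inferred
  intent. Note that with realistic sensor noise (σ ≈ 0.02 bar) the noise
  floor of the smoothed MER is of order 0.2 mmol L⁻¹ h⁻¹, so the default
  threshold tends to open the window early; raise it for lag-phase-sensitive
  Δt estimates.
- **Summaries**: MER_global is the trapezoid integral of smoothed MER over
  [x_start, x_end] divided by Δt; MER_total the same over the whole span;
  MER_max and its time come from the smoothed curve (ties → earliest);
  k_min from the unsmoothed resampled trace. Turnover statistics use raw
  pressure extrema and are invariant to resampling and smoothing. The
  maximum turnover rate is the peak time-derivative of turnover expressed
  in percent per hour, treating percent as dimensionless — for a full
  conversion this makes (peak rate) × (conversion time) land near 100.
- **Full conversion** is declared when pressure reaches the stoichiometric
  residual within a 2% relative tolerance (the tolerance is a package
  choice; no published value exists).
- **Biomass increase rate** (per-interval mode, the default) averages
  OD_max·μᵢ/(ODᵢ·μ_average) with ODᵢ at the interval start. The printed
  formula pairs OD and μ ambiguously; the per-interval average is the
  reading consistent with "average value of all biomass increase rates",
  and a doubling series 0.1→0.2→0.4 at equal spacing evaluates to 3.0.
  Zero net growth (μ_average = 0) leaves the statistic undefined (NaN,
  flagged) rather than raising.

## RCB segmentation

A new cycle starts where pressure rises between consecutive samples by
more than `jump_fraction` (default 0.2) of the trace maximum — relative to
the scale so the same setting works at 2 and 50 bar — and above an
absolute sensor-noise bound (0.3 bar) so noise blips never split a cycle.
Samples strictly inside a multi-sample repressurization ramp are dropped:
keeping them would corrupt the next cycle's p₀ and violate the
no-intra-segment-rise precondition of the rate estimator. Cycles are
labelled RCB1…RCBn. Each cycle gets the full kinetics summary; a cycle
whose smoothed MER never exceeds the activity threshold is flagged
no-growth instead of erroring.

## Simulator

State (ξ, X): dξ/dt = q_max·X·V_liquid·p_H₂/(K_p + p_H₂) after a lag,
dX/dt = Y_x·(dξ/dt)/V_liquid, with p_H₂ from the species balance and gas
law. The Monod dependence is on the H₂ *partial pressure*, not a dissolved
concentration — this keeps the model closed without a gas–liquid transfer
submodel and is the model's main simplification; it also omits
thermodynamic limitation near equilibrium, product inhibition and pH
dynamics. Consequently, passing recovery tests shows the analysis chain is
unbiased for gas-limited Monod-shaped conversions with white sensor noise;
it does not certify behaviour on traces dominated by transfer limitation,
drift, or non-Gaussian sensor artifacts.

Integration is fixed-step RK4 (dt = 0.01 h) for cross-platform
reproducibility, with a periodic step-doubling error check that rejects
parameter sets whose local error exceeds 10⁻⁶ bar. Defaults emulate a
thermophilic hydrogenotroph at 10 bar in a 160 mL vessel with 60 mL
liquid at 65 °C: q_max = 60 mmol g⁻¹ h⁻¹, K_p = 0.5 bar, X₀ = 0.02 g
CDW L⁻¹, Y_x = 2.5 g CDW per mol CH₄ (μ ≈ 0.15 h⁻¹ at substrate
saturation, full conversion in ~27 h), lag 5 h, sensor noise σ = 0.02 bar,
5-min recording, OD/CDW factor 2.5. These are typical literature-scale
values for thermophilic *Methanothermobacter*-like cultures; any positive
values work for testing. RCB simulation carries biomass across cycles and
repressurizes once pressure is within 0.5% of the stoichiometric residual
— deliberately tighter than the 2% analysis tolerance, so that
full-conversion verdicts on simulated data are not decided by the sign of
a single noise sample. Recovery checks are run at these defaults, varying
only the seed; 20 traces per noise level with 48 h horizons keep the whole
suite fast while the estimates are already tight (peak-rate error ≤ ~3% at
σ = 0, ≤ ~5% at σ = 0.05 bar).

The screening fixture places k collinear cluster centroids along a random
sign pattern, with the extreme clusters separated by `separation`
noise-sd in *every* variable, plus a missing-at-random mask (at least one
observed cell per row and column). The alignment fixture builds a
reference with Tyr-Gly-Tyr at residues 444–446, applies per-class Y/F (or
gap) substitutions, sprinkles deletions at non-motif sites and inserts a
few columns that are gaps in the reference, so the residue-number→column
map is exercised nontrivially.

## Screening multivariate stage

Imputation is **regularized iterative PCA**: initialize missing cells with
column means, then alternate rank-`ncomp` SVD reconstruction (singular
values shrunk by the noise variance estimated from discarded components,
λ_k → λ_k − σ̂²) and re-substitution into missing cells only, until the
largest change on an imputed cell is below 10⁻⁶. The shrinkage is what
keeps the fit from chasing noise through the missing cells — the
unregularized variant oscillates on noisy cluster-structured data — while
on exactly low-rank data σ̂² ≈ 0 and the truth is recovered to numerical
precision. Observed entries are never altered.

Standardization is column-wise (x − mean)/sd with sample sd (ddof = 1)
over observed entries. PCA is an SVD of the centered matrix with a
deterministic sign convention (largest-magnitude loading per component
made positive). k-means runs on the first two components with 25 seeded
restarts (k defaults to 4; configurable, since no k is canonical), and
quality is reported as between-SS/total-SS in percent — stated explicitly
as that ratio, since "within cluster sum of squares accounted X%" phrasing
in the literature is usually this quantity. The decomposition
between + within = total is asserted on every run. ncomp for imputation
defaults to 2, matching the downstream two-component use.

## Motif scanning

Residue numbering follows the reference sequence's ungapped coordinates
(1-based): the k-th non-gap reference character anchors residue k to its
alignment column. Every sequence's characters at the mapped columns
444–446 are reported; classification is case-insensitive into YGY / FGY /
YGF / FGF, and anything else (gap, X, non-YF substitution, non-G at 445)
is "other/gapped". For sequences with long indels relative to the
reference only the reference-mapped columns are reported — no per-sequence
renumbering is attempted.

## Numerical conventions

Extrema ties break to the earliest timestamp. Floats in output tables are
rendered at 6 significant digits; row order is deterministic (vessel,
cycle, id), so identical inputs give byte-identical files. Duplicate
timestamps on ingest collapse to their mean with a logged warning. All
randomness — simulator noise, fixture generation, k-means restarts — flows
from explicit integer seeds.

## Known limitations

Real-gas behaviour, gas–liquid mass transfer, carbonate/pH speciation and
vapor-pressure corrections are out of scope. MER neglects dissolved gas
and biomass carbon sinks by construction. The active-window threshold is
noise-sensitive at its default. Cluster memberships of any particular
laboratory screening matrix are not reproduced here — the stage is
validated on generative ground truth, not on deposited data.
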