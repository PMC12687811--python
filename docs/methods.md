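# Methods

## Scope and model overview

`nadflux` analyses stable-isotope tracing of NAD+ metabolism in the mouse:
constant-rate intravenous infusion of a labeled precursor — uniformly
13C-labeled tryptophan ([U-13C11]-Trp, 1.25 nmol per g body weight per min)
or 2,4,5,6-deuterated nicotinamide ([2,4,5,6-2H]-NAM, 0.1 nmol/g/min) — for
20 h, long enough for serum and fast tissue pools to approach isotopic steady
state. Serum is sampled at 0, 15, 30 min, 1, 2, 6, 15 and 20 h; tissues and
gut-luminal contents at the end of the infusion. The package covers the
chain from raw isotopologue intensities to precursor-contribution estimates,
plus DSS-colitis disease-activity scoring and the group statistics used for
such designs.

## Atom maps and expected shifts

The pathway atlas encodes the de novo (kynurenine) route Trp → NFK → Kyn →
3HK → 3HAA → QUIN → NAD+, the salvage loop NAM → NAD+ → NAM, NAM methylation
to MeNAM, and the microbial Preiss-Handler branch NAM → NA → NAD+. Each
transition records the number of substrate atoms of each element the product
retains; expected isotopologue shifts are computed by graph walk, taking the
running minimum of the shift and the per-step retention. Carbon losses along
the kynurenine pathway (formate at the formamidase step, alanine at
kynureninase, CO2 at QPRT) give the canonical ladder M+11 → M+10 → M+7 → M+6
for the 13C-Trp tracer. The d4-NAM tracer's 4-position deuterium sits at the
redox-active site of the nicotinamide ring and is modeled as a deterministic
−1 applied exactly once, at the NAM → NAD+ incorporation transition: M+4 NAM
yields M+3 NAD+, and NAM recycled from NAD+ breakdown is M+3 and keeps its
remaining deuteria through further salvage rounds. Phosphorylated
intermediates (NMN, NaMN, NaAD) are lumped into the incorporation
transitions so the atlas contains exactly the species an LC-MS method
monitors.

Two deliberate choices:

* **Luminal NA.** The microbial NAM → NA deamidation step requires the
  label to have passed through NAD+ (`requires_prior_nad`). Biologically,
  NAM secreted into the gut lumen is host-recycled material — intact
  infusate (M+4) is not observed in luminal samples — so luminal NA appears
  only at M+3 in the d4-NAM arm.
* **3HAA.** Structurally, 3HAA retains 7 tracer carbons from U-13C-Trp and
  the atlas reports M+7. Because the metabolite is conventionally reported
  at M+6 in some workflows, `PathwayMap.overrides` lets a user pin a
  per-(tracer, metabolite) reported shift without touching the atom map.

## Natural-abundance and purity correction

The forward matrix column *j* is the raw distribution expected from a
species truly carrying *j* tracer atoms: each heavy position independently
retains its label with probability `purity` (default 0.99), and every light
tracer-element position is naturally heavy with the element's abundance
(13C 0.0107, 2H 0.000115 by default; configurable). In `high` resolution
mode (default, appropriate to ~180,000 resolving power where heteroatom
isotopologues are mass-resolved) only the tracer element is convolved;
`nominal` mode additionally convolves N, O (+1 and +2) and S over nominal
mass. Correction solves `A x = raw` by non-negative least squares and
renormalizes, so corrected fractions are non-negative by construction rather
than clamped; a relative fit residual above 1e-3 flags the record. The
forward convolution doubles as the independent oracle: `correct ∘ forward`
round-trips random MIDs up to C12/H12 to better than 1e-8.

## The synthetic-data generator

The simulator stands in for the study's animals. Kinetics are linear
first-order mass-isotopomer balances on a compartment graph (default: serum,
liver, colon, colon lumen), solved with BDF and the exact constant Jacobian
(atol 1e-10, rtol 1e-8). Pool sizes are constant because configurations are
balanced — an automatic balancer closes every pool with unlabeled
dietary/endogenous sources or excretion/consumption sinks, and `validate`
refuses unbalanced configs. Label states track (metabolite, shift,
redox-intact) so the single redox-deuterium loss composes correctly through
recycling loops. Linearity is justified by the trace-level doses; there is
no enzyme saturation.

The study reports no pool sizes or flux magnitudes, so preset magnitudes are
desk-scale choices fixed once: serum NAM 1 nmol/g with fast tissue exchange
(10 nmol/g/min to colon), colon NAD+ 100 nmol/g turning over at
1.0 nmol/g/min split 70% salvage / 30% de novo, liver NAD+ 300 nmol/g at
2.2 nmol/g/min (91% salvage), and a small host → lumen NAM transfer feeding
microbial NA production. These rates put colon NAD+ half-time near 70 min,
so 20 h of infusion reaches steady state, and keep a full simulation under
0.1 s. The `early_flare` and `active_flare` presets change only directions
anchored by the biology of DSS colitis: colonic NAD+ pool reduced (to 80 and
50 nmol/g), colonic salvage flux and NAD+ consumption raised, colonic de
novo throttled (the QPRT bottleneck), hepatic de novo raised, and the
circulating Kyn pool enlarged. Magnitudes of these changes are free
parameters recorded in the config, not calibrated claims.

The forward measurement model applies tracer impurity and natural-abundance
convolution (the same code path the correction inverts), scales by pool size,
and multiplies mean-one log-normal noise with a given CV (default 0.05);
all randomness flows from a single integer seed and outputs are
byte-reproducible. What the generator does **not** emulate: biological
between-animal variation beyond measurement noise, absolute quantification,
chromatographic artifacts, saturation, or compartment heterogeneity within
an organ — so passing recovery tests demonstrates correctness of the
estimator arithmetic under the stated kinetic model, not robustness to real
tissue data. One known departure from observation: because the simulator
moves whole pool compositions between compartments, a trace of intact M+4
NAM reaches the lumen, whereas measured luminal NAM is essentially all M+3
(the atlas-level `requires_prior_nad` rule captures the empirical pattern;
the kinetic model does not enforce it).

## Fractional labeling and contribution estimates

Corrected fractions are tidy per-(sample, metabolite, shift) rows; rows at
atlas-expected shifts are tagged. Serum plateau enrichment is the mean of
points at or after 900 min (the last two sampling times define the plateau,
matching the steady-state rationale of a 20-h infusion); a series is
"steady" when its last two points differ by < 0.05 absolute. Relative pool
sizes are summed isotopologue intensities (TIC) scaled to a control-group
mean of 1; the reference is recorded in the output metadata.

Contribution formulas, evaluated per animal with denominators from that
animal's serum plateau:

* NAM: `100 × NAD+(M+3) / [serum NAM(M+3) + NAM(M+4)]` — both infusate and
  recycled serum NAM salvage into M+3 NAD+;
* Trp: `100 × NAD+(M+6) / serum Trp(M+11)`.

Fractions (not concentrations) are used in both numerator and denominator,
making the estimates invariant to per-sample intensity scaling. NAM and Trp
percentages come from separate tracer arms (separate animals) and are never
forced to sum to 100; values above 100% are reported, not clipped. Two
systematic behaviours users should expect, both visible in the simulator:
recycling loops *deflate* the NAM estimate slightly below the instantaneous
salvage flux share when tissue NAM lags serum (colon reads ≈ 67–70% against
a configured 70%), and they *inflate* the Trp estimate far above the direct
de novo flux share because recycled NAM(M+6) re-enters NAD+ via salvage —
the estimator measures cumulative Trp-derived carbon, which is precisely why
a colon with no working QPRT can still show substantial "Trp contribution".
Luminal estimates use the serum denominator as well and are additionally
diluted by microbial de novo synthesis from carbohydrates.

## DAI scoring

Six components, each 0–5: weight-loss points binned from percent loss
(0; 1–5; 6–10; 11–19; 20–25; >25), plus observed ordinal scores for stool
consistency, bleeding, posture, activity and fur. Fractional weight-loss
percentages are rounded half-up to the integer grid before binning, which
covers every percentage with no gaps. The DAI is the plain sum (0–30); no
division by the number of parameters is applied. Group summaries are
per-day mean ± SEM.

## Statistics

Two groups: two-sided Mann-Whitney U, exact when both n ≤ 8 without ties,
otherwise the plain normal approximation with tie correction. The continuity
correction is deliberately omitted in the asymptotic branch: at n = 10 per
group it pushes the null rejection rate at α = 0.05 down to ≈ 0.040–0.044,
while the plain approximation sits at ≈ 0.047–0.055, closer to nominal.
Three or more groups: Kruskal-Wallis with tie correction, then Dunn's
pairwise z-tests on pooled mean ranks; Dunn p-values are reported both raw
and BH-adjusted because reporting conventions differ between tools.
Significance bands include the trend band: § < 0.1, * < 0.05, ** < 0.01,
*** < 0.001, **** < 0.0001. BH FDR adjustment is the standard step-up with
monotonicity enforcement. qPCR fold changes use 2^−ΔΔCt with a reference
gene (TBP in the study design this mirrors).

## Numerical choices and degenerate inputs

* ODE: BDF, atol 1e-10 / rtol 1e-8; unbalanced configs are refused, not
  repaired silently.
* NNLS correction: all-zero raw vectors raise ("empty measurement"); fit
  residuals flag rather than drop records.
* Zero contribution denominators yield NaN with a flag; single-animal groups
  yield NaN SEM with a flag.
* Enrichment series need ≥ 3 timepoints; shorter series raise.
* M+0 label states are canonicalized (the redox flag is meaningless without
  label), avoiding duplicate ODE states.
* Peak tables are validated row-by-row with 1-based line numbers in error
  messages; duplicate (sample, metabolite, isotopologue) keys and negative
  intensities are hard errors.

## Known limitations

Only nominal mass shifts are modeled (no position-specific isotopomers); the
indole branch of Trp metabolism is not in the atlas; rate constants are not
physiologically calibrated and luminal microbiology is a single lumped
conversion; absolute fluxes (nmol/g/min) are not estimated from
contributions; multi-tracer deconvolution within one animal is out of scope.
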