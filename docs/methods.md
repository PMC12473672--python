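# Methods

frondscape implements the quantitative workflow used to compare duckweed
(*Lemna gibba*) clones acclimated to two light regimes, together with a
synthetic-data generator that reproduces the study's measurement structure.
Because no raw dataset accompanies the workflow, every analysis stage is
validated by parameter recovery: the generators emit data with known ground
truth, and the analysis must get that truth back.

## Study design emulated by the generators

Four clones × two light levels (100 and 243 µmol photons m⁻² s⁻¹ under
continuous irradiation, i.e. 8.64 and 21.00 mol m⁻² d⁻¹ DLI), three vessels
per combination, the experiment repeated twice — so n = 6 vessels per cell
for growth, fluorescence and morphometric responses, and n = 4 samples per
cell for pigments. Trials run 7 days from a small inoculum.

The default clone set (`frondscape.params.default_clone_set`) encodes the
conditions the study reports: frond-number growth rates spanning
0.36–0.55 day⁻¹, with the slowest combination being the tetraploid clone
under low light and the fastest a diploid under high light; one clone with
no light response in growth rate; the tetraploid with the highest frond
mass-to-area ratio; under high light, Y(II) of 1 mm fronds in the
0.43–0.48 band rising to 0.54–0.56 at maturity; under low light 0.51–0.61
rising to 0.66–0.68. Values the study does not print (pigment
concentrations, colony-size means, RLC truth per clone) were fixed once at
field-realistic magnitudes for *Lemna* cultures and are not tuned.

## Growth and morphometrics

RGR = (ln FN_t1 − ln FN_t0)/(t1 − t0) on frond counts; doubling time
ln 2/RGR; colony size FN/CN; senescence as the percentage of yellowing
fronds; frond area as the ellipse π·(L/2)·(W/2); roundness L/W;
DLI = PPFD·photoperiod·3600·10⁻⁶; FMA = dry mass / projected area.
Morphometric values are averaged per vessel (five representative mature
fronds). The growth generator draws Poisson counts around the exponential
mean, colony counts around FN/⟨colony size⟩, and binomial senescent counts;
in noise-free mode counts are the rounded expectation, which bounds the RGR
round-trip error by integer rounding only (< 0.2% at fn0 = 10).

## Fast fluorescence kinetics (OJIP)

Landmarks are read at the standard protocol times — F0 at 50 µs, F300 at
300 µs, FJ at 2 ms, FI at 30 ms — by linear interpolation in log-time; Fm
is the global maximum, and the complementary area ∫(Fm − F) dt (ms basis)
is trapezoidal up to t_Fm. Derived quantities: φPo = Fv/Fm,
Vj = (FJ−F0)/Fv, Mo = 4 ms⁻¹·(F300−F0)/Fv, Sm = Area/Fv, TRo/RC = Mo/Vj,
ABS/RC = TRo/RC/φPo, ETo/RC = TRo/RC·(1−Vj), DIo/RC = ABS/RC − TRo/RC, and
PI_Abs = (φPo·Vj/Mo)·(φPo/(1−φPo))·((1−Vj)/Vj).

**Nomenclature caveat:** this workflow's parameter sheet glosses *Phi_Pav*
as "time needed to reach maximal fluorescence, in ms", which conflicts with
the usual JIP meaning of Phi_Pav as an average yield. We follow the sheet
literally — `phi_pav` is t_Fm in milliseconds — and flag the mismatch here.

The OJIP generator interpolates monotonically (PCHIP) in log-time between
the landmark knots, flat before 50 µs and after the peak (default
t_Fm = 300 ms), so landmark re-extraction is exact in noise-free mode. No
kinetic model between landmarks is asserted; the shape is the simplest
monotone curve through the observations.

## Quenching partition, ETR and rapid light curves

Y(II) = (Fm′−F)/Fm′, Y(NO) = F/Fm, Y(NPQ) = F/Fm′ − F/Fm; the three sum to
1 identically. ETR = Y(II)·PPFD·0.5·0.84 (photosystem split and leaf
absorptance are configurable constants). Rapid light curves — 13 steps from
0 to 700 µmol m⁻² s⁻¹ on an instrument-like ladder — are fitted with the
exponential rise-to-maximum ETR(I) = a·(1 − e^(−bI)) by least squares in
log-parameter space (positivity enforced; initial a from the largest ETR,
b from the first nonzero-step slope; up to 5 deterministic jittered
restarts). Reported: rETRmax = a, α = a·b, Ek = 1/b. Steps are sorted
before fitting so the result is invariant to input order. When b·Imax < 1
the curve never approached saturation and the fit is flagged
(`saturation_reached = False`): α is still meaningful, the plateau is not.
RLC noise is additive Gaussian with sd expressed as a fraction of rETRmax
(default 2% in the pipeline).

## Pigments

Chl a, Chl b and total carotenoids come from 80%-acetone extract
absorbances at 663.2, 646.8 and 470.0 nm after subtracting the 750.0 nm
turbidity baseline, using the narrow band-pass (0.1–0.5 nm) equation set
(Chl a = 12.25·A663.2 − 2.79·A646.8; Chl b = 21.50·A646.8 − 5.10·A663.2;
Car = (1000·A470 − 1.82·Chl a − 85.02·Chl b)/198, µg mL⁻¹), scaled to
µg g⁻¹ fresh mass by extract volume over sample mass. The coefficient set
is a config choice; the 3×3 system is checked for invertibility at import
and the generator produces absorbances by inverting it, so noise-free
recovery is exact. Ratios: Chl a/b; Car/(Chl a+b) on both mass and molar
bases (the molar version uses 893.5/907.5/570.9 g mol⁻¹ for Chl a/Chl b/a
generic carotenoid, since the intended basis is not stated);
VAZ/Car = (V+A+Z)/total Car and Z/VAZ from HPLC pools. Empty pools yield an
explicit undefined flag (`None`), never a silent zero.

## Scenes, transects and ontogeny maps

Scenes are 640 × 480 px at 4.6 px mm⁻¹. Fronds are non-overlapping,
randomly rotated ellipses; lengths are truncated-normal around the clone
mean (CV 0.35, floor 1 mm) so a vessel contains the whole ontogenetic
range; base/tip anchors sit at the major-axis endpoints just inside the
mask. Ground-truth Y(II) at relative axial position u (0 = base) and length
L is

    YII(u, L) = yii_young + (yii_mature − yii_young)·σ̃(L) + g·(u − ½)·ramp(L)

where σ̃ is a logistic in L (midpoint 2.5 mm, scale 0.6 mm) renormalised so
YII(L = 1 mm) = yii_young exactly, and the basipetal term (g = 0.08) ramps
in linearly over 1 mm past the 2.5 mm onset — tips of longer fronds mature
first. Y(NPQ) = ynpq_share·(1 − YII) and Y(NO) is the remainder, so closure
holds at every foreground pixel by construction. Per-pixel Gaussian noise
is applied to Y(II) before the split, which preserves closure.

Transects walk the straight base→tip segment at 1 px steps with
nearest-pixel lookup restricted to the frond's own label; off-label pixels
become explicit gaps. Fronds shorter than 6 px (> 1.0 mm at 4.6 px mm⁻¹)
are excluded. Ontogeny trends are ordinary least squares of frond-mean
parameters on frond length. Maps rank fronds by length (ties by id), split
them into 8 near-equal-count size classes, pool pixels per
(class, 1-px position) cell reduced by the median, drop up to the two
largest classes while they hold fewer than 3 fronds, and smooth the
occupied cells by scattered cubic interpolation that never extrapolates
beyond the data hull.

A known bias worth naming: a straight line fitted to the logistic
maturation trend overshoots the true 1 mm value by ≈ 0.04–0.06 because the
sigmoid's lower tail is flat. The calibration check on the high-light
0.43–0.48 band therefore allows the fitted 1 mm prediction the band plus
that bias margin; it is a consistency band, not a recovery target.

## Statistics cascade

Levene's test (median-centred, i.e. Brown–Forsythe; the centring is
switchable) checks variance homogeneity across the 8 cells and Shapiro–Wilk
checks normality of the cell-mean residuals (residuals, not raw responses,
as is statistically standard). On violation at α = 0.05 responses are
natural-log transformed (requires positivity; failure is an explicit
error). The two-way ANOVA uses the balanced cell-mean decomposition
(SS_clone, SS_light, SS_interaction = SS_cells − SS_clone − SS_light,
SS_error = SS_total − SS_cells), which equals the type-III decomposition on
balanced designs; near-balanced input is accepted with a warning.
ω² = (SS − df·MS_err)/(SS_total + MS_err), reported unclamped; all-constant
data yields ω² = 0 by convention. Branching: significant interaction →
per-light one-way ANOVAs across clones with pairwise comparisons; otherwise
a significant clone effect → overall clone comparison (one-way ANOVA +
Tukey, or Kruskal–Wallis + Mann–Whitney in pigment mode); a significant
light effect additionally triggers per-clone two-sample F- (two-sided
variance ratio) and t-tests. Pairwise p-values carry both raw and
Bonferroni-adjusted values (multiplier = the 6 pairwise comparisons of 4
clones, capped at 1). The frond-level light contrast is a common-slope
ANCOVA (`response ~ length + C(light)`) on frond-averaged Y(II).

## Pipeline and determinism

`run_pipeline(RunConfig)` executes simulate → growth → ojip → rlc →
pigments → imaging → stats, writing plain CSV/TIFF/JSON/PNG artifacts plus
a YAML config snapshot and a manifest of SHA-256 checksums; a rerun with
the same config reproduces identical checksums. All randomness descends
from one integer master seed through fixed per-generator stream offsets, so
adding draws in one generator never shifts another.

## Problem sizes

The shipped demo and verification runs use desk-scale sizes chosen to match
the study's own design: 30 fronds per scene, 13-step light curves, n = 6
vessels per cell (n = 4 for pigments), 20 replicate seeds for power-style
checks, 200 curves for noisy-recovery summaries and 10⁴ random records for
closure checks.

## Limitations

* The generators emulate measurement structure, not biology: ellipse fronds
  without gibbosity, roots or texture; independent fronds rather than
  mother–daughter colony geometry; no optical blur or instrument
  normalisation. Passing recovery tests shows the analysis is correct under
  the stated models, not that the models capture every property of real
  frond images.
* The OJIP shape between landmarks is a monotone interpolant, so derived
  quantities that depend on the full curve shape (Sm, area) are only as
  realistic as that interpolant.
* The clone-comparison branch uses Tukey (or Mann–Whitney) pairwise tests
  with an additional Bonferroni cap, mirroring the workflow it reimplements
  even though the double correction is conservative.
* RLC fits assume no photoinhibition downturn (no β term); curves measured
  far below saturation return a flagged, untrusted plateau.
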