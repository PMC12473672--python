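# frondscape

Phenotyping pipeline for duckweed (*Lemna gibba*) light-acclimation
experiments. It implements, as a tested and reusable Python library + CLI,
the full quantitative workflow of a clone × light-regime comparison:

* **growth & morphometrics** — relative growth rate
  RGR = (ln FN₇ − ln FN₀)/t, doubling time ln 2/RGR, colony size FN/CN,
  senescence %, ellipse frond area π·(L/2)·(W/2), roundness L/W,
  DLI = PPFD·photoperiod·3600·10⁻⁶, FMA = DM/area;
* **fast chlorophyll-fluorescence kinetics** — OJIP landmark extraction
  (F0, F300, FJ, FI, Fm, t_Fm, area) and the JIP-test fluxes
  (Fv/Fm, Sm, ABS/RC, TRo/RC, ETo/RC, DIo/RC, PI_Abs);
* **slow kinetics & rapid light curves** — the yield partition
  Y(II) = (Fm′−F)/Fm′, Y(NPQ) = F/Fm′ − F/Fm, Y(NO) = F/Fm (summing to 1),
  ETR = Y(II)·PPFD·0.5·0.84, and least-squares fits of
  ETR(I) = a·(1 − e^(−bI)) giving α, rETRmax and Ek = rETRmax/α;
* **pigments** — Chl a/b/carotenoid concentrations from 80%-acetone
  absorbances (A470.0/A646.8/A663.2, A750.0 baseline) and the
  xanthophyll-cycle ratios Chl a/b, Car/Chl a+b, VAZ/Car, Z/VAZ;
* **within-frond imaging** — base→tip transects of Y(II)/Y(NPQ)/Y(NO)
  rasters, frond-averaged ontogeny regressions vs frond length, and
  size-ordered interpolation maps with median pooling of overlapping
  pixels;
* **statistics** — the full decision cascade: Levene + Shapiro–Wilk checks
  with log-transform fallback, balanced two-way ANOVA with ω² effect
  sizes, branch-dependent post hocs (per-light one-way ANOVAs, Tukey or
  Kruskal–Wallis/Mann–Whitney with Bonferroni correction), per-clone
  F-/t-light contrasts and frond-level ANCOVA.

Because such experiments rarely ship raw data, the package includes a
first-class **synthetic-data generator** (`frondscape.synthetic`) that
emulates the whole measurement structure — exponential frond counts,
monotone OJIP transients with exact landmarks, saturating light curves,
closure-consistent quenching records, Beer–Lambert-consistent absorbances,
and 640×480 px fluorescence scenes with a basipetal, size-dependent Y(II)
maturation gradient — with known ground truth, so every stage is verified
by parameter recovery. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

```python
import frondscape as fs
from frondscape import imaging, quenching, synthetic

params = fs.default_clone_set()[5]          # clone MJ201 under high light

# rapid light curve: simulate at known truth, then fit it back
curve = synthetic.simulate_rlc(alpha_true=0.26, retrmax_true=65.0,
                               noise_sd=0.02, seed=3)
fit = quenching.fit_rlc(curve)
print(f"alpha={fit.alpha:.3f}  rETRmax={fit.retrmax:.1f}  Ek={fit.ek:.0f}")

# within-frond ontogeny: render a scene, extract transects, regress
scene = synthetic.render_scene(params, n_fronds=30, seed=3)
table = imaging.frond_average_table(imaging.extract_all_transects(scene))
trend = imaging.ontogeny_regression(table)
print(f"Y(II) slope={trend.slope:.4f} per mm  p={trend.p_value:.2g}  "
      f"Y(II)@1mm={trend.predict(1.0):.3f}")
```

prints

```
alpha=0.258  rETRmax=65.6  Ek=254
Y(II) slope=0.0186 per mm  p=3.3e-08  Y(II)@1mm=0.470
```

i.e. the fit recovers the simulated light-use efficiency and capacity to a
few percent under 2% measurement noise, and frond-mean Y(II) rises
significantly with frond length — photochemical efficiency builds up as
fronds expand and mature.

The end-to-end pipeline (simulate → analyze → map → stats) runs from the
shell and writes CSV tables, TIFF rasters, map figures and a checksummed
manifest:

```sh
frondscape run --out demo_run --seed 1
frondscape rlc --in demo_run/rlc.csv --out fits.csv
frondscape stats --in demo_run/growth_summary.csv --response rgr --out anova.csv
```

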