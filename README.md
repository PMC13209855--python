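# capmetrics

Characterization toolkit for spray-dried microcapsules — the powders
produced when an emulsified bioactive (here: lutein in a carrier oil,
walled with maltodextrin plus gum arabic or modified starch) is spray-dried
into a free-flowing(ish) powder. The package covers the four analysis
blocks such a study needs, plus a ground-truthed synthetic-data generator
so every stage can be exercised and validated without any instrument data.

## What it computes

**SEM particle sizing** (`capmetrics.imaging`). Micrographs are cropped
along the bottom edge (default 65 px) to remove the instrument databar,
min-max normalized to 0–255, and segmented into particle instances. The
default backend is classical — Otsu threshold → hole filling → Euclidean
distance transform → seed detection → watershed — behind an injectable
backend contract, so a learned segmentation model can be plugged in
unchanged. Particles intersecting the image boundary are excluded (their
diameters would be truncated); each retained particle's diameter is the
diameter of the **minimum enclosing circle** of its contour, which
reconstructs the full silhouette of a sphere even when it is partially
hidden behind a neighbor. Pixel diameters are calibrated by the scale bar
(default 20 µm per 229 px → 0.0873 µm/px) and summarized as valid N,
mean ± SD, and D10/D50/D90 (linear-interpolation percentiles).

**Powder QC** (`capmetrics.powder`):

- moisture MC = (mᵢ − m_d)/mᵢ × 100
- solubility S = (m_res − blank) × (25/10) / m_powder × 100
- encapsulation efficiency EE = (oil_total − oil_surface)/oil_total × 100
- bulk density ρ_b = m/V; tapped density ρ_t = m/V_f with a <1% settling
  convergence check on the tapping series
- Carr's Index CI = (ρ_t − ρ_b)/ρ_t × 100 and Hausner Ratio HR = ρ_t/ρ_b
  (identities: HR = 1/(1 − CI/100))
- feed mass balance of a recipe → dry solids, feed solids fraction, and the
  oil mass fraction m_oil of the dry matrix
- lipid-core concentration c_core = c_powder / m_oil

**HPLC quantification** (`capmetrics.hplc`). External-standard linear
calibration (OLS of area on injected amount), retention-time matching
within an analytical drift window (default 3.85 ± 0.1 min), S/N-based
detection limits (LOD = 3σ/slope, LOQ = 10σ/slope), inversion of areas to
amounts with censoring flags, and conversion to µg analyte per g powder.

**Statistics** (`capmetrics.stats`). One-way ANOVA with Shapiro–Wilk /
Levene assumption checks, Tukey HSD with the Tukey–Kramer SE for unequal
n, and a compact letter display (insert-and-absorb) such that two groups
share a letter iff they are not significantly different — with summary
statistics (mean, SD, n) as a first-class input, because published tables
expose only mean ± SD for n = 3.

**Synthetic data** (`capmetrics.synthetic`). Seeded generators for
SEM-like micrographs (log-normal diameter population, shaded disks,
overlap control, border particles, noise, databar + scale bar, full ground
truth), triplicate assay replicates, and chromatographic peak areas.

## Worked example

```python
from capmetrics import imaging
from capmetrics.synthetic import MicrographSimParams, simulate_micrograph

params = MicrographSimParams(n_particles=150, image_width=1024,
                             image_height=1024, seed=21)
img, truth = simulate_micrograph(params)
table, summary, mask = imaging.size_micrograph(img)
print(summary.valid_n, round(summary.mean_um, 2), round(summary.d50_um, 2))
```

prints `134 3.74 3.52`: of 150 simulated particles, 16 touched the border
and were excluded; the recovered mean diameter (3.74 µm) and D50 (3.52 µm)
match the interior ground truth (3.74 / 3.52 µm) to the printed precision.
More narrative scripts live in `examples/` (one per capability: sizing,
powder QC, HPLC, Tukey letters, and the full nine-formulation demo), and a
thin CLI exposes the same operations
(`capmetrics simulate-sem | size | qc | hplc | stats | run | demo`).

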