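# Methods

This note documents the models, conventions, and numerical choices behind
capmetrics, and what the synthetic-data validation does and does not show
about real data.

## Particle sizing from SEM micrographs

**Pipeline.** A micrograph arrives with an instrument databar at the
bottom edge; `crop_databar` removes it (default 65 rows) so text and scale
markers cannot be detected as particles. `normalize_contrast` applies an
affine min-max map to the 0–255 8-bit range (round-half-even); a constant
image maps to all zeros with a warning. Segmentation, border exclusion,
and measurement then operate on the cropped content region only.

**Segmentation backend contract.** Any callable
`(image_array, config) -> label_mask` can serve as the instance
segmentation backend; the bundled default is classical: Otsu threshold →
binary hole filling → Euclidean distance transform → Gaussian smoothing of
the distance field (σ = 2 px, suppressing spurious ridges from noisy
boundaries) → per-component peak seeds with minimum separation
`base_diameter_px / 2` (default 30/2 = 15 px) → marker-based watershed.
This separates moderately touching near-spherical granules; heavily fused
agglomerates may remain unsplit, and no attempt is made to resolve them —
they are simply measured as one object or excluded downstream. Instances
smaller than `min_area_px` (default 9 px, a sub-resolution speck filter)
are dropped and labels compacted.

**Border exclusion.** An instance is excluded iff it has at least one
pixel in the first/last row or column of the content region. On synthetic
images this exactly matches the generator's geometric border flag except
when a disk's true extent passes within a pixel of the boundary, where
rasterization decides; the acceptance tests compare the full excluded sets
and they agree.

**Minimum enclosing circle.** Diameters come from the smallest circle
containing the particle's outer-boundary pixel centers (identical result
to using all mask pixels, at lower cost). The implementation is Welzl's
randomized incremental algorithm with a seeded shuffle, so output is
deterministic; near-collinear circumcircle degeneracies fall back to the
largest two-point circle. Containment tolerance is 1e-7 relative. An
O(n⁴) pair/triple enumeration oracle is kept alongside for testing only.
The MEC is what makes the measurement robust to partial lateral occlusion:
for a sphere with less than half its silhouette hidden from one side, the
visible arc still determines the full circle, so the diameter is recovered
essentially exactly (verified to <3% on a fixture with ~30% of the area
hidden).

**Calibration and descriptors.** µm/px = scale-bar physical length /
scale-bar pixel length (default 20/229 ≈ 0.087336). Percentiles D10/D50/D90
use linear interpolation between closest ranks; SD uses the n−1
denominator; histograms use 0.5 µm bins from 0. Coordinates are (row, col),
0-based, pixel centers at integers.

## Synthetic micrograph model

Particles are opaque disks with linear radial shading (brightest at the
center, falling to 55% of the level step at the rim), drawn over a uniform
background, with i.i.d. Gaussian sensor noise (default SD 8 intensity
levels) and an appended mid-gray databar carrying a white scale bar of
exactly `scalebar_px` columns and no text glyphs — so the crop stage is
exercised but cannot exploit databar content. Diameters are log-normal
(default median 3.7 µm, log-SD 0.45: most particles under 6 µm, tail to
~12–14 µm, matching the right-skewed unimodal populations of spray-dried
microcapsules). Placement is rejection sampling, largest-first;
`max_overlap_fraction` bounds the pairwise lens-area overlap as a fraction
of the smaller disk (0 means disjoint, with a 2 px cushion so disjoint
disks stay 8-disconnected); failure to place raises an error naming how
many fit. The generator does **not** model electron-optics effects
(charging, shadowing, depth of field), surface texture, dents, debris, or
multi-particle agglomerate morphology beyond pairwise overlap. Passing the
recovery tests therefore demonstrates the pipeline's geometric correctness
(segmentation, exclusion, MEC, calibration, summarization) — not that any
particular segmentation backend is adequate for real SEM texture; that is
exactly what the injectable backend seam is for.

**Validation scale.** The parameter-recovery checks use three seeded
2048×2048 micrographs with 360 particles each (~13% area fraction, ≥300
interior non-fused particles per image), recovering mean diameter and D50
within 5% and the border-excluded set exactly. Distributional checks use
1000-particle draws (KS test at α = 0.01 against the specified
log-normal).

## Powder QC conventions

- **Replicates.** Each formula is evaluated per analytical replicate and
  then averaged (mean ± n−1 SD). For nonlinear quantities (EE, CI, HR)
  this differs from evaluating the formula at the replicate means; the
  per-replicate convention is canonical here and the formula-at-means
  value is only a diagnostic.
- **Solubility blank.** The blank residue is subtracted from the aliquot
  residue *before* the dilution factor is applied (the physically coherent
  order: both are residues of equal-mass aliquots). Negative corrected
  residues floor at 0 with a warning.
- **Tapped density convergence.** The series is accepted iff the final
  pair's relative change is < 1%; otherwise a convergence error names the
  last relative change.
- **Units.** Densities are computed in g/mL and converted ×1000 to kg/m³
  for reporting. Report tables round half-up at 2 decimals (matching how
  bench tables are printed, where round-half-even would disagree on
  exact .5 boundaries).
- **Identities.** EE + surface/total × 100 = 100 and HR = 1/(1 − CI/100)
  hold algebraically and are enforced by property tests.

## HPLC quantification

Calibration is unweighted OLS (a plain linear response is assumed; no 1/x
weighting). R² is the squared correlation; the response factor is
RF = area/amount and `rf_rsd` its percent RSD over non-zero levels. The
default calibration levels are {2.45, 12.25, 61.25, 122.5} ng/injection —
four levels spanning the stated 2.45–122.5 ng linear range. Detection
limits follow the S/N definition: LOD = 3σ_noise/slope, LOQ = 10σ_noise/
slope, hence LOQ/LOD = 10/3 exactly (published values that round to a
slightly different ratio are a printing-precision artifact). Censoring
flags partition [0, ∞): below_lod / between_lod_loq / quantified /
extrapolated (beyond the calibrated range); areas below the intercept
floor at amount 0. The injection volume is not part of the published
protocol and defaults to 10 µL — powder concentrations scale with it, so
it is an explicit, logged configuration value.

## Statistics

The summary-statistics path (mean, SD, n per group) is first-class:
MS_within pools Σ(nᵢ−1)sᵢ²/Σ(nᵢ−1) and group means enter directly, which
agrees exactly with the raw-data decomposition when raw data realize the
same summaries. Tukey HSD uses the studentized range distribution
(`scipy.stats.studentized_range`, quantile accuracy well below 1e-6) with
the Tukey–Kramer SE √(MS_w/2 · (1/nᵢ + 1/nⱼ)) for unequal n; significance
is p ≤ α (α = 0.05). At k = 2 the procedure reduces to the pooled t-test.
Assumption checks (Shapiro–Wilk per group, Levene across groups) are
advisory and never block the ANOVA; constant groups report NaN normality.
For particle-diameter comparisons the default unit of analysis is the
individual particle (unequal group sizes, Tukey–Kramer) — image-level
means are also representable via the summary path.

**Letter display.** Insert-and-absorb: start with one letter covering all
groups; for each significant pair, split every letter containing both;
absorb letters that became subsets. Letters are ordered by descending
mean, so "a" always marks the largest-mean group. The resulting display
satisfies share-a-letter ⇔ not-significant for any significance pattern,
including non-transitive ones (property-tested for k ≤ 10).

**Calibration.** Under the global null (9 groups, n = 3), 1000 seeded
Monte-Carlo replicates put the family-wise error rate within [0.035,
0.065] of the nominal 0.05, using the max-studentized-range shortcut that
is provably equivalent to "any pair significant".

## Orchestration

`RunConfig` is a plain dataclass serializable to JSON; every run writes
the fully resolved config and a manifest (config hash, seed, per-stage
counts). Stages with no configured input are skipped with a notice; a
stage failure raises an error naming the stage and input path, leaving
earlier outputs on disk. `demo(seed)` simulates a full nine-formulation
study at the bundled study conditions (recipes, assay means/SDs,
calibration line, per-formulation particle-size medians) and is a pure
function of its seed. Demo micrographs default to 512×512 content with 40
particles per formulation; validation-grade recovery runs use the larger
2048×2048 / 360-particle configuration described above.

## Known limitations

- The classical watershed backend is tuned for bright convex particles on
  a dark background; real micrograph texture (dents, debris, charging
  halos) will generally need a learned backend via `register_backend`.
- Heavily fused agglomerates are not split (by design), which biases the
  tail of the size distribution upward if they survive the area filter.
- Diameters are 2-D silhouette measurements; no stereological correction
  to 3-D size distributions is attempted.
- The bundled published Valid-N values (676–1165 per formulation) came
  from the original micrographs and cannot be regenerated here; only
  simulation-based recovery is claimed for the imaging chain.
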