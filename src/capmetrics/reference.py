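"""Bundled reference dataset for the nine spray-dried lutein formulations.

These are the published bench summary statistics (mean, SD, n = 3 analytical
replicates) and the formulation recipes for a solvent-free lutein
microencapsulation study: nine spray-dried powders coded by extraction
method, carrier oil, and wall material (maltodextrin blended with gum
arabic, tapioca starch, or waxy maize starch).

They serve two purposes: as inputs to the summary-statistics statistics
path (ANOVA / Tukey / letter display on mean-SD-n triples), and as the
default "study conditions" the synthetic-data generator emulates.
"""

from __future__ import annotations

FORMULATION_CODES = [
    "CON", "ETA", "EHS", "STA", "SHS", "CTA", "CHS", "GTA", "GHS",
]

# Recipe per batch: carrier oil extract [g], Tween 80 emulsifier [g], and two
# 15% (w/w) aqueous polymer solutions of 133 g each (maltodextrin plus the
# second wall material named in the code).
RECIPE_OIL_G = 20.0
RECIPE_EMULSIFIER_G = 0.4
RECIPE_SOLUTION_G = 133.0
RECIPE_SOLID_FRACTION = 0.15

# Bench assay summaries: code -> (mean, sd), n = 3 throughout.
MOISTURE_PCT = {
    "CON": (3.43, 0.06), "ETA": (2.45, 0.05), "EHS": (1.96, 0.04),
    "STA": (0.98, 0.02), "SHS": (1.96, 0.04), "CTA": (0.98, 0.02),
    "CHS": (0.98, 0.02), "GTA": (1.47, 0.03), "GHS": (1.96, 0.04),
}

SOLUBILITY_PCT = {
    "CON": (70.5, 5.61), "ETA": (75.59, 10.95), "EHS": (75.84, 0.72),
    "STA": (80.83, 5.35), "SHS": (75.35, 10.68), "CTA": (81.29, 17.11),
    "CHS": (85.81, 0.24), "GTA": (75.2, 0.24), "GHS": (80.55, 5.52),
}

SURFACE_OIL_G100G = {
    "CON": (20.48, 0.50), "ETA": (20.57, 1.50), "EHS": (18.48, 1.50),
    "STA": (16.98, 1.00), "SHS": (13.98, 3.00), "CTA": (17.98, 2.00),
    "CHS": (15.98, 0.04), "GTA": (18.97, 0.04), "GHS": (16.48, 0.50),
}

TOTAL_OIL_G100G = {
    "CON": (35.67, 2.08), "ETA": (31.67, 0.58), "EHS": (30.33, 4.73),
    "STA": (34.33, 3.21), "SHS": (32.33, 1.53), "CTA": (33.33, 1.53),
    "CHS": (32.00, 1.73), "GTA": (35.33, 4.73), "GHS": (33.00, 3.00),
}

ENCAPSULATION_EFFICIENCY_PCT = {
    "CON": (42.44, 4.01), "ETA": (34.98, 5.80), "EHS": (37.91, 11.89),
    "STA": (50.11, 7.18), "SHS": (56.59, 10.44), "CTA": (45.93, 7.43),
    "CHS": (49.97, 2.57), "GTA": (45.60, 7.86), "GHS": (49.88, 3.07),
}

BULK_DENSITY_KG_M3 = {
    "CON": (394.66, 5.90), "ETA": (267.65, 3.75), "EHS": (260.47, 30.96),
    "STA": (261.74, 4.59), "SHS": (264.19, 4.08), "CTA": (259.02, 1.53),
    "CHS": (271.58, 6.49), "GTA": (271.14, 1.88), "GHS": (272.12, 2.75),
}

TAPPED_DENSITY_KG_M3 = {
    "CON": (666.00, 1.15), "ETA": (506.73, 50.59), "EHS": (494.60, 4.98),
    "STA": (524.60, 30.28), "SHS": (553.12, 27.57), "CTA": (582.59, 33.94),
    "CHS": (540.21, 14.67), "GTA": (525.98, 13.91), "GHS": (587.45, 1.36),
}

CARR_INDEX_PCT = {
    "CON": (40.70, 0.88), "ETA": (46.87, 4.66), "EHS": (47.35, 5.73),
    "STA": (49.92, 2.02), "SHS": (52.08, 1.65), "CTA": (55.33, 2.36),
    "CHS": (49.66, 0.20), "GTA": (48.36, 1.03), "GHS": (53.61, 0.47),
}

HAUSNER_RATIO = {
    "CON": (1.69, 0.03), "ETA": (1.90, 0.17), "EHS": (1.92, 0.21),
    "STA": (2.00, 0.08), "SHS": (2.09, 0.07), "CTA": (2.25, 0.12),
    "CHS": (1.99, 0.01), "GTA": (1.94, 0.04), "GHS": (2.16, 0.02),
}

# Particle-size descriptors per formulation from the published SEM sizing:
# code -> (valid_n, mean_um, sd_um, d10_um, d50_um, d90_um).
SIZE_SUMMARY = {
    "CON": (1090, 4.07, 1.90, 2.06, 3.66, 6.58),
    "ETA": (1040, 4.39, 2.25, 2.22, 3.86, 7.39),
    "EHS": (1135, 4.11, 2.01, 2.16, 3.57, 6.48),
    "STA": (676, 4.33, 2.52, 2.01, 3.52, 7.54),
    "SHS": (796, 4.34, 2.24, 2.11, 3.75, 7.58),
    "CTA": (906, 4.38, 2.23, 2.15, 3.81, 7.42),
    "CHS": (889, 4.80, 2.28, 2.55, 4.37, 7.56),
    "GTA": (1052, 4.22, 2.00, 2.23, 3.71, 6.63),
    "GHS": (1165, 3.85, 1.94, 1.99, 3.36, 6.36),
}

# Lutein concentration in the spray-dried powders [ug/g], code -> (mean, sd).
LUTEIN_POWDER_UG_G = {
    "CON": (32.85, 7.18), "ETA": (18.8, 3.27), "EHS": (17.62, 0.54),
    "STA": (20.07, 1.02), "SHS": (20.62, 0.97), "CTA": (19.5, 2.69),
    "CHS": (20.12, 1.45), "GTA": (26.82, 0.77), "GHS": (24.97, 0.82),
}

# Published lipid-core lutein concentrations [ug/g oil], code -> (mean, sd).
LUTEIN_CORE_UG_G = {
    "CON": (99.04, 21.64), "ETA": (56.68, 9.86), "EHS": (53.11, 1.63),
    "STA": (60.5, 3.06), "SHS": (62.15, 2.91), "CTA": (58.79, 8.1),
    "CHS": (60.65, 4.37), "GTA": (80.85, 2.31), "GHS": (75.27, 2.46),
}

# HPLC external-standard calibration for lutein at 450 nm.
CALIBRATION_SLOPE = 6379.25       # area units per ng injected
CALIBRATION_INTERCEPT = 2232.78   # area units
CALIBRATION_R_SQUARED = 0.9999964
CALIBRATION_RF_RSD_PCT = 8.91
# Four calibration levels spanning the stated linear range 2.45-122.5 ng.
CALIBRATION_LEVELS_NG = (2.45, 12.25, 61.25, 122.5)
LOD_NG = 0.13   # S/N 3:1
LOQ_NG = 0.42   # S/N 10:1
REFERENCE_RT_MIN = 3.85
RT_WINDOW_MIN = 0.1

# SEM sizing pipeline constants.
DATABAR_CROP_ROWS = 65
SCALEBAR_PX = 229
SCALEBAR_UM = 20.0
BASE_DIAMETER_PX = 30

# Log-normal particle population: median below 6 um with a right tail to
# 12-14 um, as observed across all nine formulations.
PARTICLE_MEDIAN_UM = 3.7
PARTICLE_LOG_SD = 0.45
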