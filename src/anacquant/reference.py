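"""Published reference values for the cashew-peduncle anacardic acid study.

These are the printed results of the validated HPLC-DAD method applied to
five commercial cashew clones (CCP 09, CCP 76, BRS 265, BRS 275 and
Embrapa 51): the external-standard calibration summary, the validation
figures, the per-extraction dry-weight amounts (``None`` marks values
reported below the limit of quantification), the per-extraction recovery
percentages, and the totals column.  They serve as regression anchors for
the arithmetic of this package — recovery accumulation, censored totals,
significance statistics — not as data the package recomputes from raw
signal (no raw chromatograms were deposited).
"""

from __future__ import annotations

from types import MappingProxyType

CLONES = ("CCP 09", "CCP 76", "BRS 265", "BRS 275", "Embrapa 51")
ANALYTES = ("AnAc 15:3", "AnAc 15:2", "AnAc 15:1")

CALIBRATION_LEVELS = (1.0, 5.0, 10.0, 20.0, 40.0, 60.0, 80.0, 100.0)  # ug/mL
CALIBRATION_REPLICATES = 3

#: printed calibration line and significance summary (95% confidence)
CALIBRATION_SUMMARY = MappingProxyType({
    "slope": 2333.5,            # area per ug/mL
    "intercept": 2956.2,        # area
    "r_squared": 0.998,
    "s_slope": 15.79,
    "s_intercept": 830.91,
    "t_slope": 147.63,          # printed; 2333.5/15.79 = 147.78 (rounding)
    "t_intercept": 3.56,
    "t_tabulated": 2.009,       # stored as printed (df not stated)
    "f_stat": 21812.56,
    "f_tabulated": 1.576,       # stored as printed (matches no standard quantile)
})

#: printed precision and suitability figures (percent CV / RSD)
PRECISION_SUMMARY = MappingProxyType({
    "intraday_cv": 0.20, "intraday_n": 6, "intraday_r_squared": 0.9993,
    "interday_cv": 0.29, "interday_n": 9, "interday_r_squared": 0.9979,
})
SUITABILITY_SUMMARY = MappingProxyType({"rt_rsd": 0.45, "area_rsd": 0.30, "n": 10})

#: printed detection limits, ug/mL (visual method; 0.83 appears in the text
#: where the summary table prints 0.85 — the table value is kept)
LOD_UG_ML = 0.18
LOQ_UG_ML = 0.85
LOQ_UG_ML_TEXT_VARIANT = 0.83

#: printed three-point peak purities per analyte (fractions)
PURITIES = MappingProxyType({
    "AnAc 15:3": 0.9917, "AnAc 15:2": 0.9819, "AnAc 15:1": 0.9940,
})

SAMPLE_MASS_G = 0.5
RECONSTITUTION_VOLUME_ML = 3.0
EXTRACTION_SOLVENT_ML = 9.0
N_EXTRACTIONS = 5

#: per-extraction amounts, mg/100 g dry weight; None = below LOQ
EXTRACTION_AMOUNTS = MappingProxyType({
    "CCP 09": {
        "AnAc 15:3": (22.07, 2.32, None, None, None),
        "AnAc 15:2": (16.66, 1.81, None, None, None),
        "AnAc 15:1": (109.88, 14.63, 2.39, 0.81, None),
    },
    "CCP 76": {
        "AnAc 15:3": (23.16, 6.34, 1.65, None, None),
        "AnAc 15:2": (41.22, 12.01, 3.62, None, None),
        "AnAc 15:1": (79.98, 24.07, 7.74, 0.16, None),
    },
    "BRS 265": {
        "AnAc 15:3": (39.88, 4.64, 0.23, None, None),
        "AnAc 15:2": (33.29, 3.99, 0.10, None, None),
        "AnAc 15:1": (115.26, 16.14, 2.33, 1.12, None),
    },
    "BRS 275": {
        "AnAc 15:3": (26.88, 2.95, None, None, None),
        "AnAc 15:2": (17.51, 1.64, None, None, None),
        "AnAc 15:1": (81.26, 10.45, 1.42, 0.49, None),
    },
    "Embrapa 51": {
        "AnAc 15:3": (16.56, 3.05, None, None, None),
        "AnAc 15:2": (11.66, 2.05, None, None, None),
        "AnAc 15:1": (75.95, 16.56, 2.09, 0.40, None),
    },
})

#: printed totals column, mg/100 g dry weight
TOTAL_AMOUNTS = MappingProxyType({
    "CCP 09": {"AnAc 15:3": 24.40, "AnAc 15:2": 18.47, "AnAc 15:1": 127.72},
    "CCP 76": {"AnAc 15:3": 31.16, "AnAc 15:2": 56.87, "AnAc 15:1": 111.96},
    "BRS 265": {"AnAc 15:3": 44.76, "AnAc 15:2": 37.38, "AnAc 15:1": 134.86},
    "BRS 275": {"AnAc 15:3": 29.83, "AnAc 15:2": 19.15, "AnAc 15:1": 93.63},
    "Embrapa 51": {"AnAc 15:3": 19.62, "AnAc 15:2": 13.71, "AnAc 15:1": 95.02},
})

#: per-extraction recovery percentages (raw-area shares)
RECOVERY_PERCENT = MappingProxyType({
    "CCP 09": {
        "AnAc 15:3": (85.35, 11.42, 2.18, 0.93, 0.11),
        "AnAc 15:2": (83.88, 12.27, 2.56, 1.14, 0.13),
        "AnAc 15:1": (84.51, 11.73, 2.18, 1.17, 0.19),
    },
    "CCP 76": {
        "AnAc 15:3": (71.17, 21.05, 7.06, 0.66, 0.03),
        "AnAc 15:2": (70.48, 21.42, 7.30, 0.78, 0.02),
        "AnAc 15:1": (70.25, 21.58, 7.36, 0.77, 0.02),
    },
    "BRS 265": {
        "AnAc 15:3": (85.33, 11.26, 2.00, 1.33, 0.05),
        "AnAc 15:2": (84.97, 11.76, 2.03, 1.16, 0.06),
        "AnAc 15:1": (84.15, 12.23, 2.21, 1.33, 0.06),
    },
    "BRS 275": {
        "AnAc 15:3": (84.56, 11.33, 2.34, 1.54, 0.22),
        "AnAc 15:2": (84.41, 11.19, 1.90, 1.31, 0.18),
        "AnAc 15:1": (84.73, 11.58, 2.24, 1.29, 0.15),
    },
    "Embrapa 51": {
        "AnAc 15:3": (78.67, 17.24, 2.74, 1.17, 0.17),
        "AnAc 15:2": (78.24, 17.56, 2.73, 1.17, 0.28),
        "AnAc 15:1": (78.13, 17.62, 2.88, 1.15, 0.20),
    },
})

#: reported cumulative recoveries after two extractions, percent
TWO_STEP_RECOVERY = MappingProxyType({
    "CCP 09": {"AnAc 15:3": 96.77, "AnAc 15:2": 96.15, "AnAc 15:1": 96.24},
    "CCP 76": {"AnAc 15:3": 92.22, "AnAc 15:2": 91.90, "AnAc 15:1": 91.83},
    "BRS 265": {"AnAc 15:3": 96.59, "AnAc 15:2": 96.73, "AnAc 15:1": 96.38},
    "BRS 275": {"AnAc 15:3": 95.89, "AnAc 15:2": 95.60, "AnAc 15:1": 96.31},
    "Embrapa 51": {"AnAc 15:3": 95.91, "AnAc 15:2": 95.80, "AnAc 15:1": 95.75},
})

#: reported study range of per-clone grand totals, mg/100 g
TOTAL_RANGE = (128.35, 217.00)
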