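"""Reference cohort statistics for Crowe type-IV dysplastic hips.

Published CT-based planning measurements for a reference cohort of 30
Crowe type-IV hips (44-mm cup, 45° abduction / 20° anteversion, medialized
with anterior-wall and transverse-ligament tangency).  The synthetic-cohort
generator is parameterized so that its population moments emulate this
cohort; the correlation table is also the input for the printed-value
consistency checks (squaring a reported Pearson r must reproduce the
reported R² of the paired simple regression).

Values are (mean, SD); ratios are dimensionless, lengths mm, volumes mm³.
"""

REFERENCE_N_HIPS = 30

# (mean, SD) per measurement
REFERENCE_MOMENTS = {
    "asucr": (0.0832, 0.0427),
    "aiucr": (0.0521, 0.0246),
    "psucr": (0.1012, 0.0435),
    "piucr": (0.0592, 0.0478),
    "tucr": (0.2958, 0.1003),
    "height_mm": (31.99, 4.09),
    "ap_diameter_mm": (25.23, 4.82),
    "volume_mm3": (21257.59, 9165.69),
}

# (variable_1, variable_2, pearson_r, reported_r_squared)
REFERENCE_CORRELATIONS = [
    ("asucr", "tucr", 0.461, 0.213),
    ("psucr", "piucr", 0.644, 0.415),
    ("psucr", "tucr", 0.889, 0.791),
    ("piucr", "tucr", 0.768, 0.590),
    ("height_mm", "asucr", 0.395, 0.156),
    ("height_mm", "piucr", -0.585, 0.342),
    ("volume_mm3", "piucr", -0.473, 0.224),
]

# reference cohort split at the TUCR 0.3 guideline boundary
REFERENCE_TUCR_SPLIT = 0.3
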