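"""Reference compound-level confusion-matrix counts and metrics for the
liver biomarker concordance analysis (single parameters and ALT-anchored
positive-emphasis combinations)."""

# parameter: (tp, fp, fn, tn, mcc, sensitivity %, specificity %)
SINGLE_PARAMETER_ROWS = {
    "Alanine aminotransferase (ALT)": (135, 64, 206, 392, 0.2921, 39.6, 86.0),
    "Alkaline phosphatase (ALP)": (106, 43, 217, 371, 0.2771, 32.8, 89.6),
    "Cholesterol": (124, 61, 174, 303, 0.2755, 41.6, 83.2),
    "Aspartate aminotransferase (AST)": (93, 49, 226, 374, 0.2211, 29.2, 88.4),
    "Bilirubin": (53, 27, 198, 322, 0.1941, 21.1, 92.3),
    "Triglycerides": (84, 54, 172, 261, 0.1820, 32.8, 82.9),
    "Albumin": (99, 61, 223, 306, 0.1669, 30.7, 83.4),
    "Creatinine": (59, 33, 247, 374, 0.1650, 19.3, 91.9),
    "Urea": (61, 43, 199, 301, 0.1438, 23.5, 87.5),
    "Protein": (92, 66, 226, 311, 0.1358, 28.9, 82.5),
}

# combination: (fp, tp, tn, fn, mcc, sensitivity %, specificity %)
COMBINED_PARAMETER_ROWS = {
    "ALT + alkaline phosphatase": (53, 168, 379, 180, 0.3972, 48.3, 87.7),
    "ALT + creatinine": (44, 157, 384, 192, 0.3942, 45.0, 89.7),
    "ALT + cholesterol": (74, 182, 378, 168, 0.3790, 52.0, 83.6),
    "ALT + bilirubin": (47, 150, 393, 196, 0.3742, 43.4, 89.3),
    "ALT + aspartate aminotransferase": (54, 149, 389, 194, 0.3541, 43.4, 87.8),
    "ALT + triglycerides": (72, 168, 377, 180, 0.3486, 48.3, 84.0),
    "ALT + albumin": (70, 166, 379, 183, 0.3475, 47.6, 84.4),
    "ALT + urea": (59, 155, 374, 192, 0.3457, 44.7, 86.4),
    "ALT + protein": (72, 167, 373, 182, 0.3427, 47.9, 83.8),
    "ALT alone": (64, 135, 392, 206, 0.2921, 39.6, 86.0),
}
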