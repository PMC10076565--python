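"""Published calibration constants for the study conditions the simulator
reproduces: a single-center cohort of non-stenotic (<50%) intracranial
atherosclerotic plaques on 3-D high-resolution vessel-wall MRI, split into
culprit lesions (ipsilateral to a DWI-confirmed acute infarct in a
symptomatic patient) and non-culprit lesions (asymptomatic patients).

Continuous imaging features are given as group mean ± SD, binary clinical
covariates as group prevalences; these are the defaults the synthetic-cohort
generator draws from, and the reference surface for the closed-form checks.
"""

from __future__ import annotations

INITIAL_COHORT_N = 209

# exclusions applied to the initial cohort, by reason
EXCLUSIONS = {
    "extracranial_stenosis_ge_50": 7,
    "aneurysm": 15,
    "vasculitis": 5,
    "moyamoya": 3,
    "dissection": 10,
    "suspected_cardiogenic_stroke": 5,
    "aortic_arch_plaque_or_wall_ge_4mm": 5,
    "intracranial_hemorrhage": 2,
    "severe_consciousness_disturbance": 2,
    "poor_image_quality": 5,
}

N_CULPRIT = 111
N_NONCULPRIT = 39

# plaque location counts per group (culprit, non-culprit)
LOCATION_COUNTS = {
    "MCA": (97, 36),
    "ACA": (3, 0),
    "ICA": (11, 3),
}

# continuous features: name -> ((culprit mean, sd), (non-culprit mean, sd))
CONTINUOUS_FEATURES = {
    "wall_max": ((1.65, 0.43), (1.23, 0.24)),
    "wall_min": ((0.37, 0.17), (0.31, 0.09)),
    "stenosis_pct": ((16.92, 9.13), (14.34, 8.85)),
    "plaque_burden_pct": ((69.95, 8.69), (62.55, 5.19)),
    "remodeling_ratio_pct": ((104.73, 27.85), (97.00, 22.73)),
    "eccentricity_index_pct": ((77.16, 9.68), (74.98, 7.22)),
    "enhancement_ratio_stenosis_pct": ((39.20, 20.60), (15.58, 9.54)),
    "enhancement_ratio_whole_pct": ((42.44, 20.79), (16.66, 9.68)),
    "plaque_volume": ((37.22, 11.46), (17.77, 6.02)),
    "hist_mean": ((119.15, 36.49), (123.75, 32.00)),
    "hist_sd": ((34.39, 12.58), (32.19, 10.48)),
    "hist_median": ((118.13, 36.96), (120.72, 37.46)),
    "hist_minimum": ((43.80, 23.37), (46.61, 20.83)),
    "hist_maximum": ((196.35, 55.56), (194.55, 48.88)),
    "hist_cv": ((0.29, 0.09), (0.26, 0.06)),
    "hist_entropy": ((6.62, 4.99), (6.51, 0.37)),
}

AGE = ((58.5, 12.6), (58.9, 10.6))

# binary covariates: name -> (culprit prevalence, non-culprit prevalence)
BINARY_COVARIATES = {
    "male": (83 / 111, 30 / 39),
    "smoking": (48 / 111, 10 / 39),
    "alcohol": (28 / 111, 7 / 39),
    "diabetes": (31 / 111, 9 / 39),
    "hypertension": (60 / 111, 16 / 39),
    "coronary_artery_disease": (2 / 111, 0 / 39),
    "hyperlipidemia": (40 / 111, 3 / 39),
    "iph": (13 / 111, 1 / 39),
}

# hyperlipidemia 2x2 table: rows = group (culprit, non-culprit),
# cols = (present, absent)
HYPERLIPIDEMIA_TABLE = ((40, 71), (3, 36))

# NIHSS: median (range) per group; simulated as truncated geometric pmfs
NIHSS_CULPRIT = {"median": 3, "range": (0, 18)}
NIHSS_NONCULPRIT = {"median": 0, "range": (0, 6)}

# physical truncation bounds for the truncated-normal feature draws
TRUNCATION_BOUNDS = {
    "plaque_burden_pct": (0.0, 100.0),
    "eccentricity_index_pct": (0.0, 100.0),
    "enhancement_ratio_stenosis_pct": (-100.0, float("inf")),
    "enhancement_ratio_whole_pct": (-100.0, float("inf")),
    "stenosis_pct": (-100.0, 50.0),
    "hist_entropy": (0.0, 8.0),
}
DEFAULT_TRUNCATION = (0.0, float("inf"))
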