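"""Reference results from the original two-winter field study.

The original study (17 GPS-collared wolves in the boreal forest of
northeastern Alberta, January-March of two winters) published its model
selection tables and final-model coefficients. Those printed values are
shipped here as plain data so users can rerun the selection arithmetic —
AIC = 2K - 2 logL, Akaike weights, evidence ratios, the parsimony pick, and
the back-transformations — against the published numbers without access to
the raw collar and camera data (which were never deposited).

``TRAVEL_SELECTION_PRINTED`` row 8 of the original travel-probability table
repeated the full-interaction formula with K=8, inconsistent with the K=16 of
its own top row; that row is reproduced verbatim but flagged
(``typo_suspect``) and excluded from K-consistency checks.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "SPEED_SELECTION_PRINTED",
    "TRAVEL_SELECTION_PRINTED",
    "SPEED_COEFFICIENTS_PRINTED",
    "TRAVEL_COEFFICIENTS_PRINTED",
    "REFERENCE_SUMMARIES",
]

# Travel-speed selection table (LMM on log10 speed; by-wolf random intercept
# + time-of-day slope). Columns: rank, formula, K, logL, AIC, delta_AIC, weight.
SPEED_SELECTION_PRINTED = pd.DataFrame(
    [
        (1, "snowfall_category + time_of_day", 12, -3501.96, 7027.93, 0.00, 0.51),
        (2, "snowfall_category * time_of_day", 18, -3496.88, 7029.75, 1.82, 0.20),
        (3, "snowfall_category + time_of_day + snow_depth", 13, -3501.95, 7029.90, 1.98, 0.19),
        (4, "snowfall_category * time_of_day + snow_depth", 19, -3496.85, 7031.71, 3.78, 0.08),
        (5, "time_of_day", 6, -3511.88, 7035.76, 7.83, 0.01),
        (6, "snowfall_category", 11, -3507.28, 7036.55, 8.62, 0.01),
        (7, "time_of_day + snow_depth", 7, -3511.75, 7037.50, 9.57, 0.00),
        (8, "snowfall_category + snow_depth", 12, -3507.26, 7038.52, 10.60, 0.00),
        (9, "Null model", 5, -3517.27, 7044.54, 16.61, 0.00),
        (10, "snow_depth", 6, -3517.15, 7046.30, 18.37, 0.00),
    ],
    columns=["rank", "formula", "K", "logL", "AIC", "delta_AIC", "weight"],
)

# Travel-probability selection table (logistic GLMM; by-wolf random intercept).
TRAVEL_SELECTION_PRINTED = pd.DataFrame(
    [
        (1, "snowfall_category * time_of_day + snow_depth", 16, -10769.14, 21570.28, 0.00, 0.62, False),
        (2, "snowfall_category * time_of_day", 15, -10770.63, 21571.25, 0.97, 0.38, False),
        (3, "snowfall_category + time_of_day + snow_depth", 10, -10787.63, 21595.25, 24.97, 0.00, False),
        (4, "snowfall_category + time_of_day", 9, -10789.12, 21596.24, 25.96, 0.00, False),
        (5, "time_of_day + snow_depth", 4, -10799.45, 21606.90, 36.62, 0.00, False),
        (6, "time_of_day", 3, -10800.63, 21607.26, 36.98, 0.00, False),
        (7, "snowfall_category + snow_depth", 9, -10796.56, 21611.13, 40.85, 0.00, False),
        (8, "snowfall_category * time_of_day + snow_depth", 8, -10798.37, 21612.73, 42.45, 0.00, True),
        (9, "snow_depth", 3, -10808.26, 21622.53, 52.25, 0.00, False),
        (10, "Null model", 2, -10809.69, 21623.37, 53.09, 0.00, False),
    ],
    columns=["rank", "formula", "K", "logL", "AIC", "delta_AIC", "weight", "typo_suspect"],
)

# Final travel-speed model coefficients (log10 scale) with the published
# back-transforms 10^x and bootstrap CI limits (transformed scale).
SPEED_COEFFICIENTS_PRINTED = pd.DataFrame(
    [
        ("Intercept", 1.081, 0.026, 12.049, 10.701, 13.609),
        ("time_of_day: night", 0.107, 0.028, 1.280, 1.130, 1.459),
        ("snowfall_category: control", 0.061, 0.023, 1.152, 1.037, 1.273),
        ("snowfall_category: two_before", 0.037, 0.023, 1.088, 0.981, 1.211),
        ("snowfall_category: one_before", 0.045, 0.021, 1.110, 1.006, 1.222),
        ("snowfall_category: one_after", 0.005, 0.022, 1.012, 0.914, 1.116),
        ("snowfall_category: two_after", 0.041, 0.022, 1.099, 0.995, 1.210),
        ("snowfall_category: three_after", -0.016, 0.022, 0.964, 0.874, 1.064),
    ],
    columns=["term", "beta", "se", "beta_transformed", "ci_lower_transformed", "ci_upper_transformed"],
)

# Final travel-probability model coefficients (logit scale) with exp(x)
# back-transforms and transformed bootstrap CI limits.
TRAVEL_COEFFICIENTS_PRINTED = pd.DataFrame(
    [
        ("Intercept", -0.467, 0.079, 0.627, 0.544, 0.725),
        ("time_of_day: night", -0.542, 0.086, 0.582, 0.507, 0.664),
        ("night x control", 0.563, 0.125, 1.756, 1.425, 2.187),
        ("night x two_before", 0.456, 0.130, 1.578, 1.267, 1.969),
        ("night x one_before", 0.365, 0.121, 1.440, 1.172, 1.771),
        ("night x one_after", 0.268, 0.123, 1.307, 1.063, 1.608),
        ("night x two_after", 0.621, 0.123, 1.862, 1.507, 2.316),
        ("night x three_after", 0.546, 0.122, 1.726, 1.410, 2.138),
        ("snowfall_category: control", -0.243, 0.096, 0.784, 0.658, 0.926),
        ("snowfall_category: two_before", -0.201, 0.100, 0.818, 0.681, 0.975),
        ("snowfall_category: one_before", -0.026, 0.094, 0.974, 0.821, 1.153),
        ("snowfall_category: one_after", -0.025, 0.094, 0.975, 0.820, 1.159),
        ("snowfall_category: two_after", -0.169, 0.096, 0.845, 0.709, 1.006),
        ("snowfall_category: three_after", -0.095, 0.095, 0.909, 0.763, 1.074),
    ],
    columns=["term", "beta", "se", "beta_transformed", "ci_lower_transformed", "ci_upper_transformed"],
)

# Headline descriptive statistics the study reported from its raw data.
REFERENCE_SUMMARIES = {
    "n_wolves": 17,
    "n_unique_snowfall_events": 19,
    "rest_travel_cutoff_m_per_min": 1.65,
    "mean_travel_speed_night_m_per_min": 26.3,
    "mean_travel_speed_day_m_per_min": 20.3,
    "travel_proportion_event_night": 0.27,
    "event_day_distance_km_per_day": 10.06,
    "max_event_accumulation_cm": 16,
}
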