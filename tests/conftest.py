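import numpy as np
import pandas as pd
import pytest

from wolfsnow import behavior, snow, synthetic, telemetry, windows

CATS = ["day_of_snowfall", "control", "two_before", "one_before",
        "one_after", "two_after", "three_after"]


def make_mixed_dataset(seed=42, n_wolves=8, n_per_wolf=150,
                       beta_night_logit=-0.5, beta_cat_logit=0.15,
                       beta_night_lmm=0.1, re_sd_logit=0.4,
                       lmm_cat_ref=-0.05, lmm_cat_other=0.02):
    """Small balanced dataset from a known mixed model, for fitting tests.

    Travel is Bernoulli with a by-wolf random intercept; log10 speed is
    normal with a by-wolf random intercept and night slope. Categories are
    uniform over the seven levels, so every contrast is estimable.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for w in range(n_wolves):
        b_beh = rng.normal(0, re_sd_logit)
        b_spd = rng.normal(0, 0.12)
        b_spd_night = rng.normal(0, 0.06)
        for _ in range(n_per_wolf):
            night = rng.random() < 0.55
            cat = CATS[rng.integers(0, len(CATS))]
            depth = float(rng.integers(20, 80))
            lp = -0.4 + b_beh + beta_night_logit * night + (
                0.0 if cat == "day_of_snowfall" else beta_cat_logit
            )
            travel = rng.random() < 1 / (1 + np.exp(-lp))
            mu = 1.1 + b_spd + (beta_night_lmm + b_spd_night) * night + (
                lmm_cat_ref if cat == "day_of_snowfall" else lmm_cat_other
            )
            log_speed = rng.normal(mu, 0.35)
            rows.append({
                "wolf_id": f"W{w:02d}",
                "time_of_day": "night" if night else "day",
                "snowfall_category": cat,
                "depth_cm": depth,
                "travel": int(travel),
                "behavior": "travel" if travel else "rest",
                "log10_speed": log_speed,
                "speed_m_min": 10.0 ** log_speed,
            })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def sim_config():
    return synthetic.SimConfig(n_wolves=5, n_days=25, seed=11)


@pytest.fixture(scope="session")
def snow_sim(sim_config):
    return synthetic.simulate_snow_series(sim_config)


@pytest.fixture(scope="session")
def track_sim(sim_config, snow_sim):
    return synthetic.simulate_wolf_tracks(sim_config, snow_sim)


@pytest.fixture(scope="session")
def labeled_steps(track_sim):
    thinned = telemetry.thin_to_interval(track_sim.fixes)
    steps = telemetry.compute_steps(thinned)
    logs = np.log10(np.maximum(steps["speed_m_min"].to_numpy(float),
                               behavior.DEFAULT_SPEED_FLOOR_M_PER_MIN))
    mix = behavior.fit_mixture(logs)
    cut = behavior.find_intersection(mix)
    return behavior.classify_steps(steps, cut.value_m_per_min)


@pytest.fixture(scope="session")
def analysis_dataset(sim_config, snow_sim, track_sim, labeled_steps):
    daily = snow.build_snow_daily(snow_sim.deployments, snow_sim.readings)
    thinned = telemetry.thin_to_interval(track_sim.fixes)
    cents = telemetry.daily_centroids(thinned)
    wolf_day = snow.join_wolf_day(cents, daily, snow_sim.deployments)
    ds = windows.build_analysis_dataset(labeled_steps, wolf_day, seed=7)
    return ds[ds["depth_cm"].notna()].reset_index(drop=True)
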