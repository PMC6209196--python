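"""Snowfall categories, randomized control dates, and the analysis dataset.

Every wolf-day is positioned relative to that wolf's snowfall-event dates
(camera days on which its nearest camera recorded >= 5 cm of accumulation).
Six date-based, 24-h categories span two days before an event through three
days after — the longest window that avoids overlap between consecutive
events — and a seventh "control" category holds randomly sampled dates well
outside all windows (at least three days before or four days after every
event). Days in no category and no control draw stay "unassigned" and are
excluded from modeling.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORY_ORDER",
    "WINDOW_OFFSETS",
    "assign_snowfall_categories",
    "sample_controls",
    "build_analysis_dataset",
]

#: Offset (days relative to an event date) -> category label.
WINDOW_OFFSETS = {
    -2: "two_before",
    -1: "one_before",
    0: "day_of_snowfall",
    1: "one_after",
    2: "two_after",
    3: "three_after",
}

#: Reference-level-first ordering used throughout model design matrices.
CATEGORY_ORDER = [
    "day_of_snowfall", "control", "two_before", "one_before",
    "one_after", "two_after", "three_after",
]

#: Control eligibility: date <= event-3 or date >= event+4 for every event.
CONTROL_GAP_BEFORE = 3
CONTROL_GAP_AFTER = 4


def assign_snowfall_categories(event_dates, wolf_days) -> dict:
    """Map each wolf-day date to its snowfall category.

    ``event_dates`` are one wolf's event camera-days; ``wolf_days`` the dates
    with telemetry for that wolf. A date within the [-2, +3]-day window of an
    event takes the category of its offset from the *nearest* event (ties in
    distance resolved to the earlier event); an event date is always
    ``day_of_snowfall`` no matter what other events' windows cover it. Dates
    in no window map to ``"unassigned"``.
    """
    events = sorted(set(event_dates))
    out = {}
    for d in wolf_days:
        if d in events:
            out[d] = "day_of_snowfall"
            continue
        best = None  # (abs distance, event date, offset)
        for e in events:
            off = (d - e).days
            if off in WINDOW_OFFSETS:
                key = (abs(off), e)
                if best is None or key < best[0]:
                    best = (key, off)
        out[d] = WINDOW_OFFSETS[best[1]] if best else "unassigned"
    return out


def control_eligible(date, event_dates) -> bool:
    """True iff the date is far enough from every event to act as a control."""
    return all(
        (e - date).days >= CONTROL_GAP_BEFORE or (date - e).days >= CONTROL_GAP_AFTER
        for e in event_dates
    )


def sample_controls(wolf_days, event_dates, n_controls: int = 3, seed=None,
                    rng: np.random.Generator | None = None) -> list:
    """Sample control dates for one wolf, uniformly without replacement.

    Eligible dates have telemetry and lie at least ``CONTROL_GAP_BEFORE`` days
    before or ``CONTROL_GAP_AFTER`` days after every one of the wolf's events.
    If fewer than ``n_controls`` dates are eligible, all of them are taken
    (zero eligible yields an empty list with a warning).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    eligible = sorted(d for d in set(wolf_days) if control_eligible(d, event_dates))
    if not eligible:
        logger.warning("no control-eligible dates (all telemetry within event windows)")
        return []
    k = min(n_controls, len(eligible))
    picked = rng.choice(len(eligible), size=k, replace=False)
    return sorted(eligible[i] for i in picked)


def build_analysis_dataset(
    steps: pd.DataFrame,
    wolf_day_snow: pd.DataFrame,
    n_controls: int = 3,
    seed: int = 0,
    drop_unassigned: bool = True,
    controls_per_event: bool = False,
) -> pd.DataFrame:
    """Assemble the modeling table: one row per classified step.

    Joins the labeled steps with per-wolf-day snow values, assigns snowfall
    categories from each wolf's event dates, and samples ``n_controls``
    control dates per wolf (seeded; one RNG substream per wolf so adding a
    wolf never disturbs another wolf's draw). With ``controls_per_event`` the
    draw is ``n_controls`` per event instead of per winter. Rows lacking both a category
    and a snow-depth value are always omitted; category-less rows are dropped
    entirely when ``drop_unassigned`` (the default), since all candidate
    models must be fit on a single common dataset with the seven category
    levels.

    Raises
    ------
    ValueError
        If no rows remain — usually a sign the event threshold, window, or
        simulation parameters left nothing categorized.
    """
    rows = steps.merge(
        wolf_day_snow[["wolf_id", "camera_day", "camera_id", "depth_cm", "accumulation_cm", "is_event"]],
        on=["wolf_id", "camera_day"], how="left",
    )

    cats = {}
    root = np.random.SeedSequence(seed)
    wolves = sorted(rows["wolf_id"].unique())
    streams = root.spawn(len(wolves))
    for wolf, stream in zip(wolves, streams):
        sub = wolf_day_snow[wolf_day_snow["wolf_id"] == wolf]
        event_dates = sorted(sub.loc[sub["is_event"].fillna(False).astype(bool), "camera_day"])
        wolf_days = sorted(rows.loc[rows["wolf_id"] == wolf, "camera_day"].unique())
        mapping = assign_snowfall_categories(event_dates, wolf_days)
        n_draw = n_controls * max(1, len(event_dates)) if controls_per_event else n_controls
        controls = sample_controls(
            [d for d, c in mapping.items() if c == "unassigned"],
            event_dates, n_controls=n_draw, rng=np.random.default_rng(stream),
        )
        for d in controls:
            mapping[d] = "control"
        cats[wolf] = mapping

    rows["snowfall_category"] = [
        cats[w].get(d, "unassigned") for w, d in zip(rows["wolf_id"], rows["camera_day"])
    ]

    no_cat = rows["snowfall_category"] == "unassigned"
    no_depth = rows["depth_cm"].isna()
    omitted = no_cat & no_depth
    if omitted.any():
        logger.info("omitted %d rows with neither category nor snow depth (%.2f%%)",
                    int(omitted.sum()), 100 * omitted.mean())
    rows = rows[~omitted]
    if drop_unassigned:
        rows = rows[rows["snowfall_category"] != "unassigned"]
    rows = rows.reset_index(drop=True)
    if rows.empty:
        raise ValueError(
            "analysis dataset is empty; review the event threshold, window "
            "parameters, or simulation settings"
        )
    counts = rows["snowfall_category"].value_counts()
    logger.info("analysis dataset: %d rows; per-category counts: %s",
                len(rows), counts.to_dict())
    keep = [
        "wolf_id", "camera_day", "time_of_day", "behavior", "travel",
        "speed_m_min", "log10_speed", "snowfall_category", "depth_cm",
        "accumulation_cm", "camera_id",
    ]
    return rows[[c for c in keep if c in rows.columns]]
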