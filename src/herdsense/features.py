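"""Daily behavioral characteristics and variance decomposition.

Derives one row per cow-day holding the daily feeding, rumination, and
milk characteristics, per-cow feeding-rate slopes, the lameness
categorization from four locomotion scores, and the inter-/intra-
individual coefficient-of-variation table.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .feedclean import origin_slope

__all__ = [
    "daily_summaries",
    "cow_feeding_rate",
    "categorize_lameness",
    "cv_decomposition",
    "unaccounted_feed",
    "eating_time",
    "DAILY_CHARACTERISTICS",
]

#: Table-style daily characteristic columns produced by daily_summaries
DAILY_CHARACTERISTICS = (
    "dMY", "dFMI", "dFtime", "dFfreq", "mvFMI", "mvFdur", "dFR",
    "dRUMtime", "dRUMfreq", "meRUMdur",
)


def categorize_lameness(scores) -> tuple[bool, float]:
    """Classify a cow from four locomotion scores (1-5 scale).

    A cow is lame when at least three of the four scores are >= 3 (the
    majority convention covers a cow treated mid-study).  Returns
    ``(lame, mean_locomotion)``.
    """
    s = np.asarray(scores, dtype=float)
    if s.shape != (4,) or np.any(~np.isfinite(s)):
        raise ValueError("exactly four locomotion scores are required")
    if np.any((s < 1) | (s > 5)):
        raise ValueError("locomotion scores must be in 1..5")
    lame = int((s >= 3).sum()) >= 3
    return bool(lame), float(s.mean())


def daily_summaries(visits: pd.DataFrame, rum_events: pd.DataFrame,
                    milk: pd.DataFrame, cohort: pd.DataFrame,
                    exclude_days: set[int] | None = None) -> pd.DataFrame:
    """Aggregate cleaned visits, rumination events, and milk to cow-days.

    ``dFMI`` sums intake (kg), ``dFtime`` sums durations (min), ``dFfreq``
    counts visits, ``mvFMI``/``mvFdur`` are per-visit means, and ``dFR``
    is the daily rate 1000*dFMI/dFtime (g/min); rumination analogues come
    from the event list.  Cow-days with no visits keep zeros for the sums
    and missing per-visit means.  Boundary days can be masked out via
    *exclude_days*.
    """
    exclude_days = exclude_days or set()

    days = set()
    for df in (visits, rum_events, milk):
        if len(df):
            days.update(df["day"].unique().tolist())
    days = sorted(d for d in days if d not in exclude_days)
    idx = pd.MultiIndex.from_product(
        [cohort["cow_id"].tolist(), days], names=["cow_id", "day"])
    out = pd.DataFrame(index=idx)

    if len(visits):
        v = visits[~visits["day"].isin(exclude_days)]
        agg = v.groupby(["cow_id", "day"]).agg(
            dFMI=("fmi_kg", "sum"),
            dur_s=("duration_s", "sum"),
            dFfreq=("fmi_kg", "size"),
            mvFdur=("duration_s", "mean"),
        )
        out = out.join(agg)
    else:
        out[["dFMI", "dur_s", "dFfreq", "mvFdur"]] = np.nan
    out["dFMI"] = out["dFMI"].fillna(0.0)
    out["dFfreq"] = out["dFfreq"].fillna(0).astype(int)
    out["dFtime"] = out["dur_s"].fillna(0.0) / 60.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out["mvFMI"] = np.where(out["dFfreq"] > 0,
                                out["dFMI"] / out["dFfreq"], np.nan)
        out["dFR"] = np.where(out["dFtime"] > 0,
                              1000.0 * out["dFMI"] / out["dFtime"], np.nan)
    out = out.drop(columns=["dur_s"])

    if len(rum_events):
        r = rum_events[~rum_events["day"].isin(exclude_days)]
        ragg = r.groupby(["cow_id", "day"]).agg(
            dRUMtime=("duration_min", "sum"),
            dRUMfreq=("duration_min", "size"),
            meRUMdur=("duration_min", "mean"),
        )
        out = out.join(ragg)
    else:
        out[["dRUMtime", "dRUMfreq", "meRUMdur"]] = np.nan
    out["dRUMtime"] = out["dRUMtime"].fillna(0.0)
    out["dRUMfreq"] = out["dRUMfreq"].fillna(0).astype(int)

    if len(milk):
        m = milk[~milk["day"].isin(exclude_days)]
        out = out.join(m.set_index(["cow_id", "day"])["yield_l"]
                       .rename("dMY"))
    else:
        out["dMY"] = np.nan

    out = out.reset_index()
    cow_cols = ["cow_id", "dim_start", "lame", "mean_locomotion"]
    out = out.merge(cohort[cow_cols], on="cow_id", how="left")
    out["dim"] = out["dim_start"] + out["day"] - 1
    out = out.drop(columns=["dim_start"])
    cols = ["cow_id", "day", "dim", "lame", "mean_locomotion",
            "dMY", "dFMI", "dFtime", "dFfreq", "mvFMI", "mvFdur", "dFR",
            "dRUMtime", "dRUMfreq", "meRUMdur"]
    return out[cols]


def cow_feeding_rate(visits: pd.DataFrame) -> float:
    """Overall feeding rate of one cow (g/min): origin-regression slope of
    visit intake on visit duration, converted from kg/s."""
    slope_kg_s, _ = origin_slope(visits["duration_s"].to_numpy(),
                                 visits["fmi_kg"].to_numpy())
    return 60_000.0 * slope_kg_s


def cv_decomposition(daily: pd.DataFrame,
                     characteristics=DAILY_CHARACTERISTICS) -> pd.DataFrame:
    """Inter- and intra-individual mean/SD/CV per characteristic and group.

    Inter-individual statistics weight each cow equally (computed over
    per-cow means across days); intra-individual SD and CV are per-cow
    across-day values averaged over cows, while the intra mean pools all
    cow-days.  Returns a tidy frame with one row per characteristic and
    lameness group.
    """
    rows = []
    for char in characteristics:
        if char not in daily.columns:
            continue
        for lame, grp in daily.groupby("lame"):
            vals = grp[["cow_id", char]].dropna()
            by_cow = vals.groupby("cow_id")[char]
            cow_means = by_cow.mean()
            cow_sds = by_cow.std(ddof=1)
            inter_mean = float(cow_means.mean())
            inter_sd = float(cow_means.std(ddof=1)) \
                if len(cow_means) > 1 else np.nan
            cow_cvs = 100.0 * cow_sds / cow_means
            rows.append({
                "characteristic": char,
                "group": "lame" if lame else "nonlame",
                "inter_mean": inter_mean,
                "inter_sd": inter_sd,
                "inter_cv": 100.0 * inter_sd / inter_mean
                if inter_mean else np.nan,
                "intra_mean": float(vals[char].mean()),
                "intra_sd": float(cow_sds.mean()),
                "intra_cv": float(cow_cvs.mean()),
                "n_cows": int(len(cow_means)),
                "n_cow_days": int(len(vals)),
            })
    return pd.DataFrame(rows)


def unaccounted_feed(mean_loss_per_station: float, n_stations: int,
                     n_cows: int) -> float:
    """Unassigned feed per cow (kg/day) from the station reset-window
    mass balance."""
    if mean_loss_per_station < 0 or n_stations <= 0 or n_cows <= 0:
        raise ValueError("inputs must be positive")
    return mean_loss_per_station * n_stations / n_cows


def eating_time(mass_kg: float, rate_g_per_min: float) -> float:
    """Minutes needed to eat *mass_kg* at *rate_g_per_min*."""
    if rate_g_per_min <= 0:
        raise ValueError("feeding rate must be > 0")
    if mass_kg < 0:
        raise ValueError("mass must be >= 0")
    return 1000.0 * mass_kg / rate_g_per_min
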