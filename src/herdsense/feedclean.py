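"""Two-pass cleaning of feed-station visit records.

The pipeline per cow:

1. drop zero-duration visits;
2. regress intake on duration through the origin, flag visits more than
   ``k`` residual SDs off the line or shorter than 4 s with intake above
   0.1 kg;
3. refit the origin regression on the unflagged visits;
4. replace the offending field of every flagged visit — and of any visit
   newly beyond ``k`` SDs of the second line — from the second slope:
   intake for large/negative-intake visits, duration for long low-intake
   visits and for the sub-4 s high-intake visits.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CleaningReport",
    "drop_zero_duration",
    "origin_slope",
    "first_check",
    "second_check_and_replace",
    "clean",
]

SHORT_VISIT_S = 4.0
SHORT_VISIT_FMI_KG = 0.1
LARGE_FMI_KG = 5.0


@dataclass
class CleaningReport:
    """Counts and per-cow regression diagnostics from one cleaning run."""

    n_input: int = 0
    n_zero_duration_excluded: int = 0
    n_outliers_pass1: int = 0
    n_fmi_replaced: int = 0
    n_duration_replaced: int = 0
    slopes_pass1: dict = field(default_factory=dict)   # cow -> kg/s
    slopes_pass2: dict = field(default_factory=dict)
    resid_sd_pass1: dict = field(default_factory=dict)
    resid_sd_pass2: dict = field(default_factory=dict)
    skipped_cows: list = field(default_factory=list)

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


def drop_zero_duration(visits: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Exclude visits with duration 0 s; return (kept, n_excluded).

    The original row index is preserved so cleaned rows can be traced
    back to their inputs.
    """
    mask = visits["duration_s"] > 0
    return visits[mask], int((~mask).sum())


def origin_slope(duration_s: np.ndarray, fmi_kg: np.ndarray,
                 ) -> tuple[float, float]:
    """Least-squares slope of intake on duration through the origin.

    Returns ``(slope_kg_per_s, residual_sd)``.  Requires at least two
    visits with positive duration.
    """
    d = np.asarray(duration_s, dtype=float)
    f = np.asarray(fmi_kg, dtype=float)
    use = d > 0
    if use.sum() < 2:
        raise ValueError("need >= 2 visits with positive duration")
    d, f = d[use], f[use]
    slope = float(np.sum(d * f) / np.sum(d * d))
    resid = f - slope * d
    sd = float(np.std(resid, ddof=1)) if len(resid) > 1 else 0.0
    return slope, sd


def first_check(duration_s: np.ndarray, fmi_kg: np.ndarray, slope: float,
                resid_sd: float, k: float = 5.0) -> np.ndarray:
    """Boolean mask of first-pass outliers for one cow.

    Rule 1: residual from the origin line beyond ``k`` residual SDs (if
    the residual SD is exactly zero, any off-line visit is flagged).
    Rule 2: duration < 4 s with intake > 0.1 kg.
    """
    d = np.asarray(duration_s, dtype=float)
    f = np.asarray(fmi_kg, dtype=float)
    resid = f - slope * d
    if resid_sd > 0:
        rule1 = np.abs(resid) > k * resid_sd
    else:
        rule1 = np.abs(resid) > 1e-12
    rule2 = (d < SHORT_VISIT_S) & (f > SHORT_VISIT_FMI_KG)
    return rule1 | rule2


def second_check_and_replace(cow_visits: pd.DataFrame, flagged: np.ndarray,
                             k: float = 5.0,
                             ) -> tuple[pd.DataFrame, dict]:
    """Refit on unflagged visits and replace offending fields.

    Flagged visits plus any visit beyond ``k`` SDs of the second line are
    replaced case by case from the second slope: a sub-4 s visit with
    intake above 0.1 kg gets its duration replaced; a large (>5 kg or
    > +k SD) or negative intake gets its intake replaced; a long visit
    with low intake (< -k SD) gets its duration replaced.  The untouched
    field is preserved bitwise.
    """
    out = cow_visits.copy()
    d = out["duration_s"].to_numpy(dtype=float)
    f = out["fmi_kg"].to_numpy(dtype=float)
    info = {"slope2": np.nan, "resid_sd2": np.nan,
            "n_fmi": 0, "n_duration": 0, "failed": False}

    keep = ~flagged
    if keep.sum() < 2:
        info["failed"] = True
        return out, info
    slope2, sd2 = origin_slope(d[keep], f[keep])
    info["slope2"], info["resid_sd2"] = slope2, sd2
    if slope2 <= 0:
        info["failed"] = True
        return out, info

    resid2 = f - slope2 * d
    if sd2 > 0:
        dev2 = np.abs(resid2) > k * sd2
    else:
        dev2 = np.abs(resid2) > 1e-12
    # a negative intake is always in the "large or negative FMI" case,
    # whatever the residual spread
    target = flagged | dev2 | (f < 0)

    replaced = out["replaced_field"].to_numpy(dtype=object) \
        if "replaced_field" in out else np.full(len(out), "none", dtype=object)
    for i in np.nonzero(target)[0]:
        if d[i] < SHORT_VISIT_S and f[i] > SHORT_VISIT_FMI_KG:
            d[i] = f[i] / slope2
            replaced[i] = "duration"
            info["n_duration"] += 1
        elif f[i] < 0 or f[i] > LARGE_FMI_KG or resid2[i] > 0:
            f[i] = slope2 * d[i]
            replaced[i] = "fmi"
            info["n_fmi"] += 1
        else:  # long visit with low intake
            d[i] = f[i] / slope2
            replaced[i] = "duration"
            info["n_duration"] += 1
    out["duration_s"] = d
    out["fmi_kg"] = f
    out["replaced_field"] = replaced
    return out, info


def clean(visits: pd.DataFrame, k: float = 5.0,
          ) -> tuple[pd.DataFrame, CleaningReport]:
    """Run the full two-pass cleaning over all cows.

    Cows with fewer than two usable visits are passed through unchanged
    and listed in ``report.skipped_cows``.
    """
    report = CleaningReport(n_input=len(visits))
    if "replaced_field" not in visits.columns:
        visits = visits.assign(replaced_field="none")
    kept, n_zero = drop_zero_duration(visits)
    report.n_zero_duration_excluded = n_zero

    pieces = []
    for cow_id, grp in kept.groupby("cow_id", sort=True):
        d = grp["duration_s"].to_numpy(dtype=float)
        f = grp["fmi_kg"].to_numpy(dtype=float)
        usable = (d > 0) & (f > 0)
        if usable.sum() < 2:
            report.skipped_cows.append(cow_id)
            pieces.append(grp)
            continue
        slope1, sd1 = origin_slope(d, f)
        report.slopes_pass1[cow_id] = slope1
        report.resid_sd_pass1[cow_id] = sd1
        flagged = first_check(d, f, slope1, sd1, k=k)
        report.n_outliers_pass1 += int(flagged.sum())
        fixed, info = second_check_and_replace(grp, flagged, k=k)
        if info["failed"]:
            report.skipped_cows.append(cow_id)
            pieces.append(grp)
            continue
        report.slopes_pass2[cow_id] = info["slope2"]
        report.resid_sd_pass2[cow_id] = info["resid_sd2"]
        report.n_fmi_replaced += info["n_fmi"]
        report.n_duration_replaced += info["n_duration"]
        pieces.append(fixed)
    out = pd.concat(pieces, ignore_index=False).sort_index() if pieces \
        else kept
    return out, report
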