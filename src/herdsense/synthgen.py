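"""Synthetic barn generator.

Produces a cohort of cows, a feed-station visit stream, milk yields, and a
rumination event schedule whose group-level statistics are calibrated to
the published 16-cow study, plus optional contamination to exercise the
visit-cleaning algorithm.

All tables are pandas DataFrames:

``cohort``
    one row per cow: ``cow_id, parity, dim_start, lame, loc1..loc4,
    mean_locomotion, true_feeding_rate, true_visits_per_day,
    true_rumination_time, true_rum_freq, true_fmi, milk_level``
``visits``
    one row per feed-station visit: ``cow_id, station_id, day, start_s,
    duration_s, fmi_kg, artifact, replaced_field``
``milk``
    ``cow_id, day, yield_l``
``rum_events``
    ``cow_id, day, start_s, end_s, duration_min``
``unassigned``
    ``station_id, day, kg`` — feed eaten during the reset window that the
    stations never assigned to a cow.
"""
from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    DAY_S,
    MILKING_WINDOWS,
    RESET_WINDOW,
    GeneratorConfig,
    TraitParams,
)

__all__ = [
    "Barn",
    "make_cohort",
    "simulate_visits",
    "simulate_milk",
    "simulate_rumination_schedule",
    "inject_artifacts",
    "parlor_concentrate",
    "generate",
    "save_barn",
    "load_barn",
]

# allowed start times for visits: the day minus milking and reset windows
_BLOCKED = tuple(sorted(MILKING_WINDOWS + (RESET_WINDOW,)))


def _allowed_intervals() -> list[tuple[int, int]]:
    out, cur = [], 0
    for lo, hi in _BLOCKED:
        if lo > cur:
            out.append((cur, lo))
        cur = max(cur, hi)
    if cur < DAY_S:
        out.append((cur, DAY_S))
    return out


_ALLOWED = _allowed_intervals()
_ALLOWED_LEN = np.array([hi - lo for lo, hi in _ALLOWED], dtype=float)
_ALLOWED_CUM = np.concatenate([[0.0], np.cumsum(_ALLOWED_LEN)])


def _sample_start_times(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform start times over the non-blocked part of the day."""
    u = rng.uniform(0.0, _ALLOWED_CUM[-1], size=n)
    idx = np.searchsorted(_ALLOWED_CUM, u, side="right") - 1
    idx = np.clip(idx, 0, len(_ALLOWED) - 1)
    starts = np.array([_ALLOWED[i][0] for i in idx]) + (u - _ALLOWED_CUM[idx])
    return np.sort(starts)


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Lognormal with the requested arithmetic mean and SD (moment match)."""
    if mean <= 0:
        raise ValueError("lognormal mean must be > 0")
    if sd <= 0:
        return np.full(size, float(mean)) if size is not None else float(mean)
    s2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - s2 / 2.0
    return rng.lognormal(mu, math.sqrt(s2), size)


def _lognoise(rng: np.random.Generator, cv_pct: float, size=None):
    """Multiplicative mean-1 lognormal noise with the given CV (%)."""
    if cv_pct <= 0:
        return np.ones(size) if size is not None else 1.0
    return _lognormal(rng, 1.0, cv_pct / 100.0, size)


def _trait(rng, params: TraitParams, size=None):
    return _lognormal(rng, params.mean, params.inter_sd, size)


# ---------------------------------------------------------------------------
# cohort


def make_cohort(config: GeneratorConfig, n_cows: int | None = None,
                rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a cohort of cow profiles from the configured group distributions.

    Locomotion scores are generated consistent with the lameness label:
    non-lame cows score 1-2 on all four occasions, lame cows score 3-5.
    """
    if n_cows is None:
        n_cows = config.n_cows
    if n_cows < 2:
        raise ValueError("n_cows must be >= 2")
    if config.n_cows != n_cows:
        raise ValueError(
            f"group sizes ({config.n_nonlame}+{config.n_lame}) "
            f"do not sum to n_cows={n_cows}"
        )
    rng = np.random.default_rng(config.seed) if rng is None else rng

    rows = []
    for cow_id in range(1, n_cows + 1):
        is_lame = cow_id > config.n_nonlame
        g = config.group(is_lame)
        if is_lame:
            scores = rng.choice([3, 4, 5], size=4, p=[0.55, 0.30, 0.15])
        else:
            scores = rng.choice([1, 2], size=4, p=[0.6, 0.4])
        dim = max(10.0, rng.normal(config.dim_mean, config.dim_sd))
        rumtime = max(0.0, rng.normal(g.rumtime.mean, g.rumtime.inter_sd))
        row = {
            "cow_id": cow_id,
            "parity": int(rng.choice([1, 2, 3, 4], p=[0.125, 0.375, 0.3, 0.2])),
            "dim_start": round(dim),
            "lame": bool(is_lame),
            "loc1": int(scores[0]),
            "loc2": int(scores[1]),
            "loc3": int(scores[2]),
            "loc4": int(scores[3]),
            "mean_locomotion": float(np.mean(scores)),
            "true_visits_per_day": float(_trait(rng, g.ffreq)),
            "true_rumination_time": rumtime,
            "true_rum_freq": float(_trait(rng, g.rumfreq)),
            "true_fmi": float(_trait(rng, g.fmi)),
            "milk_level": float(_trait(rng, g.milk)),
        }
        rows.append(row)
    cohort = pd.DataFrame(rows)

    if config.rate_model == "linear":
        dev = rng.normal(0.0, config.m3_cow_sd, size=n_cows)
        rate = (config.m3_base_rate
                + config.m3_rate_per_score * cohort["mean_locomotion"]
                + config.m3_rate_per_litre * cohort["milk_level"]
                + dev)
        cohort["true_feeding_rate"] = np.maximum(50.0, rate)
    else:
        rates = np.empty(n_cows)
        for i, is_lame in enumerate(cohort["lame"]):
            g = config.group(bool(is_lame))
            rates[i] = _trait(rng, g.frate)
        cohort["true_feeding_rate"] = rates

    # rumination-feeding couplings also hold between cows (centered on
    # the group means, so group-level rumination means are unchanged)
    adj = np.empty(n_cows)
    for i, is_lame in enumerate(cohort["lame"]):
        g = config.group(bool(is_lame))
        adj[i] = (config.rum_per_frate
                  * (cohort["true_feeding_rate"].iat[i] - g.frate.mean)
                  + config.rum_per_milk
                  * (cohort["milk_level"].iat[i] - g.milk.mean))
    cohort["true_rumination_time"] = np.maximum(
        0.0, cohort["true_rumination_time"] + adj)
    return cohort


# ---------------------------------------------------------------------------
# visits


def simulate_visits(cohort: pd.DataFrame, n_days: int, config: GeneratorConfig,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the feed-station visit stream.

    Per cow-day: the daily intake target and feeding rate are drawn around
    the cow's traits (with lactation-stage trend on intake), the visit
    count is Poisson, and the day's intake is split across visits.  Visits
    exceeding the 5 kg cap are truncated (door forced up) unless the cow
    overrides it.  No visit starts inside the station reset window; feed
    eaten there accrues to the per-station ``unassigned`` ledger.

    Returns ``(visits, unassigned, daily_truth)``.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng

    recs: list[dict] = []
    truth: list[dict] = []
    for cow in cohort.itertuples(index=False):
        g = config.group(bool(cow.lame))
        for day in range(1, n_days + 1):
            dim = cow.dim_start + (day - 1)
            fmi_target = (cow.true_fmi
                          + config.fmi_trend * (dim - config.dim_ref))
            fmi_target = max(1.0, fmi_target) * _lognoise(rng, g.fmi.intra_cv)
            rate = cow.true_feeding_rate * _lognoise(rng, g.frate.intra_cv)
            n = max(1, int(rng.poisson(cow.true_visits_per_day)))

            # split the day's feeding time across visits (normalized
            # gammas); intake then carries multiplicative noise around
            # rate * duration, so visit intake regressed on duration is
            # unbiased for the cow's rate
            time_min = 1000.0 * fmi_target / rate
            w = rng.gamma(config.visit_split_conc, 1.0, size=n)
            dur_min = time_min * w / w.sum()
            fmi = rate * dur_min / 1000.0 * _lognoise(
                rng, 100.0 * config.visit_noise_cv, size=n)

            # 5 kg cap: door opens; truncate the visit unless overridden
            over = fmi > config.cap_kg
            if over.any():
                keep = rng.random(n) < config.cap_override_p
                trunc = over & ~keep
                scale = np.where(trunc, config.cap_kg / fmi, 1.0)
                fmi = fmi * scale
                dur_min = dur_min * scale

            starts = _sample_start_times(rng, n)
            stations = rng.integers(1, config.n_stations + 1, size=n)
            for j in range(n):
                recs.append({
                    "cow_id": cow.cow_id,
                    "station_id": int(stations[j]),
                    "day": day,
                    "start_s": float(starts[j]),
                    "duration_s": float(dur_min[j] * 60.0),
                    "fmi_kg": float(fmi[j]),
                })
            truth.append({
                "cow_id": cow.cow_id, "day": day,
                "fmi_target": float(fmi_target), "rate": float(rate),
                "n_visits": n,
            })

    visits = pd.DataFrame(recs)
    visits["artifact"] = "none"
    visits["replaced_field"] = "none"

    n_days_range = np.arange(1, n_days + 1)
    stations = np.arange(1, config.n_stations + 1)
    sd = pd.MultiIndex.from_product([stations, n_days_range],
                                    names=["station_id", "day"]).to_frame(index=False)
    if config.reset_loss_kg > 0:
        sd["kg"] = rng.gamma(2.0, config.reset_loss_kg / 2.0, size=len(sd))
    else:
        sd["kg"] = 0.0
    return visits, sd, pd.DataFrame(truth)


def inject_artifacts(visits: pd.DataFrame, config: GeneratorConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Append labelled contaminating visits at the configured rates.

    Three artifact families: zero-duration visits, sub-4 s visits with
    intake above 0.1 kg, and visits far off the cow's intake-vs-duration
    line (including negative intakes).  Ground-truth labels are kept in
    the ``artifact`` column so cleaning can be scored.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    n = len(visits)
    if n == 0:
        return visits.copy()

    cow_rate = visits.groupby("cow_id")["fmi_kg"].sum() / \
        visits.groupby("cow_id")["duration_s"].sum()  # kg/s

    extra: list[dict] = []

    def _base_row(kind: str) -> dict:
        src = visits.iloc[int(rng.integers(0, n))]
        return {
            "cow_id": int(src["cow_id"]),
            "station_id": int(src["station_id"]),
            "day": int(src["day"]),
            "start_s": float(rng.uniform(0, DAY_S)),
            "artifact": kind,
            "replaced_field": "none",
        }

    for _ in range(rng.binomial(n, config.zero_duration_rate)):
        row = _base_row("zero_duration")
        row.update(duration_s=0.0, fmi_kg=0.0)
        extra.append(row)

    for _ in range(rng.binomial(n, config.short_high_rate)):
        row = _base_row("short_high")
        row.update(duration_s=float(rng.uniform(1.0, 3.5)),
                   fmi_kg=float(rng.uniform(0.15, 1.0)))
        extra.append(row)

    for _ in range(rng.binomial(n, config.rate_outlier_rate)):
        row = _base_row("rate_outlier")
        dur = float(rng.uniform(60.0, 600.0))
        on_line = cow_rate.loc[row["cow_id"]] * dur
        # push far off the line; half the outliers get a negative intake
        if rng.random() < 0.5:
            fmi = float(-rng.uniform(0.1, 1.0))
        else:
            fmi = float(on_line + rng.uniform(3.0, 8.0))
        row.update(duration_s=dur, fmi_kg=fmi)
        extra.append(row)

    if not extra:
        return visits.copy()
    out = pd.concat([visits, pd.DataFrame(extra)], ignore_index=True)
    return out.sample(frac=1.0, random_state=int(rng.integers(2**31))
                      ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# milk


def parlor_concentrate(milk_yield) -> float | np.ndarray:
    """Daily parlor concentrate allowance (kg/day) for a milk yield (l/day).

    0.6 kg/day base plus 1 kg/day per 3 l of milk above 30 l/day.
    """
    y = np.asarray(milk_yield, dtype=float)
    if np.any(y < 0):
        raise ValueError("milk yield must be >= 0")
    out = 0.6 + np.maximum(0.0, (y - 30.0) / 3.0)
    return float(out) if np.isscalar(milk_yield) else out


def simulate_milk(cohort: pd.DataFrame, n_days: int, config: GeneratorConfig,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Daily milk yields (sum of three milkings) with a lactation trend."""
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    rows = []
    for cow in cohort.itertuples(index=False):
        g = config.group(bool(cow.lame))
        for day in range(1, n_days + 1):
            if rng.random() < config.milk_missing_rate:
                continue
            dim = cow.dim_start + (day - 1)
            level = cow.milk_level + config.milk_trend * (dim - config.dim_ref)
            y = max(0.0, level) * _lognoise(rng, g.milk.intra_cv)
            rows.append({"cow_id": cow.cow_id, "day": day,
                         "yield_l": float(y)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rumination schedule


def _merge_intervals(iv: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for lo, hi in sorted(iv):
        if out and lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def _free_gaps(busy: list[tuple[float, float]]) -> list[tuple[float, float]]:
    gaps, cur = [], 0.0
    for lo, hi in busy:
        if lo > cur:
            gaps.append((cur, lo))
        cur = max(cur, hi)
    if cur < DAY_S:
        gaps.append((cur, DAY_S))
    return gaps


def _place_events(rng: np.random.Generator, busy: list[tuple[float, float]],
                  durations_s: np.ndarray) -> list[tuple[float, float]]:
    """Place non-overlapping events of given lengths into the free gaps.

    Each event is assigned its own gap (chosen with probability
    proportional to capacity); durations exceeding the gap are clipped
    and the excess redistributed to events with slack, so the total
    placed time matches the requested total whenever the free time
    allows it.
    """
    gaps = _free_gaps(_merge_intervals(busy))
    if not gaps or len(durations_s) == 0:
        return []
    caps = np.array([hi - lo for lo, hi in gaps], dtype=float)

    # first-fit-decreasing packing: several events may share one gap
    assigned: list[list[float]] = [[] for _ in gaps]
    remaining = caps.copy()
    for d in np.sort(np.asarray(durations_s, dtype=float))[::-1]:
        gi = int(np.argmax(remaining))  # largest slack first
        if remaining[gi] < d:
            d = remaining[gi]  # clip (only when the day is nearly full)
            if d <= 1.0:
                continue
        assigned[gi].append(float(d))
        remaining[gi] -= d

    # within each gap, spread its events with random separations
    placed: list[tuple[float, float]] = []
    for gi, durs in enumerate(assigned):
        if not durs:
            continue
        lo, hi = gaps[gi]
        slack = (hi - lo) - sum(durs)
        cuts = rng.dirichlet(np.ones(len(durs) + 1)) * max(0.0, slack)
        rng.shuffle(durs)
        cur = lo
        for d, c in zip(durs, cuts):
            cur += c
            placed.append((float(cur), float(cur + d)))
            cur += d
    return sorted(placed)


def simulate_rumination_schedule(
    cohort: pd.DataFrame, n_days: int, config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    visits: pd.DataFrame | None = None,
    daily_covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate per-cow rumination events.

    Event count per cow-day is Poisson around the cow's event frequency;
    the day's total rumination time is split over events via normalized
    gamma weights (mean duration ~= time/frequency ~= 20 min).  Events
    avoid the milking windows and, when *visits* is given, the cow's own
    feeding visits.  When *daily_covariates* (columns ``cow_id, day, dFR,
    dMY``) is given, the day's rumination time is shifted by the
    within-cow couplings ``rum_per_frate`` and ``rum_per_milk``.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng

    cov = None
    if daily_covariates is not None:
        cov = daily_covariates.set_index(["cow_id", "day"])

    vis_by = None
    if visits is not None and len(visits):
        vis_by = {k: g for k, g in visits.groupby(["cow_id", "day"])}

    rows = []
    for cow in cohort.itertuples(index=False):
        g = config.group(bool(cow.lame))
        for day in range(1, n_days + 1):
            target = cow.true_rumination_time
            if cov is not None and (cow.cow_id, day) in cov.index:
                c = cov.loc[(cow.cow_id, day)]
                if np.isfinite(c.get("dFR", np.nan)):
                    target += config.rum_per_frate * (
                        c["dFR"] - cow.true_feeding_rate)
                if np.isfinite(c.get("dMY", np.nan)):
                    dim = cow.dim_start + (day - 1)
                    expected_milk = cow.milk_level + config.milk_trend * (
                        dim - config.dim_ref)
                    target += config.rum_per_milk * (
                        c["dMY"] - expected_milk)
            target = max(0.0, target * _lognoise(rng, g.rumtime.intra_cv))
            n_ev = max(1, int(rng.poisson(cow.true_rum_freq)))
            w = rng.gamma(config.event_split_shape, 1.0, size=n_ev)
            dur_s = target * 60.0 * w / w.sum()

            busy = [(float(a), float(b)) for a, b in MILKING_WINDOWS]
            if vis_by is not None and (cow.cow_id, day) in vis_by:
                v = vis_by[(cow.cow_id, day)]
                busy += list(zip(v["start_s"], v["start_s"] + v["duration_s"]))
            for start, end in _place_events(rng, busy, dur_s):
                rows.append({
                    "cow_id": cow.cow_id, "day": day,
                    "start_s": float(start), "end_s": float(end),
                    "duration_min": float((end - start) / 60.0),
                })
    return pd.DataFrame(rows)


def _reassign_starts(visits: pd.DataFrame, rum_events: pd.DataFrame,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Re-draw visit start times so visits avoid the cow's rumination
    events (durations and intakes are untouched)."""
    out = visits.copy()
    starts = out["start_s"].to_numpy().copy()
    ev_by = {k: g for k, g in rum_events.groupby(["cow_id", "day"])} \
        if len(rum_events) else {}
    base_busy = [(float(a), float(b)) for a, b in _BLOCKED]
    for (cow, day), grp in out.groupby(["cow_id", "day"]):
        busy = list(base_busy)
        if (cow, day) in ev_by:
            ev = ev_by[(cow, day)]
            busy += list(zip(ev["start_s"], ev["end_s"]))
        pieces = _free_gaps(_merge_intervals(busy))
        idx = grp.index.to_numpy()
        durs = grp["duration_s"].to_numpy()
        for j in np.argsort(durs)[::-1]:
            d = durs[j]
            caps = np.array([hi - lo - d for lo, hi in pieces])
            feas = np.nonzero(caps >= 0)[0]
            if len(feas) == 0:
                # no room left: keep the original (possibly overlapping)
                continue
            w = caps[feas] + 1.0
            pi = int(feas[rng.choice(len(feas), p=w / w.sum())])
            lo, hi = pieces[pi]
            s = lo + rng.uniform(0.0, (hi - lo) - d)
            starts[idx[j]] = s
            new = pieces[:pi] + pieces[pi + 1:]
            if s - lo > 1.0:
                new.append((lo, s))
            if hi - (s + d) > 1.0:
                new.append((s + d, hi))
            pieces = new
    out["start_s"] = starts
    return out


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class Barn:
    """One realization of the synthetic barn."""

    cohort: pd.DataFrame
    visits: pd.DataFrame
    unassigned: pd.DataFrame
    milk: pd.DataFrame
    rum_events: pd.DataFrame
    daily_truth: pd.DataFrame
    config: GeneratorConfig
    seed: int
    n_days: int


def generate(config: GeneratorConfig, n_days: int = 22,
             seed: int | None = None) -> Barn:
    """Generate a full barn: cohort, visits, milk, rumination, ledger.

    Rumination couplings use the *realized* daily feeding rate and milk
    yield, so downstream model fits see the configured coefficients.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    cohort = make_cohort(config, rng=rng)
    visits, unassigned, truth = simulate_visits(cohort, n_days, config, rng=rng)
    daily = visits.groupby(["cow_id", "day"]).agg(
        fmi=("fmi_kg", "sum"), dur_s=("duration_s", "sum")).reset_index()
    daily["dFR"] = 1000.0 * daily["fmi"] / (daily["dur_s"] / 60.0)
    milk = simulate_milk(cohort, n_days, config, rng=rng)
    cov = daily.merge(milk.rename(columns={"yield_l": "dMY"}),
                      on=["cow_id", "day"], how="left")
    # rumination claims the day's big time blocks first; visits are then
    # re-slotted around the events (their durations/intakes unchanged)
    rum = simulate_rumination_schedule(
        cohort, n_days, config, rng=rng, daily_covariates=cov)
    visits = _reassign_starts(visits, rum, rng)
    visits = inject_artifacts(visits, config, rng=rng)
    return Barn(cohort=cohort, visits=visits, unassigned=unassigned,
                milk=milk, rum_events=rum, daily_truth=truth,
                config=config, seed=seed, n_days=n_days)


_EPOCH = pd.Timestamp("2014-06-23")  # "day 1" anchor for ISO timestamps


def _iso(day: pd.Series, sec: pd.Series) -> pd.Series:
    return (_EPOCH + pd.to_timedelta(day - 1, unit="D")
            + pd.to_timedelta(sec, unit="s")).dt.strftime("%Y-%m-%dT%H:%M:%S")


def save_barn(barn: Barn, outdir: str) -> dict[str, str]:
    """Write the barn as CSV files plus a provenance sidecar."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    visits = barn.visits.copy()
    visits["start"] = _iso(visits["day"], visits["start_s"])
    milk = barn.milk.copy()
    rum = barn.rum_events.copy()
    rum["start"] = _iso(rum["day"], rum["start_s"])
    rum["end"] = _iso(rum["day"], rum["end_s"])

    for name, df in (("cohort", barn.cohort), ("visits", visits),
                     ("milk", milk), ("rumination_truth", rum),
                     ("unassigned", barn.unassigned)):
        p = os.path.join(outdir, f"{name}.csv")
        df.to_csv(p, index=False)
        paths[name] = p

    cfg_path = os.path.join(outdir, "config.yaml")
    barn.config.to_yaml(cfg_path)
    paths["config"] = cfg_path
    prov = os.path.join(outdir, "provenance.json")
    with open(prov, "w") as fh:
        json.dump({"seed": barn.seed, "n_days": barn.n_days,
                   "n_cows": int(len(barn.cohort))}, fh, indent=2)
    paths["provenance"] = prov
    return paths


def load_barn(outdir: str) -> Barn:
    """Reload a barn written by :func:`save_barn`."""
    with open(os.path.join(outdir, "provenance.json")) as fh:
        prov = json.load(fh)
    config = GeneratorConfig.from_yaml(os.path.join(outdir, "config.yaml"))

    def _read(name):
        return pd.read_csv(os.path.join(outdir, f"{name}.csv"))

    visits = _read("visits").drop(columns=["start"], errors="ignore")
    rum = _read("rumination_truth").drop(columns=["start", "end"],
                                         errors="ignore")
    return Barn(cohort=_read("cohort"), visits=visits,
                unassigned=_read("unassigned"), milk=_read("milk"),
                rum_events=rum, daily_truth=pd.DataFrame(),
                config=config, seed=prov["seed"], n_days=prov["n_days"])
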