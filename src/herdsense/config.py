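"""Configuration for the synthetic barn generator.

Group-level trait means/SDs default to the published group-level summaries
for a 16-cow mixed-parity cohort (7 non-lame, 9 lame).  Every knob is a
plain dataclass field so configs round-trip through YAML.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

#: seconds in a barn day
DAY_S = 86_400

#: milking-parlor periods (seconds since midnight); cows are treated as
#: absent from the pen for the whole period: 0730-1000, 1430-1630, 2130-2330
MILKING_WINDOWS = ((27_000, 36_000), (52_200, 59_400), (77_400, 84_600))

#: daily feed-station reset window 1145-1215; no intake is assigned to cows
RESET_WINDOW = (42_300, 44_100)


@dataclass
class TraitParams:
    """Mean / between-cow SD / within-cow CV (%) for one daily trait."""

    mean: float
    inter_sd: float
    intra_cv: float

    def __post_init__(self) -> None:
        if self.inter_sd < 0 or self.intra_cv < 0:
            raise ValueError("trait SDs/CVs must be >= 0")


@dataclass
class GroupTraits:
    """Daily trait distributions for one lameness group."""

    ffreq: TraitParams    # feeding frequency, visits/day
    frate: TraitParams    # feeding rate, g/min
    fmi: TraitParams      # fresh-matter intake, kg/day
    rumtime: TraitParams  # rumination time, min/day
    rumfreq: TraitParams  # rumination frequency, events/day
    milk: TraitParams     # milk yield, l/day


def _default_nonlame() -> GroupTraits:
    return GroupTraits(
        ffreq=TraitParams(60.3, 10.1, 9.7),
        frate=TraitParams(206.0, 48.1, 7.0),
        fmi=TraitParams(39.4, 6.48, 6.1),
        rumtime=TraitParams(480.0, 73.6, 5.2),
        rumfreq=TraitParams(24.5, 4.79, 11.3),
        milk=TraitParams(18.8, 8.85, 14.5),
    )


def _default_lame() -> GroupTraits:
    return GroupTraits(
        ffreq=TraitParams(33.9, 17.8, 9.0),
        frate=TraitParams(289.0, 74.4, 5.8),
        fmi=TraitParams(33.8, 9.63, 9.6),
        rumtime=TraitParams(482.0, 46.4, 5.2),
        rumfreq=TraitParams(25.0, 4.26, 10.2),
        milk=TraitParams(25.9, 5.96, 5.5),
    )


@dataclass
class GeneratorConfig:
    """All parameters of the synthetic barn.

    ``rate_model`` selects how per-cow feeding rates arise: ``"group"``
    draws them from the lameness-group lognormals; ``"linear"`` builds
    them from the visit-level truth ``m3_base_rate + m3_rate_per_score *
    mean_locomotion + m3_rate_per_litre * milk`` plus a cow deviation.
    """

    nonlame: GroupTraits = field(default_factory=_default_nonlame)
    lame: GroupTraits = field(default_factory=_default_lame)
    n_nonlame: int = 7
    n_lame: int = 9

    # days in milk at study start
    dim_mean: float = 238.0
    dim_sd: float = 91.1
    dim_ref: float = 238.0  # trends are centered here so group means hold

    # lactation-stage trends, per day in milk
    milk_trend: float = -0.05   # l/day per DIM
    fmi_trend: float = 0.07     # kg/day per DIM

    # within-cow couplings of rumination time to the day's realized
    # feeding rate (min/day per g/min) and milk yield (min/day per l)
    rum_per_frate: float = -0.24
    rum_per_milk: float = 3.57

    # barn layout and feed-station mechanics
    n_stations: int = 12
    cap_kg: float = 5.0
    cap_override_p: float = 0.05
    reset_loss_kg: float = 2.8  # mean unassigned kg/station/day

    # visit-level noise
    visit_split_conc: float = 6.0   # Dirichlet-like concentration of intake split
    visit_noise_cv: float = 0.25

    # rumination event shaping
    event_split_shape: float = 4.0  # gamma shape for splitting daily time

    # contamination rates (fraction of clean visits); zero by default
    zero_duration_rate: float = 0.0
    short_high_rate: float = 0.0
    rate_outlier_rate: float = 0.0

    milk_missing_rate: float = 0.0

    # visit-level feeding-rate truth used when rate_model == "linear"
    m3_base_rate: float = 119.0      # g/min at zero score, zero milk
    m3_rate_per_score: float = 36.0  # g/min per locomotion score unit
    m3_rate_per_litre: float = 0.32  # g/min per l/day of milk
    m3_cow_sd: float = 12.0          # SD of the per-cow rate deviation
    rate_model: str = "group"

    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.zero_duration_rate, self.short_high_rate,
                     self.rate_outlier_rate, self.milk_missing_rate,
                     self.cap_override_p):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates and probabilities must be in [0, 1]")
        if self.n_nonlame < 0 or self.n_lame < 0:
            raise ValueError("group sizes must be >= 0")
        if self.rate_model not in ("group", "linear"):
            raise ValueError("rate_model must be 'group' or 'linear'")

    @property
    def n_cows(self) -> int:
        return self.n_nonlame + self.n_lame

    def group(self, is_lame: bool) -> GroupTraits:
        return self.lame if is_lame else self.nonlame

    def contaminated(self, rate: float = 0.01) -> "GeneratorConfig":
        """Copy of this config with all contamination rates set to *rate*."""
        return dataclasses.replace(
            self,
            zero_duration_rate=rate,
            short_high_rate=rate,
            rate_outlier_rate=rate,
        )

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GeneratorConfig":
        d = dict(d)
        for key in ("nonlame", "lame"):
            if key in d and isinstance(d[key], dict):
                d[key] = GroupTraits(
                    **{k: TraitParams(**v) for k, v in d[key].items()}
                )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def m3_truth_config() -> GeneratorConfig:
    """Config whose visit-level truth is the no-intercept random-slope
    model: per-cow rate = m3_base_rate + m3_rate_per_score * score +
    m3_rate_per_litre * milk + cow deviation.

    The per-cow rate is held constant across days (no intra-day rate
    drift) and the intake cap is always overridden, so the visit-level
    slopes are exactly the configured coefficients.
    """
    cfg = GeneratorConfig(rate_model="linear", cap_override_p=1.0)
    for g in (cfg.nonlame, cfg.lame):
        g.frate = TraitParams(g.frate.mean, g.frate.inter_sd, 0.0)
    return cfg
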