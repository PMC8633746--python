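"""Configuration objects for simulation and analysis runs.

Two dataclasses are exposed:

* :class:`SimConfig` — every knob of the synthetic respirometry experiment
  (chamber layout, cycle timing, latent-rate model, growth model).
* :class:`RunConfig` — analysis-side parameters (quantile, QC threshold,
  rolling-window length, model alpha, scaling-exponent policy) plus
  pipeline plumbing (mode, paths, seed).

Both validate on construction and round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import yaml

__all__ = ["SimConfig", "RunConfig", "parse_clock", "format_clock"]


def parse_clock(value: Union[str, int, float]) -> int:
    """Convert a ``"HH:MM"`` clock string to seconds past midnight.

    Integers/floats are interpreted as seconds past midnight and passed
    through (mod 24 h) so configs may use either form.
    """
    if isinstance(value, (int, float)):
        return int(value) % 86400
    parts = value.strip().split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"bad clock time {value!r}; expected HH:MM")
    h, m = int(parts[0]), int(parts[1])
    s = int(parts[2]) if len(parts) == 3 else 0
    if not (0 <= h < 24 and 0 <= m < 60 and 0 <= s < 60):
        raise ValueError(f"bad clock time {value!r}")
    return h * 3600 + m * 60 + s


def format_clock(seconds: int) -> str:
    seconds = int(seconds) % 86400
    return f"{seconds // 3600:02d}:{(seconds % 3600) // 60:02d}"


@dataclass
class SimConfig:
    """Parameters of the synthetic intermittent-flow respirometry experiment.

    Defaults mirror the study layout this package models: 5 batches of 16
    chambers, ~45 h trials of 7-min cycles (2 min flush / 5 min measure),
    15 degC, 12L:12D photoperiod, shelter condition toggled mid-trial and a
    chase-elicited maximum-rate event near the end.
    """

    # --- layout -----------------------------------------------------------
    n_batches: int = 5
    chambers_per_batch: int = 16
    chamber_volume_l: float = 0.100
    #: group sizes assigned per batch when ``group_assignment == "by_batch"``
    group_pattern: Tuple[int, ...] = (4, 8, 8, 4, 8)
    group_assignment: str = "by_batch"  # "by_batch" | "split"

    # --- cycle / trial timing --------------------------------------------
    cycle_flush_s: float = 120.0
    cycle_measure_s: float = 300.0
    sample_interval_s: float = 1.0
    trial_duration_h: float = 45.0
    n_blank_cycles: int = 3
    lights_on: str = "07:00"
    lights_off: str = "19:00"
    #: clock time at which fish enter the chambers
    start_clock: str = "15:30"
    condition_change_offset_h: float = 21.0
    chase_offset_h: float = 43.0
    temp_c: float = 15.0
    o2_saturation_mg_l: float = 10.08  # freshwater at 15 degC, 1 atm

    # --- latent metabolic model (mg O2 kg^-1 h^-1 unless noted) ----------
    smr_mean: float = 160.0
    smr_cv: float = 0.25
    mmr_multiplier: float = 4.0
    day_activity_multiplier: float = 1.20
    shelter_multiplier: float = 0.92
    trial_effect_multiplier: float = 1.09
    day2_multiplier: float = 0.85
    #: allometric exponent used to scale absolute uptake with mass
    scaling_b: float = 0.85
    burst_rate_per_h: float = 2.0
    burst_decay_min: float = 3.0
    burst_amp_mean: float = 0.5
    chase_halflife_min: float = 10.0
    flush_tau_s: float = 30.0

    # --- chamber background & sensor noise -------------------------------
    background_start: float = -0.02  # mg O2 L^-1 h^-1 (signed slope)
    background_end: float = -0.08
    #: sensor noise; at 0.005 the R^2 filter trims burst-contaminated cycles
    #: without starving low-uptake night windows
    noise_sd: float = 0.005  # mg O2 L^-1

    # --- fish / growth ----------------------------------------------------
    mass_mean_g: float = 1.95
    mass_sd_g: float = 0.57
    sgr_mean_by_group: Dict[int, float] = field(
        default_factory=lambda: {4: 0.64, 8: 0.50}
    )
    sgr_sd: float = 0.23
    sgr_floor: float = -0.1  # % day^-1, clamp
    growth_days: float = 21.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_batches < 1 or self.chambers_per_batch < 1:
            raise ValueError("n_batches and chambers_per_batch must be >= 1")
        if self.chamber_volume_l <= 0:
            raise ValueError("chamber_volume_l must be positive")
        for name in (
            "mmr_multiplier",
            "day_activity_multiplier",
            "shelter_multiplier",
            "trial_effect_multiplier",
            "day2_multiplier",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.shelter_multiplier > 1:
            raise ValueError("shelter_multiplier must be <= 1")
        if self.mmr_multiplier <= 1:
            raise ValueError("mmr_multiplier must be > 1")
        if self.day_activity_multiplier < 1:
            raise ValueError("day_activity_multiplier must be >= 1")
        if self.cycle_flush_s <= 0 or self.cycle_measure_s <= 0:
            raise ValueError("cycle durations must be positive")
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval_s must be positive")
        if self.trial_duration_h * 3600 <= (self.n_blank_cycles + 2) * self.cycle_s:
            raise ValueError("trial too short for blank blocks plus measurement")
        if self.chase_offset_h >= self.trial_duration_h:
            raise ValueError("chase must occur within the trial")
        if self.condition_change_offset_h >= self.chase_offset_h:
            raise ValueError("condition change must precede the chase")
        if self.smr_mean <= 0 or self.smr_cv <= 0:
            raise ValueError("smr_mean and smr_cv must be positive")
        if self.mass_mean_g <= 0 or self.mass_sd_g < 0:
            raise ValueError("mass parameters out of range")
        if self.group_assignment not in ("by_batch", "split"):
            raise ValueError("group_assignment must be 'by_batch' or 'split'")
        for g in self.group_sizes:
            if self.chambers_per_batch % g != 0:
                raise ValueError(
                    f"group size {g} does not divide chambers_per_batch "
                    f"({self.chambers_per_batch})"
                )
        # normalise key type after YAML round trips (YAML maps may load str keys)
        self.sgr_mean_by_group = {int(k): float(v) for k, v in self.sgr_mean_by_group.items()}
        self.group_pattern = tuple(int(g) for g in self.group_pattern)

    # --- derived ----------------------------------------------------------
    @property
    def cycle_s(self) -> float:
        return self.cycle_flush_s + self.cycle_measure_s

    @property
    def group_sizes(self) -> Tuple[int, ...]:
        return tuple(sorted(set(self.group_pattern)))

    @property
    def fish_in_s(self) -> float:
        """Trace time at which fish enter the chamber (after leading blanks)."""
        return self.n_blank_cycles * self.cycle_s

    @property
    def n_fish_cycles(self) -> int:
        total = int(self.trial_duration_h * 3600 // self.cycle_s)
        return total - 2 * self.n_blank_cycles

    @property
    def condition_change_s(self) -> float:
        """Trace time of the shelter-condition toggle."""
        return self.fish_in_s + self.condition_change_offset_h * 3600

    @property
    def chase_s(self) -> float:
        """Trace time of the chase-induced maximum-rate event."""
        return self.fish_in_s + self.chase_offset_h * 3600

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["group_pattern"] = tuple(data.get("group_pattern", (4, 8, 8, 4, 8)))
        return cls(**data)


@dataclass
class RunConfig:
    """Analysis and orchestration parameters for a pipeline run."""

    mode: str = "simulate"  # "simulate" | "analyze"
    out_dir: str = "run_out"
    raw_path: Optional[str] = None
    schedule_path: Optional[str] = None
    meta_path: Optional[str] = None

    # respirometry_core
    exclude_initial_s: float = 30.0
    r2_min: float = 0.95
    # metabolic_traits
    q: float = 0.2
    min_cycles: int = 10
    mmr_window_s: float = 180.0
    mmr_cycles_considered: int = 1
    acclimation_h: float = 5.0
    reference_mass_g: float = 1.95
    #: "per-trait" fits b per trait from the initial-trial cohort; a float fixes it
    b_policy: Union[str, float] = "per-trait"
    # treatment_stats
    alpha: float = 0.05
    chi2_flavor: str = "lrt"  # "lrt" | "wald"
    log_response: bool = True

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ValueError("mode must be 'simulate' or 'analyze'")
        if not 0 < self.q <= 1:
            raise ValueError("q must be in (0, 1]")
        if not 0 <= self.r2_min <= 1:
            raise ValueError("r2_min must be in [0, 1]")
        if self.exclude_initial_s < 0:
            raise ValueError("exclude_initial_s must be >= 0")
        if self.mmr_window_s <= 0:
            raise ValueError("mmr_window_s must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_cycles < 1:
            raise ValueError("min_cycles must be >= 1")
        if self.chi2_flavor not in ("lrt", "wald"):
            raise ValueError("chi2_flavor must be 'lrt' or 'wald'")
        if isinstance(self.b_policy, str):
            if self.b_policy != "per-trait":
                raise ValueError("b_policy must be 'per-trait' or a number")
        else:
            self.b_policy = float(self.b_policy)
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if self.mode == "analyze":
            missing = [
                n
                for n, p in (
                    ("raw", self.raw_path),
                    ("schedule", self.schedule_path),
                    ("meta", self.meta_path),
                )
                if p is None
            ]
            if missing:
                raise ValueError(f"analyze mode requires paths for: {', '.join(missing)}")

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "sim" in data and isinstance(data["sim"], dict):
            data["sim"]["group_pattern"] = tuple(
                data["sim"].get("group_pattern", (4, 8, 8, 4, 8))
            )
        return cls(**data)
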