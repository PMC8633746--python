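"""Synthetic intermittent-flow respirometry experiment generator.

Produces raw per-chamber dissolved-oxygen traces, trial schedules, fish
metadata and a ground-truth table with known latent parameters, so the
downstream extraction/aggregation/inference stages can be validated by
parameter recovery.

The latent oxygen-uptake model is multiplicative around a per-fish baseline
(``true_smr``): photoperiod activity, shelter cover on the chamber, trial
day, and a final-vs-initial trial effect each scale the rate; Poisson-
arriving activity bursts add exponentially decaying excursions above the
floor; a chase event near the end of the trial jumps the rate to
``true_mmr`` with exponential relaxation back to baseline.

Chamber oxygen evolves by forward-difference integration during closed
measure phases and by closed-form exponential relaxation toward the
saturated inflow during flush phases. Blank cycles (empty chamber) at both
ends of the trace carry only the programmed linear background drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import SimConfig, format_clock, parse_clock

__all__ = [
    "TrueFishState",
    "simulate_cohort",
    "instantaneous_mo2",
    "draw_activity_bursts",
    "simulate_trial",
    "simulate_experiment",
    "write_experiment",
]

TRIALS = ("initial", "final")


@dataclass
class TrueFishState:
    """Ground-truth latent parameters of one simulated fish."""

    fish_id: str
    batch: int
    chamber_id: str
    tank_id: str
    group_size: int
    shelter_available: bool
    mass_initial_g: float
    mass_final_g: float
    true_smr: float  # mg O2 kg^-1 h^-1, baseline floor
    true_mmr: float  # mg O2 kg^-1 h^-1
    sgr_true: float  # % day^-1
    activity_event_rate: float  # events h^-1
    activity_decay_min: float

    def __post_init__(self) -> None:
        if self.true_mmr <= self.true_smr:
            raise ValueError("true_mmr must exceed true_smr")
        if self.mass_initial_g <= 0 or self.mass_final_g <= 0:
            raise ValueError("masses must be positive")

    def mass_g(self, trial: str) -> float:
        return self.mass_initial_g if trial == "initial" else self.mass_final_g


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def _batch_group_sizes(config: SimConfig) -> List[int]:
    if config.group_assignment == "by_batch":
        pattern = list(config.group_pattern)
        return [pattern[i % len(pattern)] for i in range(config.n_batches)]
    # "split": not used for batch-level sizes (handled per batch)
    return [0] * config.n_batches


def simulate_cohort(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> List[TrueFishState]:
    """Draw a cohort of fish with treatment assignments and latent traits.

    Batches are assigned whole to one group size following
    ``config.group_pattern`` (``by_batch``, the default) or split evenly
    between the configured group sizes (``split``). Within a batch, fish
    are partitioned into tanks of the assigned group size; half of the
    tanks of each group size receive shelter.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    fish: List[TrueFishState] = []
    batch_sizes = _batch_group_sizes(config)
    # alternate which tank gets shelter first so shelter is balanced across
    # tanks of each group size over the whole design
    shelter_toggle: Dict[int, int] = {}
    tank_counter = 0
    sigma = math.sqrt(math.log(1 + config.smr_cv**2))
    mu = math.log(config.smr_mean) - sigma**2 / 2
    for b in range(config.n_batches):
        if config.group_assignment == "by_batch":
            sizes = [batch_sizes[b]] * (config.chambers_per_batch // batch_sizes[b])
        else:
            groups = config.group_sizes
            per = config.chambers_per_batch // len(groups)
            sizes = []
            for g in groups:
                if per % g != 0:
                    raise ValueError(
                        f"cannot split {config.chambers_per_batch} chambers "
                        f"evenly into tanks of {groups}"
                    )
                sizes.extend([g] * (per // g))
        idx = 0
        for size in sizes:
            tank_counter += 1
            tank_id = f"T{tank_counter:02d}"
            k = shelter_toggle.get(size, 0)
            shelter_toggle[size] = k + 1
            shelter = k % 2 == 0
            for _ in range(size):
                idx += 1
                mass = float(
                    np.clip(
                        rng.normal(config.mass_mean_g, config.mass_sd_g),
                        0.4 * config.mass_mean_g,
                        None,
                    )
                )
                smr = float(rng.lognormal(mu, sigma))
                sgr_mu = config.sgr_mean_by_group.get(size, 0.5)
                sgr = float(max(rng.normal(sgr_mu, config.sgr_sd), config.sgr_floor))
                mass_final = mass * math.exp(sgr / 100.0 * config.growth_days)
                fid = f"B{b + 1}F{idx:02d}"
                fish.append(
                    TrueFishState(
                        fish_id=fid,
                        batch=b + 1,
                        chamber_id=f"B{b + 1}C{idx:02d}",
                        tank_id=tank_id,
                        group_size=size,
                        shelter_available=shelter,
                        mass_initial_g=mass,
                        mass_final_g=mass_final,
                        true_smr=smr,
                        true_mmr=smr * config.mmr_multiplier,
                        sgr_true=sgr,
                        activity_event_rate=config.burst_rate_per_h,
                        activity_decay_min=config.burst_decay_min,
                    )
                )
    return fish


# ---------------------------------------------------------------------------
# latent rate
# ---------------------------------------------------------------------------


def draw_activity_bursts(
    rate_per_h: float,
    amp_mean: float,
    duration_s: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Poisson-arriving burst onset times (s) and exponential amplitudes."""
    n = rng.poisson(rate_per_h * duration_s / 3600.0)
    times = np.sort(rng.uniform(0.0, duration_s, size=n))
    amps = rng.exponential(amp_mean, size=n)
    return times, amps


def _lights_on_mask(
    t: np.ndarray, start_clock_s: int, lights_on_s: int, lights_off_s: int
) -> np.ndarray:
    clock = (start_clock_s + np.asarray(t, dtype=float)) % 86400.0
    return (clock >= lights_on_s) & (clock < lights_off_s)


def instantaneous_mo2(
    fish: TrueFishState,
    t: Union[float, np.ndarray],
    config: SimConfig,
    *,
    trial: str = "initial",
    shelter_on_chamber: Union[bool, np.ndarray] = False,
    bursts: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    chase_s: Optional[float] = None,
) -> np.ndarray:
    """Latent mass-specific uptake rate (mg O2 kg^-1 h^-1) at time ``t``.

    ``t`` is seconds since the fish entered the chamber. The rate is the
    product of the fish baseline and the configured photoperiod / shelter /
    trial-day / trial multipliers, times an activity-burst factor (>= 1),
    with the chase response taking the rate to ``true_mmr`` immediately
    after ``chase_s`` and decaying back. The rate never exceeds
    ``true_mmr``.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    start = parse_clock(config.start_clock)
    day = _lights_on_mask(t, start, parse_clock(config.lights_on), parse_clock(config.lights_off))
    rate = np.full(t.shape, fish.true_smr, dtype=float)
    rate[day] *= config.day_activity_multiplier
    shelter_on = np.broadcast_to(np.asarray(shelter_on_chamber, dtype=bool), t.shape)
    rate[shelter_on] *= config.shelter_multiplier
    day2 = t >= config.condition_change_offset_h * 3600.0
    rate[day2] *= config.day2_multiplier
    if trial == "final":
        rate *= config.trial_effect_multiplier
    if bursts is not None and len(bursts[0]) > 0:
        tau = fish.activity_decay_min * 60.0
        factor = np.ones_like(rate)
        for t0, a in zip(*bursts):
            live = t >= t0
            factor[live] += a * np.exp(-(t[live] - t0) / tau)
        rate *= factor
    if chase_s is not None:
        post = t >= chase_s
        if np.any(post):
            lam = math.log(2.0) / (config.chase_halflife_min * 60.0)
            decay = np.exp(-lam * (t[post] - chase_s))
            rate[post] = rate[post] + (fish.true_mmr - rate[post]) * decay
    return np.minimum(rate, fish.true_mmr)


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------


def _cycle_layout(config: SimConfig) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample arrays (time, phase, cycle_index, is_blank) for one trace.

    Trace time 0 is the start of the first leading blank cycle; fish enter
    at ``config.fish_in_s``.
    """
    cyc = config.cycle_s
    nb = config.n_blank_cycles
    n_total = 2 * nb + config.n_fish_cycles
    dt = config.sample_interval_s
    n_per = int(round(cyc / dt))
    offs = np.arange(n_per) * dt
    in_flush = offs < config.cycle_flush_s
    times = (np.arange(n_total)[:, None] * cyc + offs[None, :]).ravel()
    cycles = np.repeat(np.arange(n_total), n_per)
    blank = (cycles < nb) | (cycles >= nb + config.n_fish_cycles)
    flush = np.tile(in_flush, n_total)
    phase = np.where(flush, "flush", "measure").astype(object)
    phase[blank & ~flush] = "blank"
    return times, phase, cycles, blank


def _background_slope(
    t: np.ndarray, config: SimConfig, t_end: float
) -> np.ndarray:
    """Signed background drift (mg O2 L^-1 h^-1), linear over the trace."""
    frac = np.clip(np.asarray(t, dtype=float) / max(t_end, 1.0), 0.0, 1.0)
    return config.background_start + frac * (config.background_end - config.background_start)


def simulate_trial(
    fish_states: Sequence[TrueFishState],
    config: SimConfig,
    trial: str,
    rng: np.random.Generator,
    shelter_first: Optional[Dict[str, bool]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one ~45 h trial for a set of chambers (one fish each).

    Returns ``(traces, schedule)``. ``traces`` holds every chamber's raw
    samples (`time_s, clock_time, chamber_id, phase, cycle_index,
    o2_mg_per_l, temp_c`); ``schedule`` one row per chamber with shelter
    order and event times (absolute trace seconds).

    Raises ``ValueError`` if the configured rates would drive oxygen to
    zero or below anywhere in a trace.
    """
    if trial not in TRIALS:
        raise ValueError(f"trial must be one of {TRIALS}")
    times, phase, cycles, blank = _cycle_layout(config)
    t_end = float(times[-1])
    csat = config.o2_saturation_mg_l
    start_clock = parse_clock(config.start_clock)
    clock0 = start_clock - int(config.fish_in_s)  # clock at trace time 0
    bg = _background_slope(times, config, t_end)  # per-sample, mg/L/h

    if shelter_first is None:
        shelter_first = {
            f.chamber_id: bool(rng.integers(0, 2)) for f in fish_states
        }
    if trial == "final":
        shelter_first = {k: not v for k, v in shelter_first.items()}

    measure_like = phase != "flush"
    dt = config.sample_interval_s
    # clock strings are shared by every chamber; build once via a minute table
    minute_table = np.array([format_clock(m * 60) for m in range(1440)])
    clock_str = minute_table[((clock0 + times.astype(int)) % 86400) // 60]
    frames: List[pd.DataFrame] = []
    sched_rows: List[dict] = []
    for f in fish_states:
        mass_kg = f.mass_g(trial) / 1000.0
        v_eff = config.chamber_volume_l - mass_kg  # density 1 kg/L
        if v_eff <= 0:
            raise ValueError(f"fish {f.fish_id} does not fit chamber volume")
        t_fish = times - config.fish_in_s
        occupied = ~blank
        sf = shelter_first[f.chamber_id]
        shelter_on = np.where(
            t_fish < config.condition_change_offset_h * 3600.0, sf, not sf
        )
        bursts = draw_activity_bursts(
            f.activity_event_rate,
            config.burst_amp_mean,
            t_end - config.fish_in_s,
            rng,
        )
        rate_ms = np.zeros_like(times)
        occ_idx = occupied & measure_like
        rate_ms[occ_idx] = instantaneous_mo2(
            f,
            t_fish[occ_idx],
            config,
            trial=trial,
            shelter_on_chamber=shelter_on[occ_idx],
            bursts=bursts,
            chase_s=config.chase_offset_h * 3600.0,
        )
        # total concentration slope during closed phases, mg/L/h (signed)
        slope = bg - rate_ms * mass_kg / np.where(blank, config.chamber_volume_l, v_eff)
        o2 = np.empty_like(times)
        c = csat
        n_per = int(round(config.cycle_s / dt))
        n_flush = int(round(config.cycle_flush_s / dt))
        tau = config.flush_tau_s
        slope_2d = slope.reshape(-1, n_per)
        o2_2d = o2.reshape(-1, n_per)
        flush_decay = np.exp(-(np.arange(n_flush) * dt) / tau)
        for ci in range(slope_2d.shape[0]):
            o2_2d[ci, :n_flush] = csat + (c - csat) * flush_decay
            c_m0 = csat + (c - csat) * math.exp(-config.cycle_flush_s / tau)
            seg = slope_2d[ci, n_flush:]
            # left-rule forward difference: exact for piecewise-constant rate
            drop = np.concatenate(([0.0], np.cumsum(seg[:-1]) * dt / 3600.0))
            o2_2d[ci, n_flush:] = c_m0 + drop
            c = o2_2d[ci, -1] + seg[-1] * dt / 3600.0
        if np.any(o2 <= 0):
            raise ValueError(
                f"oxygen depleted in chamber {f.chamber_id}: rate parameters "
                "too high for chamber volume/flush settings"
            )
        if config.noise_sd > 0:
            o2 = o2 + rng.normal(0.0, config.noise_sd, size=o2.shape)
        frames.append(
            pd.DataFrame(
                {
                    "time_s": times,
                    "clock_time": clock_str,
                    "chamber_id": f.chamber_id,
                    "phase": phase,
                    "cycle_index": cycles,
                    "o2_mg_per_l": np.round(o2, 6),
                    "temp_c": config.temp_c,
                }
            )
        )
        sched_rows.append(
            {
                "chamber_id": f.chamber_id,
                "fish_id": f.fish_id,
                "trial": trial,
                "shelter_first": int(sf),
                "fish_in_s": config.fish_in_s,
                "condition_change_s": config.condition_change_s,
                "chase_s": config.chase_s,
                "fish_out_s": config.fish_in_s + config.n_fish_cycles * config.cycle_s,
                "lights_on": config.lights_on,
                "lights_off": config.lights_off,
                "start_clock": config.start_clock,
            }
        )
    traces = pd.concat(frames, ignore_index=True)
    schedule = pd.DataFrame(sched_rows)
    return traces, schedule


# ---------------------------------------------------------------------------
# whole experiment
# ---------------------------------------------------------------------------


def _true_floor(
    fish: TrueFishState, config: SimConfig, trial: str, shelter_first: bool
) -> float:
    """Lowest latent maintenance rate reachable during a trial.

    Nights are the floor (day multiplier >= 1): night 1 carries the
    first-half shelter state, night 2 the reversed state plus the day-2
    multiplier. This is the quantity a quantile-based minimum-rate
    estimator targets.
    """
    m_trial = config.trial_effect_multiplier if trial == "final" else 1.0
    s = config.shelter_multiplier
    night1 = s if shelter_first else 1.0
    night2 = config.day2_multiplier * (1.0 if shelter_first else s)
    return fish.true_smr * m_trial * min(night1, night2)


def simulate_experiment(
    config: SimConfig, seed: Optional[int] = None
) -> Dict[str, pd.DataFrame]:
    """Simulate the full two-trial experiment for every batch.

    Returns a dict with keys ``raw_initial``, ``raw_final`` (traces),
    ``schedule`` (both trials), ``metadata`` and ``truth``. Deterministic
    for a fixed seed.
    """
    if seed is not None:
        config = SimConfig(**{**config.__dict__, "seed": seed})
    root = np.random.default_rng(config.seed)
    cohort_rng = np.random.default_rng(root.integers(2**63))
    fish = simulate_cohort(config, cohort_rng)
    raw: Dict[str, List[pd.DataFrame]] = {t: [] for t in TRIALS}
    sched_frames: List[pd.DataFrame] = []
    for b in range(1, config.n_batches + 1):
        batch_fish = [f for f in fish if f.batch == b]
        order_rng = np.random.default_rng(root.integers(2**63))
        shelter_first = {
            f.chamber_id: bool(order_rng.integers(0, 2)) for f in batch_fish
        }
        for trial in TRIALS:
            trial_rng = np.random.default_rng(root.integers(2**63))
            traces, sched = simulate_trial(
                batch_fish, config, trial, trial_rng, shelter_first=dict(shelter_first)
            )
            raw[trial].append(traces)
            sched_frames.append(sched)
    meta = pd.DataFrame(
        {
            "fish_id": [f.fish_id for f in fish],
            "batch": [f.batch for f in fish],
            "chamber_id": [f.chamber_id for f in fish],
            "tank_id": [f.tank_id for f in fish],
            "group_size": [f.group_size for f in fish],
            "shelter_available": [int(f.shelter_available) for f in fish],
            "mass_initial_g": [round(f.mass_initial_g, 4) for f in fish],
            "mass_final_g": [round(f.mass_final_g, 4) for f in fish],
        }
    )
    schedule = pd.concat(sched_frames, ignore_index=True)
    sf_by_fish_trial = {
        (r.fish_id, r.trial): bool(r.shelter_first) for r in schedule.itertuples()
    }
    truth = pd.DataFrame(
        {
            "fish_id": [f.fish_id for f in fish],
            "true_smr": [f.true_smr for f in fish],
            "true_mmr": [f.true_mmr for f in fish],
            "sgr_true": [f.sgr_true for f in fish],
            "true_smr_floor_initial": [
                _true_floor(f, config, "initial", sf_by_fish_trial[(f.fish_id, "initial")])
                for f in fish
            ],
            "true_smr_floor_final": [
                _true_floor(f, config, "final", sf_by_fish_trial[(f.fish_id, "final")])
                for f in fish
            ],
            "activity_event_rate": [f.activity_event_rate for f in fish],
            "activity_decay_min": [f.activity_decay_min for f in fish],
        }
    )
    return {
        "raw_initial": pd.concat(raw["initial"], ignore_index=True),
        "raw_final": pd.concat(raw["final"], ignore_index=True),
        "schedule": schedule,
        "metadata": meta,
        "truth": truth,
    }


def write_experiment(data: Dict[str, pd.DataFrame], out_dir: Union[str, Path]) -> Dict[str, Path]:
    """Write experiment tables as CSV; returns the path of each file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    names = {
        "raw_initial": "raw_initial.csv",
        "raw_final": "raw_final.csv",
        "schedule": "schedule.csv",
        "metadata": "metadata.csv",
        "truth": "ground_truth.csv",
    }
    for key, fname in names.items():
        if key in data:
            p = out / fname
            data[key].to_csv(p, index=False)
            paths[key] = p
    return paths
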