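"""Aggregation of per-cycle uptake estimates into individual trait values.

Traits per fish x trial: windowed minimum metabolic rates (0.2-quantile of
the qc-passed cycle estimates in each day/night window), SMR (lowest valid
windowed minimum), MMR (steepest 3-min rolling regression in the
post-chase measurement cycle), aerobic scope (MMR - SMR), mass-adjusted
variants via the log-log scaling exponent, and specific growth rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import parse_clock
from .core import BackgroundModel, SlopeFit, estimate_background, fit_slope, segment_cycles

__all__ = [
    "WindowSpec",
    "ScalingFit",
    "build_windows",
    "mo2min_quantile",
    "compute_smr",
    "compute_mmr",
    "compute_as",
    "estimate_scaling_exponent",
    "mass_adjust",
    "compute_sgr",
    "compute_traits",
]

logger = logging.getLogger(__name__)


@dataclass
class WindowSpec:
    """One day/night estimation window of a fish-trial."""

    fish_id: str
    trial: str
    photoperiod: str  # "day" | "night"
    shelter_on: bool
    trial_day: int  # 1 | 2
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.start_s >= self.end_s:
            raise ValueError(f"empty window [{self.start_s}, {self.end_s})")
        if self.photoperiod not in ("day", "night"):
            raise ValueError("photoperiod must be 'day' or 'night'")
        if self.trial_day not in (1, 2):
            raise ValueError("trial_day must be 1 or 2")


@dataclass
class ScalingFit:
    """Log-log scaling of absolute uptake with body mass."""

    b: float
    intercept: float
    n: int
    reference_mass_g: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.b):
            raise ValueError("non-finite scaling exponent")
        if self.n < 3:
            raise ValueError("scaling fit needs n >= 3")


def build_windows(sched_row: pd.Series, acclimation_h: float = 5.0) -> List[WindowSpec]:
    """Derive the four estimation windows of one fish-trial from its schedule.

    Night day 1 runs from ``acclimation_h`` after chamber entry to the
    first lights-on; day 1 from lights-on to the shelter-condition change;
    night day 2 from ``acclimation_h`` after the change to the second
    lights-on; day 2 from there to the chase. Each window carries the
    shelter state of its half of the trial.
    """
    fish_in = float(sched_row["fish_in_s"])
    change = float(sched_row["condition_change_s"])
    chase = float(sched_row["chase_s"])
    start_clock = parse_clock(sched_row["start_clock"])
    lights_on = parse_clock(sched_row["lights_on"])
    # first lights-on at/after chamber entry, in trace time
    delta = (lights_on - start_clock) % 86400
    t_on1 = fish_in + delta
    t_on2 = t_on1 + 86400
    sf = bool(int(sched_row["shelter_first"]))
    fid, trial = sched_row["fish_id"], sched_row["trial"]
    acc = acclimation_h * 3600.0
    windows: List[WindowSpec] = []

    def _add(photoperiod, shelter, day, start, end):
        if end <= start:
            logger.warning(
                "fish %s trial %s: %s window day %d is empty "
                "([%s, %s)); skipped",
                fid, trial, photoperiod, day, start, end,
            )
            return
        windows.append(
            WindowSpec(fid, trial, photoperiod, shelter, day, float(start), float(end))
        )

    _add("night", sf, 1, fish_in + acc, min(t_on1, change))
    _add("day", sf, 1, t_on1, min(change, chase))
    _add("night", not sf, 2, change + acc, min(t_on2, chase))
    _add("day", not sf, 2, t_on2, chase)
    return windows


def mo2min_quantile(
    values: Sequence[float], q: float = 0.2, min_cycles: int = 10
) -> Optional[float]:
    """Empirical ``q``-quantile of qc-passed cycle estimates in one window.

    Linear interpolation between order statistics ((n-1)-spacing
    convention, numpy's default). Returns ``None`` (invalid) when fewer
    than ``min_cycles`` estimates survive.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < min_cycles:
        return None
    return float(np.quantile(arr, q, method="linear"))


def compute_smr(mo2min_values: Iterable[Optional[float]]) -> Optional[float]:
    """Lowest valid windowed minimum rate of a fish-trial; None if none valid."""
    valid = [v for v in mo2min_values if v is not None]
    return min(valid) if valid else None


def _rolling_slopes(t: np.ndarray, y: np.ndarray, window_s: float) -> np.ndarray:
    """OLS slope (per second) of every contiguous window spanning ``window_s``.

    Windows start at each sample index and end at the last sample within
    ``window_s`` of the start; starts whose window would run past the data
    are not produced.
    """
    slopes = []
    n = t.size
    j_end = np.searchsorted(t, t + window_s, side="right")
    for i in range(n):
        j = j_end[i]
        if t[n - 1] - t[i] < window_s - 1e-9:
            break
        tw = t[i:j]
        yw = y[i:j]
        tc = tw - tw.mean()
        sxx = float(tc @ tc)
        if sxx == 0.0:
            continue
        slopes.append(float(tc @ (yw - yw.mean())) / sxx)
    return np.asarray(slopes)


def compute_mmr(
    post_chase_trace: pd.DataFrame,
    bg: BackgroundModel,
    chamber_volume_l: float,
    fish_mass_g: float,
    chase_s: float,
    window_s: float = 180.0,
    cycles_considered: int = 1,
    exclude_initial_s: float = 30.0,
) -> Optional[float]:
    """Maximum metabolic rate from the post-chase measurement cycle(s).

    Over each of the first ``cycles_considered`` measurement cycles that
    start after the chase, slide a ``window_s`` regression window one
    sample at a time (head-excluded like any cycle) and keep the steepest
    background-corrected, volume-scaled, mass-specific rate. Returns
    ``None`` when no post-chase cycle exists.
    """
    windows = segment_cycles(post_chase_trace, exclude_initial_s, phase="measure")
    post = [w for w in windows if w["time_s"].iloc[0] >= chase_s]
    if not post:
        return None
    v_eff = chamber_volume_l - fish_mass_g / 1000.0
    if v_eff <= 0:
        raise ValueError("effective volume <= 0")
    mass_kg = fish_mass_g / 1000.0
    best = -np.inf
    for w in post[:cycles_considered]:
        t = w["time_s"].to_numpy(dtype=float)
        y = w["o2_mg_per_l"].to_numpy(dtype=float)
        slopes = _rolling_slopes(t, y, window_s) * 3600.0
        if slopes.size == 0:  # cycle shorter than the rolling window
            f = fit_slope(w)
            slopes = np.asarray([f.slope])
        t_mid = (t[0] + t[-1]) / 2.0
        rates = -(slopes - float(bg(t_mid))) * v_eff / mass_kg
        best = max(best, float(rates.max()))
    return best if math.isfinite(best) else None


def compute_as(mmr: Optional[float], smr: Optional[float]) -> Optional[float]:
    """Aerobic scope: MMR - SMR; invalid if either input is."""
    if mmr is None or smr is None:
        return None
    return mmr - smr


def estimate_scaling_exponent(
    mass_g: Sequence[float],
    mo2_abs: Sequence[float],
    reference_mass_g: float = 1.95,
) -> ScalingFit:
    """OLS slope of log absolute uptake on log body mass."""
    m = np.asarray(mass_g, dtype=float)
    r = np.asarray(mo2_abs, dtype=float)
    if m.size != r.size or m.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.any(m <= 0) or np.any(r <= 0):
        raise ValueError("masses and rates must be positive for log-log fit")
    x, y = np.log(m), np.log(r)
    xc = x - x.mean()
    b = float(xc @ (y - y.mean())) / float(xc @ xc)
    return ScalingFit(
        b=b,
        intercept=float(y.mean() - b * x.mean()),
        n=int(m.size),
        reference_mass_g=reference_mass_g,
    )


def mass_adjust(
    mo2: Union[float, np.ndarray],
    mass_g: Union[float, np.ndarray],
    mean_mass_g: float,
    b: float,
):
    """Scale uptake to a common reference mass along the allometric slope.

    adjusted = mean_mass^(b-1) * mass^(1-b) * mo2; the identity map when
    mass equals the reference mass or b = 1.
    """
    if mean_mass_g <= 0 or np.any(np.asarray(mass_g) <= 0):
        raise ValueError("masses must be positive")
    return (mean_mass_g ** (b - 1.0)) * (np.asarray(mass_g) ** (1.0 - b)) * mo2


def compute_sgr(mass_initial_g: float, mass_final_g: float, t_days: float) -> float:
    """Specific growth rate, % day^-1: 100 * [ln(Mf) - ln(Mi)] / t."""
    if t_days <= 0:
        raise ValueError("growth period must be positive")
    if mass_initial_g <= 0 or mass_final_g <= 0:
        raise ValueError("masses must be positive")
    return 100.0 * (math.log(mass_final_g) - math.log(mass_initial_g)) / t_days


# ---------------------------------------------------------------------------
# high-level driver
# ---------------------------------------------------------------------------


def _mmr_background(raw_chamber: pd.DataFrame, exclude_initial_s, n_blank) -> BackgroundModel:
    blanks = segment_cycles(raw_chamber, exclude_initial_s, phase="blank")
    if len(blanks) < 2 * n_blank:
        return BackgroundModel.zero()
    fits = [fit_slope(w) for w in blanks]
    return estimate_background(fits[:n_blank], fits[-n_blank:], n_blank)


def compute_traits(
    estimates: pd.DataFrame,
    schedule: pd.DataFrame,
    metadata: pd.DataFrame,
    raw: Optional[pd.DataFrame] = None,
    q: float = 0.2,
    min_cycles: int = 10,
    mmr_window_s: float = 180.0,
    mmr_cycles_considered: int = 1,
    acclimation_h: float = 5.0,
    chamber_volume_l: float = 0.100,
    exclude_initial_s: float = 30.0,
    n_blank_cycles: int = 3,
    reference_mass_g: float = 1.95,
    b_policy: Union[str, float] = "per-trait",
    growth_days: float = 21.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Build the per-fish trait table and the long windowed-minimum table.

    ``estimates`` is the qc-annotated per-cycle table from the extraction
    stage; ``raw`` (the trace table) is needed for MMR — when omitted, MMR
    and aerobic scope are invalid (NaN). The scaling exponent used for
    mass adjustment is fitted per trait on the initial-trial cohort
    (``b_policy='per-trait'``) or fixed to a numeric value.

    Returns ``(traits, mo2min_long)``.
    """
    est = estimates[estimates["qc_pass"].astype(bool)]
    meta = metadata.set_index("fish_id")
    post_by_chamber: Dict = {}
    if raw is not None:
        # only the tail of each trace is needed for MMR; pre-slice once
        chase_min = float(schedule["chase_s"].astype(float).min())
        raw_post = raw[raw["time_s"].astype(float) >= chase_min - 3600.0]
        gcols = ["chamber_id", "trial"] if "trial" in raw.columns else ["chamber_id"]
        post_by_chamber = dict(tuple(raw_post.groupby(gcols)))
    long_rows: List[dict] = []
    trait_rows: List[dict] = []
    for (_, _), sched_grp in schedule.groupby(["chamber_id", "trial"]):
        sched_row = sched_grp.iloc[0]
        fid, trial = sched_row["fish_id"], sched_row["trial"]
        m = meta.loc[fid]
        mass = float(m["mass_initial_g"] if trial == "initial" else m["mass_final_g"])
        sub = est[(est["fish_id"] == fid) & (est["trial"] == trial)]
        windows = build_windows(sched_row, acclimation_h)
        mins: List[Optional[float]] = []
        for w in windows:
            vals = sub[(sub["t_mid_s"] >= w.start_s) & (sub["t_mid_s"] < w.end_s)][
                "mo2_mass_specific"
            ]
            v = mo2min_quantile(vals.to_numpy(), q=q, min_cycles=min_cycles)
            mins.append(v)
            long_rows.append(
                {
                    "fish_id": fid,
                    "trial": trial,
                    "trial_day": w.trial_day,
                    "photoperiod": w.photoperiod,
                    "shelter_on": int(w.shelter_on),
                    "window_start_s": w.start_s,
                    "window_end_s": w.end_s,
                    "n_cycles": int(len(vals)),
                    "mo2min": np.nan if v is None else v,
                    "valid": int(v is not None),
                    "mass_g": mass,
                }
            )
        smr = compute_smr(mins)
        mmr = None
        if raw is not None:
            key = (
                (sched_row["chamber_id"], trial)
                if "trial" in raw.columns
                else (sched_row["chamber_id"],)
            )
            chamber = post_by_chamber.get(key)
            if chamber is not None and not chamber.empty:
                all_est = estimates[
                    (estimates["fish_id"] == fid) & (estimates["trial"] == trial)
                ]
                if "background" in all_est.columns and len(all_est) >= 2:
                    # backgrounds on the estimate table are linear in time
                    # between the blank anchors, so two points reconstruct it
                    first, last = all_est.iloc[0], all_est.iloc[-1]
                    bg = BackgroundModel(
                        float(first["background"]),
                        float(last["background"]),
                        float(first["t_mid_s"]),
                        float(last["t_mid_s"]),
                    )
                else:
                    bg = _mmr_background(chamber, exclude_initial_s, n_blank_cycles)
                mmr = compute_mmr(
                    chamber,
                    bg,
                    chamber_volume_l,
                    mass,
                    chase_s=float(sched_row["chase_s"]),
                    window_s=mmr_window_s,
                    cycles_considered=mmr_cycles_considered,
                    exclude_initial_s=exclude_initial_s,
                )
        if mmr is not None and smr is not None and mmr < smr:
            logger.warning("fish %s trial %s: MMR < SMR; MMR flagged invalid", fid, trial)
            mmr = None
        aerobic_scope = compute_as(mmr, smr)
        trait_rows.append(
            {
                "fish_id": fid,
                "trial": trial,
                "batch": int(m["batch"]),
                "group_size": int(m["group_size"]),
                "shelter_available": int(m["shelter_available"]),
                "mass_g": mass,
                "smr": np.nan if smr is None else smr,
                "mmr": np.nan if mmr is None else mmr,
                "aerobic_scope": np.nan if aerobic_scope is None else aerobic_scope,
                "smr_valid": int(smr is not None),
                "mmr_valid": int(mmr is not None),
                "sgr": compute_sgr(
                    float(m["mass_initial_g"]), float(m["mass_final_g"]), growth_days
                ),
            }
        )
    traits = pd.DataFrame(trait_rows)
    long = pd.DataFrame(long_rows)
    long = long.merge(metadata[["fish_id", "batch"]], on="fish_id", how="left")

    # --- mass adjustment ---------------------------------------------------
    def _b_for(trait_col: str, frame: pd.DataFrame, value_col: str) -> float:
        if not isinstance(b_policy, str):
            return float(b_policy)
        init = frame[(frame["trial"] == "initial") & frame[value_col].notna()]
        mo2_abs = init[value_col] * init["mass_g"] / 1000.0
        ok = (mo2_abs > 0) & (init["mass_g"] > 0)
        if ok.sum() < 3:
            logger.warning("too few rows to fit b for %s; using b=1", trait_col)
            return 1.0
        return estimate_scaling_exponent(
            init.loc[ok, "mass_g"], mo2_abs[ok], reference_mass_g
        ).b

    b_used: Dict[str, float] = {}
    b_used["mo2min"] = _b_for("mo2min", long, "mo2min")
    long["mo2min_adj"] = mass_adjust(
        long["mo2min"], long["mass_g"], reference_mass_g, b_used["mo2min"]
    )
    for col in ("smr", "mmr"):
        b_used[col] = _b_for(col, traits, col)
        traits[f"{col}_adj"] = mass_adjust(
            traits[col], traits["mass_g"], reference_mass_g, b_used[col]
        )
    traits["aerobic_scope_adj"] = traits["mmr_adj"] - traits["smr_adj"]
    traits["b_smr"] = b_used["smr"]
    traits["b_mmr"] = b_used["mmr"]
    traits["reference_mass_g"] = reference_mass_g
    long["b_mo2min"] = b_used["mo2min"]
    return traits, long
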