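"""Synthetic winter PIT-tracking datasets with known ground truth.

The generator emulates a boreal-stream winter study: three fish groups
(European sculpin, juvenile and adult brown trout, default sizes
182/50/161), 26 weekly tracking occasions from early November, detection
probability declining with a shared ice-thickness series and with
group-specific strength (small 12-mm tags suffer more under thick ice),
weekly survival driven by an individual Fulton-condition covariate on the
logit scale, a per-group transient fraction (permanent emigration at
release), and occasional week-1 tag shedding whose stationary tags mimic the
"no movement" detection pattern the fate-classification rules must catch.

Every quantity that downstream stages estimate is recorded in a ``truth``
sidecar so parameter and label recovery can be asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .histories import GROUPS, FishRecord, ReachTable, TrackingRecord, default_reach_table
from .icegrowth import IceSeries, WinterSeries, grow_series

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_fish",
    "simulate_winter",
    "simulate_tracking",
    "simulate_dataset",
    "simulate_histories",
]

#: total length bounds (mm) by group: all sculpin >70 mm and trout >110 mm
#: were tagged; 110-150 mm trout count as juveniles, >150 mm as adults
LENGTH_BOUNDS = {
    "sculpin": (71.0, 130.0),
    "juvenile_trout": (110.0, 150.0),
    "adult_trout": (151.0, 300.0),
}


@dataclass(frozen=True)
class PhiSpec:
    """True weekly survival structure: logit(phi) = intercept + cond_slope * K."""

    intercept: float = 4.6
    cond_slope: float = 1.6


@dataclass(frozen=True)
class PSpec:
    """True weekly detection structure on the logit scale.

    logit(p) = intercept[g] + ice_slope[g] * ice_m + complex_slope * (complex - center).
    Group intercepts/slopes reflect tag size: adult trout (23-mm tags) stay
    highly detectable, sculpin and juvenile trout (12-mm tags) drop sharply
    as ice thickens.
    """

    intercepts: dict = field(
        default_factory=lambda: {"sculpin": 0.65, "juvenile_trout": 0.60, "adult_trout": 1.60}
    )
    ice_slopes: dict = field(
        default_factory=lambda: {"sculpin": -6.2, "juvenile_trout": -4.0, "adult_trout": -1.7}
    )
    complex_slope: float = -0.03
    complex_center: float = 33.0


@dataclass(frozen=True)
class SimulationConfig:
    n_per_group: dict = field(
        default_factory=lambda: {"sculpin": 182, "juvenile_trout": 50, "adult_trout": 161}
    )
    n_occasions: int = 26
    phi_spec: PhiSpec = PhiSpec()
    p_spec: PSpec = PSpec()
    transient_frac: dict = field(
        default_factory=lambda: {"sculpin": 0.04, "juvenile_trout": 0.08, "adult_trout": 0.25}
    )
    #: spawning adults emigrate this many times more often than spent ones
    #: (post-spawning returns to home habitat outside the reach)
    spawning_transience_ratio: float = 2.1
    tagloss_rate: dict = field(
        default_factory=lambda: {"sculpin": 0.0, "juvenile_trout": 0.0, "adult_trout": 0.05}
    )
    condition_dist: dict = field(
        default_factory=lambda: {
            "sculpin": (1.10, 0.12),
            "juvenile_trout": (1.00, 0.10),
            "adult_trout": (1.00, 0.10),
        }
    )
    # winter weather: sinusoidal seasonal air-temperature curve plus noise
    temp_offset_c: float = 2.0
    temp_amplitude_c: float = 9.0
    temp_noise_sd_c: float = 3.0
    snowfall_prob: float = 0.4
    snowfall_mean_m: float = 0.05
    melt_rate_m_per_day: float = 0.02
    settling_rate: float = 0.03
    shoveling_days: tuple = (50, 71, 132)
    start_date: str = "2010-11-01"
    spring_recapture_prob: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_occasions < 2:
            raise ValueError("need at least 2 occasions")
        for g, n in self.n_per_group.items():
            if g not in GROUPS or n < 0 or int(n) != n:
                raise ValueError(f"invalid group size {g}={n}")
        for d in (self.transient_frac, self.tagloss_rate):
            for g, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"probability {g}={v} outside [0, 1]")


@dataclass
class SimulatedDataset:
    registry: list
    tracking: list
    winter: WinterSeries
    ice: IceSeries
    reach: ReachTable
    truth: dict
    config: SimulationConfig


def simulate_fish(
    config: SimulationConfig, rng: np.random.Generator, reach: ReachTable | None = None
) -> list[FishRecord]:
    """Draw a tagged-fish registry with group-appropriate lengths and condition.

    Condition K is drawn per fish from the configured (truncated-normal)
    distribution and the weight set exactly from the cube law
    ``W = K * L_cm^3 / 100``, so Fulton's index recovers K without error.
    """
    reach = reach or default_reach_table()
    fish: list[FishRecord] = []
    i = 0
    for g in GROUPS:
        n = int(config.n_per_group.get(g, 0))
        lo, hi = LENGTH_BOUNDS[g]
        lengths = rng.uniform(lo, hi, size=n)
        mean, sd = config.condition_dist[g]
        K = mean + sd * rng.standard_normal(n) if sd > 0 else np.full(n, float(mean))
        K = np.maximum(K, 0.2)
        subreaches = rng.choice(reach.subreach_id, size=n)
        for j in range(n):
            maturity = None
            if g == "adult_trout":
                maturity = "spawning" if rng.random() < 0.5 else "spent"
            fish.append(
                FishRecord(
                    fish_id=f"F{i:04d}",
                    group=g,
                    length_mm=float(lengths[j]),
                    weight_g=float(K[j] * (lengths[j] / 10.0) ** 3 / 100.0),
                    subreach_id=int(subreaches[j]),
                    maturity=maturity,
                )
            )
            i += 1
    return fish


def simulate_winter(config: SimulationConfig, rng: np.random.Generator) -> WinterSeries:
    """Daily winter weather: seasonal temperature curve, snowpack, shovelings."""
    n_days = 7 * config.n_occasions + 7
    start = pd.Timestamp(config.start_date)
    dates = pd.date_range(start, periods=n_days, freq="D")
    d = np.arange(n_days)
    temps = (
        config.temp_offset_c
        - config.temp_amplitude_c * np.sin(np.pi * d / n_days)
        + config.temp_noise_sd_c * rng.standard_normal(n_days)
    )
    snow = np.zeros(n_days)
    depth = 0.0
    for i in range(n_days):
        depth *= 1.0 - config.settling_rate  # compaction of the standing pack
        if temps[i] < 0 and rng.random() < config.snowfall_prob:
            depth += rng.exponential(config.snowfall_mean_m)
        elif temps[i] > 0:
            depth = max(0.0, depth - config.melt_rate_m_per_day)
        snow[i] = depth
    shovel_dates = [dates[day] for day in config.shoveling_days if day < n_days]
    return WinterSeries(dates=dates, air_temp=temps, snow_depth=snow, shoveling_dates=shovel_dates)


def weekly_ice_covariate(ice: IceSeries, n_occasions: int) -> np.ndarray:
    """Mean ice thickness (m) per tracking week w = 1..n (days 7(w-1)+1 .. 7w)."""
    out = np.zeros(n_occasions)
    for w in range(1, n_occasions + 1):
        lo, hi = 7 * (w - 1) + 1, 7 * w + 1
        out[w - 1] = ice.thickness[lo : min(hi, len(ice.thickness))].mean()
    return out


def simulate_tracking(
    registry: list[FishRecord],
    ice: IceSeries,
    config: SimulationConfig,
    rng: np.random.Generator,
    reach: ReachTable | None = None,
) -> SimulatedDataset:
    """Latent alive/present dynamics plus detections and positions.

    Residents hold a home position near their subreach midpoint and make a
    jittered random walk with occasional lateral excursions; permanent
    emigrants (transients) leave at release and are never redetected inside
    the reach; shed tags sit still in the channel and only accrue
    zero-movement detections.
    """
    reach = reach or default_reach_table()
    n_occ = config.n_occasions
    ice_w = weekly_ice_covariate(ice, n_occ)
    total = reach.total_length_m

    n = len(registry)
    alive = np.ones((n, n_occ + 1), dtype=bool)
    present = np.ones((n, n_occ + 1), dtype=bool)
    true_fate = []
    tracking: list[TrackingRecord] = []

    for i, fish in enumerate(registry):
        g = fish.group
        K = 100.0 * fish.weight_g / (fish.length_mm / 10.0) ** 3
        comp = reach.row(fish.subreach_id)["complexity"]
        phi_w = expit(config.phi_spec.intercept + config.phi_spec.cond_slope * K)
        logit_p = (
            config.p_spec.intercepts[g]
            + np.asarray(config.p_spec.ice_slopes[g]) * ice_w
            + config.p_spec.complex_slope * (comp - config.p_spec.complex_center)
        )
        p_w = expit(logit_p)

        t_frac = config.transient_frac.get(g, 0.0)
        if fish.maturity in ("spawning", "spent") and config.spawning_transience_ratio != 1.0:
            # split the group-level fraction so spawning fish emigrate
            # ratio-times more often while the group mean stays t_frac
            r = config.spawning_transience_ratio
            base = 2.0 * t_frac / (1.0 + r)
            if base * r <= 1.0:  # keep the group mean exactly t_frac
                t_frac = base * (r if fish.maturity == "spawning" else 1.0)
        emigrant = rng.random() < t_frac
        shed = (not emigrant) and rng.random() < config.tagloss_rate.get(g, 0.0)
        fate = "emigrant" if emigrant else ("shed" if shed else "resident")
        true_fate.append(fate)

        home = reach.midpoint(fish.subreach_id)
        pos = home
        for w in range(1, n_occ + 1):
            # survival over interval w-1 -> w (shed tags persist physically)
            if fate != "shed" and alive[i, w - 1]:
                alive[i, w] = rng.random() < phi_w
            else:
                alive[i, w] = alive[i, w - 1] if fate == "shed" else False
            if emigrant:
                present[i, w] = False
                continue
            present[i, w] = present[i, w - 1]
            detectable = (alive[i, w] and present[i, w]) if fate != "shed" else True
            if not detectable:
                continue
            if rng.random() < p_w[w - 1]:
                if fate == "shed":
                    # stationary tag; jitter small enough that successive
                    # readings never differ beyond the 0.5 m accuracy
                    obs_pos = home + rng.uniform(-0.2, 0.2)
                    lateral = False
                else:
                    pos = float(np.clip(pos + rng.normal(0.0, 3.0), 0.0, total))
                    pos = float(np.clip(pos, home - 20.0, home + 20.0))
                    obs_pos = pos
                    lateral = rng.random() < 0.5
                tracking.append(
                    TrackingRecord(
                        fish_id=fish.fish_id,
                        occasion=w,
                        detected=True,
                        position_m=obs_pos,
                        lateral=lateral,
                    )
                )

    # spring electrofishing recaptures: residents alive and present at the end
    for i, fish in enumerate(registry):
        if true_fate[i] == "resident" and alive[i, -1] and present[i, -1]:
            fish.spring_recaptured = bool(rng.random() < config.spring_recapture_prob)

    truth = {
        "fate": np.array(true_fate),
        "alive": alive,
        "present": present,
        "ice_weekly_m": ice_w,
        "phi_spec": config.phi_spec,
        "p_spec": config.p_spec,
    }
    return SimulatedDataset(
        registry=registry,
        tracking=tracking,
        winter=None,
        ice=ice,
        reach=reach,
        truth=truth,
        config=config,
    )


def simulate_dataset(config: SimulationConfig | None = None, seed: int | None = None) -> SimulatedDataset:
    """Full bundle: fish registry, winter weather, ice series, tracking, truth."""
    config = config or SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    reach = default_reach_table()
    registry = simulate_fish(config, rng, reach)
    winter = simulate_winter(config, rng)
    ice = grow_series(winter)
    ds = simulate_tracking(registry, ice, config, rng, reach)
    ds.winter = winter
    return ds


def simulate_histories(
    phi: np.ndarray, p: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Encounter histories straight from per-individual phi/p matrices.

    ``phi`` and ``p`` are (n, T-1) arrays (interval survival; detection at
    occasions 2..T).  All individuals are released at occasion 1.  This is
    the occasion-scale workhorse behind parameter-recovery experiments and
    the median c-hat simulations.
    """
    phi = np.atleast_2d(phi)
    p = np.atleast_2d(p)
    n, n_int = phi.shape
    H = np.zeros((n, n_int + 1), dtype=int)
    H[:, 0] = 1
    alive = np.ones(n, dtype=bool)
    for t in range(n_int):
        alive &= rng.random(n) < phi[:, t]
        H[:, t + 1] = alive & (rng.random(n) < p[:, t])
    return H
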