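"""Degree-day river-ice growth with an insulating snow layer.

The surface-ice thickness is approximated with the Stefan equation,

    h_i = sqrt(2 * k_si * S_sec / (rho * L)),

where ``S_sec`` is the cumulative freezing degree-day sum converted to
degree-seconds, ``rho`` the ice density and ``L`` the latent heat of fusion.
Snow cover slows growth: the conductivity entering the Stefan expression is
the series (harmonic-type) conductivity of the ice-snow sandwich,

    k_si = (h_i + h_s) / (h_i / k_i + h_s / k_s),

which couples the equation to its own solution; a fixed-point iteration from
the bare-ice start resolves it.  Snow shoveling on the ice (done in the field
to keep PIT antennas within detection range) is modelled by resetting the
effective snow layer to 3 cm, after which fresh snowfall accumulates again.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IcePhysics",
    "WinterSeries",
    "IceSeries",
    "IceModelError",
    "freezing_degree_days",
    "effective_conductivity",
    "ice_thickness",
    "grow_series",
]

SECONDS_PER_DAY = 86_400.0
#: snow depth (m) the layer is reset to after a shoveling occasion
SHOVELED_SNOW_DEPTH = 0.03


class IceModelError(ValueError):
    """Raised for unphysical inputs or a non-converging thickness solve."""


@dataclass(frozen=True)
class IcePhysics:
    """Physical constants of the ice-snow system.

    Parameters
    ----------
    rho : float
        Ice density, kg m^-3.
    latent_heat : float
        Latent heat of fusion, J kg^-1 (333.4 J/g).
    k_ice, k_snow : float
        Thermal conductivities of ice and snow, W m^-1 K^-1.  Snow insulates,
        so ``k_snow < k_ice`` is required.
    """

    rho: float = 1000.0
    latent_heat: float = 333_400.0
    k_ice: float = 2.24
    k_snow: float = 0.2

    def __post_init__(self) -> None:
        for name in ("rho", "latent_heat", "k_ice", "k_snow"):
            if getattr(self, name) <= 0:
                raise IceModelError(f"{name} must be strictly positive")
        if self.k_snow >= self.k_ice:
            raise IceModelError("k_snow must be smaller than k_ice")


@dataclass
class WinterSeries:
    """Daily winter weather driving the ice model."""

    dates: pd.DatetimeIndex
    air_temp: np.ndarray  # deg C, daily mean
    snow_depth: np.ndarray  # m, observed on the ice
    shoveling_dates: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.air_temp = np.asarray(self.air_temp, dtype=float)
        self.snow_depth = np.asarray(self.snow_depth, dtype=float)
        if len(self.dates) == 0:
            raise IceModelError("empty weather series")
        if len(self.air_temp) != len(self.dates) or len(self.snow_depth) != len(self.dates):
            raise IceModelError("air_temp/snow_depth length must match dates")
        if np.any(self.snow_depth < 0):
            raise IceModelError("snow depth must be non-negative")
        step = np.diff(self.dates.values).astype("timedelta64[D]")
        if len(step) and not np.all(step == np.timedelta64(1, "D")):
            raise IceModelError("dates must be strictly increasing and daily")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "air_temp_c": self.air_temp, "snow_depth_m": self.snow_depth}
        )


@dataclass
class IceSeries:
    """Daily degree-day accumulation and modelled ice thickness."""

    dates: pd.DatetimeIndex
    degree_days: np.ndarray  # cumulative S, deg C day
    thickness: np.ndarray  # h_i, m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "degree_days": self.degree_days, "h_i_m": self.thickness}
        )

    def weekly_mean(self, n_weeks: int, start: pd.Timestamp | None = None) -> np.ndarray:
        """Mean thickness per consecutive 7-day block (the weekly covariate)."""
        start = self.dates[0] if start is None else pd.Timestamp(start)
        offset_days = (self.dates - start).days.to_numpy()
        out = np.zeros(n_weeks)
        for w in range(n_weeks):
            sel = (offset_days >= 7 * w) & (offset_days < 7 * (w + 1))
            if sel.any():
                out[w] = self.thickness[sel].mean()
            elif w > 0:
                out[w] = out[w - 1]
        return out


def freezing_degree_days(air_temp, through_index: int | None = None) -> float:
    """Cumulative freezing degree-days S = sum over days of max(0, -T_air).

    ``through_index`` (exclusive) limits the sum to a prefix of the series.
    """
    temps = np.asarray(air_temp, dtype=float)
    if through_index is not None:
        temps = temps[:through_index]
    if temps.size == 0:
        raise IceModelError("cannot accumulate degree-days over an empty series")
    return float(np.sum(np.maximum(0.0, -temps)))


def effective_conductivity(h_i: float, h_s: float, physics: IcePhysics = IcePhysics()) -> float:
    """Series thermal conductivity of the stacked ice-snow layer."""
    if h_i < 0 or h_s < 0:
        raise IceModelError("layer thicknesses must be non-negative")
    if h_i + h_s == 0:
        raise IceModelError("ice and snow thickness cannot both be zero")
    return (h_i + h_s) / (h_i / physics.k_ice + h_s / physics.k_snow)


def ice_thickness(
    S: float,
    h_s: float = 0.0,
    physics: IcePhysics = IcePhysics(),
    tol: float = 1e-12,
    max_iter: int = 100,
) -> float:
    """Solve the snow-coupled Stefan equation for ice thickness (m).

    For ``h_s == 0`` this reduces to the closed form
    ``sqrt(2 * k_ice * S_sec / (rho * L))``; otherwise the effective
    conductivity depends on the unknown thickness and the self-consistent
    solution is found by fixed-point iteration from the bare-ice start.
    """
    if S < 0:
        raise IceModelError("degree-day sum must be non-negative")
    if S == 0:
        return 0.0
    s_sec = S * SECONDS_PER_DAY
    scale = 2.0 * s_sec / (physics.rho * physics.latent_heat)
    h = np.sqrt(scale * physics.k_ice)  # bare-ice start
    if h_s == 0:
        return float(h)
    for _ in range(max_iter):
        h_new = np.sqrt(scale * effective_conductivity(h, h_s, physics))
        if abs(h_new - h) <= tol * max(1.0, abs(h_new)):
            return float(h_new)
        h = h_new
    raise IceModelError(f"thickness fixed point did not converge (last iterate {h:.6g} m)")


def effective_snow_series(winter: WinterSeries) -> np.ndarray:
    """Snow depth entering the conductivity, with shoveling resets.

    Fresh accumulation (positive day-to-day increments of the observed depth)
    adds to the effective layer; melt/settling only thins it once the observed
    pack drops below it.  At each shoveling date the layer is reset to 3 cm
    (or the observed depth if that is smaller), after which accumulation
    resumes.
    """
    obs = winter.snow_depth
    shovel = {pd.Timestamp(d) for d in winter.shoveling_dates}
    eff = np.empty_like(obs)
    eff[0] = obs[0]
    for i in range(len(obs)):
        if i > 0:
            eff[i] = min(obs[i], eff[i - 1] + max(0.0, obs[i] - obs[i - 1]))
        if winter.dates[i] in shovel:
            eff[i] = min(SHOVELED_SNOW_DEPTH, obs[i])
    return eff


def grow_series(
    winter: WinterSeries,
    physics: IcePhysics = IcePhysics(),
    accumulate_from: str = "freeze_up",
) -> IceSeries:
    """Daily ice-thickness trajectory over a winter.

    Degree-days accumulate from the first sub-zero day (``freeze_up``,
    default) or from the series start (``start``); the snow depth used in the
    conductivity is the shoveling-adjusted effective series.
    """
    if accumulate_from not in ("freeze_up", "start"):
        raise IceModelError("accumulate_from must be 'freeze_up' or 'start'")
    temps = winter.air_temp
    freezing = np.maximum(0.0, -temps)
    if accumulate_from == "freeze_up":
        below = np.nonzero(temps < 0)[0]
        start = below[0] if below.size else len(temps)
        freezing = freezing.copy()
        freezing[:start] = 0.0
    S = np.cumsum(freezing)
    h_snow = effective_snow_series(winter)
    thickness = np.array(
        [ice_thickness(S[i], h_snow[i], physics) for i in range(len(S))]
    )
    return IceSeries(dates=winter.dates, degree_days=S, thickness=thickness)
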