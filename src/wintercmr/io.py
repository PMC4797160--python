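"""Delimited-text readers/writers and the MARK-style ``.inp`` dialect.

All tabular inputs are plain CSV.  Encounter histories are exchanged in the
``.inp`` dialect used by capture-recapture software for interoperability
checks: one line per fish —

    <history string> <group dummy columns> <covariates...> ;

e.g. ``10110101011011 1 0 0 1.0523 46.1 ;`` for a sculpin with condition and
complexity covariates.  Group dummy columns follow the fixed group order
(sculpin, juvenile trout, adult trout, restricted to groups present).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .histories import EncounterHistory, FishRecord, ReachTable, TrackingRecord
from .icegrowth import IceSeries, WinterSeries

__all__ = [
    "write_registry", "read_registry",
    "write_tracking", "read_tracking",
    "write_reach", "read_reach",
    "write_weather", "read_weather",
    "write_ice_series",
    "write_inp", "read_inp",
]


def write_registry(registry: list[FishRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "fish_id": f.fish_id,
                "group": f.group,
                "length_mm": f.length_mm,
                "weight_g": f.weight_g,
                "subreach_id": f.subreach_id,
                "tag_length_mm": f.tag_length_mm,
                "tag_weight_g": f.tag_weight_g,
                "maturity": f.maturity if f.maturity is not None else "",
                "spring_recaptured": int(f.spring_recaptured),
            }
            for f in registry
        ]
    ).to_csv(path, index=False)


def read_registry(path) -> list[FishRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        FishRecord(
            fish_id=str(r.fish_id),
            group=r.group,
            length_mm=float(r.length_mm),
            weight_g=float(r.weight_g),
            subreach_id=int(r.subreach_id),
            tag_length_mm=int(r.tag_length_mm),
            tag_weight_g=float(r.tag_weight_g),
            maturity=r.maturity or None,
            spring_recaptured=bool(int(r.spring_recaptured)),
        )
        for r in df.itertuples()
    ]


def write_tracking(tracking: list[TrackingRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "fish_id": t.fish_id,
                "occasion": t.occasion,
                "detected": int(t.detected),
                "position_m": t.position_m,
                "lateral": int(t.lateral),
            }
            for t in tracking
        ]
    ).to_csv(path, index=False)


def read_tracking(path) -> list[TrackingRecord]:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"tracking file {path} contains no records")
    return [
        TrackingRecord(
            fish_id=str(r.fish_id),
            occasion=int(r.occasion),
            detected=bool(int(r.detected)),
            position_m=float(r.position_m),
            lateral=bool(int(r.lateral)),
        )
        for r in df.itertuples()
    ]


def write_reach(reach: ReachTable, path) -> None:
    reach.to_frame().to_csv(path, index=False)


def read_reach(path) -> ReachTable:
    df = pd.read_csv(path)
    return ReachTable(
        subreach_id=df["subreach_id"].to_numpy(),
        length_m=df["length_m"].to_numpy(),
        mean_depth_cm=df["mean_depth_cm"].to_numpy(),
        complexity=df["complexity"].to_numpy(),
    )


def write_weather(winter: WinterSeries, path) -> None:
    df = winter.to_frame()
    df["shoveling"] = df["date"].isin([pd.Timestamp(d) for d in winter.shoveling_dates]).astype(int)
    df.to_csv(path, index=False)


def read_weather(path) -> WinterSeries:
    df = pd.read_csv(path, parse_dates=["date"])
    shovel = df.loc[df.get("shoveling", 0) == 1, "date"].tolist() if "shoveling" in df else []
    return WinterSeries(
        dates=pd.DatetimeIndex(df["date"]),
        air_temp=df["air_temp_c"].to_numpy(),
        snow_depth=df["snow_depth_m"].to_numpy(),
        shoveling_dates=shovel,
    )


def write_ice_series(ice: IceSeries, path) -> None:
    ice.to_frame().to_csv(path, index=False)


def write_inp(
    path,
    histories: list[EncounterHistory],
    groups: list[str],
    covariates: pd.DataFrame | None = None,
    group_levels: list[str] | None = None,
) -> None:
    """Write encounter histories in the ``.inp`` dialect (see module docstring)."""
    if group_levels is None:
        seen = list(dict.fromkeys(groups))
        group_levels = seen
    lines = []
    for i, h in enumerate(histories):
        dummies = " ".join("1" if groups[i] == g else "0" for g in group_levels)
        covs = ""
        if covariates is not None and len(covariates.columns):
            covs = " " + " ".join(f"{covariates.iloc[i][c]:.6g}" for c in covariates.columns)
        lines.append(f"{h.as_string()} {dummies}{covs} ;")
    header = f"/* groups: {' '.join(group_levels)}"
    if covariates is not None and len(covariates.columns):
        header += f" | covariates: {' '.join(covariates.columns)}"
    header += " */"
    Path(path).write_text(header + "\n" + "\n".join(lines) + "\n")


def read_inp(path) -> tuple[list[EncounterHistory], list[str], pd.DataFrame]:
    """Parse an ``.inp`` file back into histories, group labels and covariates."""
    text = Path(path).read_text()
    group_levels, cov_names = [], []
    lines = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("/*"):
            body = line.strip("/* ").rstrip(" */")
            if body.startswith("groups:"):
                parts = body.split("|")
                group_levels = parts[0].split(":", 1)[1].split()
                if len(parts) > 1 and "covariates:" in parts[1]:
                    cov_names = parts[1].split(":", 1)[1].split()
            continue
        lines.append(line.rstrip(";").split())
    histories, groups, cov_rows = [], [], []
    for i, fields in enumerate(lines):
        bits = np.array([int(c) for c in fields[0]])
        histories.append(EncounterHistory(fish_id=f"f{i}", bits=bits, pooled=len(bits) < 20))
        ng = len(group_levels) if group_levels else 0
        dummies = [int(x) for x in fields[1 : 1 + ng]]
        groups.append(group_levels[dummies.index(1)] if ng else "all")
        cov_rows.append([float(x) for x in fields[1 + ng :]])
    if cov_rows and len(cov_rows[0]):
        names = cov_names or [f"cov{j}" for j in range(len(cov_rows[0]))]
        cov = pd.DataFrame(cov_rows, columns=names)
    else:
        cov = pd.DataFrame()
    return histories, groups, cov
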