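"""Commute exposure: binned worker counts → per-mode distance → mode shares.

The census records, per worker, a single main commute mode and a one-way
home-to-work distance grouped into seven bins (0–1, 2–5, 6–10, 11–20, 21–30,
31–50, >50 km). Walking is reported only up to 10 km and cycling up to 30 km,
so the longer bins are structural zeros for those modes. Multiplying each
bin's worker count by a representative one-way distance and summing over bins
gives the total daily commute distance per mode — the exposure variable M_m
of the fatality model. Because the census records only the main mode, access
and egress walking for public-transport trips (IPT, bus, train) would
otherwise be lost; a configurable per-commuter walk increment restores it
for PT commuters travelling beyond the first bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MODES: tuple[str, ...] = ("walk", "cycle", "2W", "car", "IPT", "bus", "train")
PT_MODES: tuple[str, ...] = ("IPT", "bus", "train")
#: on-road modes entering the regression and scenario models (train excluded)
ROAD_MODES: tuple[str, ...] = ("walk", "cycle", "2W", "car", "IPT", "bus")

BINS: tuple[str, ...] = ("0-1", "2-5", "6-10", "11-20", "21-30", "31-50", ">50")
#: last bin index (inclusive) with possible non-zero counts, per capped mode
_MODE_BIN_CAP = {"walk": 2, "cycle": 4}  # walk ≤ 10 km, cycle ≤ 30 km

#: closed-bin midpoints, km one-way; the open >50 km bin is configurable
_CLOSED_MIDPOINTS = (0.5, 3.5, 8.0, 15.5, 25.5, 40.5)
DEFAULT_OPEN_BIN_KM = 60.0


def bin_representative_distances(
    overrides: Mapping[str, float] | None = None,
    open_bin_km: float = DEFAULT_OPEN_BIN_KM,
) -> dict[str, float]:
    """Representative one-way distance (km) for each census distance bin.

    Defaults are the closed-bin midpoints plus ``open_bin_km`` for >50 km.
    ``overrides``, if given, must cover every bin with positive values and
    replaces the defaults wholesale.
    """
    if overrides is None:
        reps = dict(zip(BINS[:-1], _CLOSED_MIDPOINTS))
        reps[BINS[-1]] = float(open_bin_km)
    else:
        missing = [b for b in BINS if b not in overrides]
        if missing:
            raise ValueError(f"bin override missing bins {missing}")
        reps = {b: float(overrides[b]) for b in BINS}
    bad = [b for b, v in reps.items() if not v > 0]
    if bad:
        raise ValueError(f"non-positive representative distance for bins {bad}")
    return reps


@dataclass(frozen=True)
class CommuteBinTable:
    """Worker counts for one unit, as a mode × distance-bin matrix."""

    unit_id: str
    counts: np.ndarray  # shape (len(MODES), len(BINS))

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (len(MODES), len(BINS)):
            raise ValueError(
                f"counts must be {len(MODES)}×{len(BINS)} (mode × bin), "
                f"got {counts.shape}"
            )
        if (counts < 0).any():
            raise ValueError(f"unit {self.unit_id!r}: negative worker count")
        for mode, cap in _MODE_BIN_CAP.items():
            m = MODES.index(mode)
            if counts[m, cap + 1 :].any():
                raise ValueError(
                    f"unit {self.unit_id!r}: {mode} counts beyond the "
                    f"{BINS[cap]} km bin must be zero"
                )
        object.__setattr__(self, "counts", counts)

    def count(self, mode: str, bin_label: str) -> float:
        return float(self.counts[MODES.index(mode), BINS.index(bin_label)])


@dataclass(frozen=True)
class ExposureTable:
    """Per-unit total one-way commute distance by mode, and mode shares."""

    unit_id: str
    distance_km: Mapping[str, float]
    pt_walk_km: float = 0.0
    shares: Mapping[str, float] = field(default_factory=dict)


def total_mode_distance(
    table: CommuteBinTable, reps: Mapping[str, float] | None = None
) -> dict[str, float]:
    """Σ over bins of worker count × representative distance, per mode (km)."""
    reps = bin_representative_distances() if reps is None else reps
    rep_vec = np.array([reps[b] for b in BINS])
    totals = table.counts @ rep_vec
    return {m: float(t) for m, t in zip(MODES, totals)}


def add_pt_access_walk(
    table: CommuteBinTable,
    distances: Mapping[str, float],
    walk_per_trip: float = 1.0,
) -> dict[str, float]:
    """Add PT access/egress walking to the walk distance total.

    Each IPT/bus/train commuter whose trip falls beyond the 0–1 km bin
    contributes ``walk_per_trip`` km of walking (the default 1 km covers both
    ends of the trip). Train vehicular distance never enters the regression,
    but its access walking does — it is covered on the road network. PT
    vehicular distances are left unchanged.
    """
    if walk_per_trip < 0:
        raise ValueError("walk_per_trip must be non-negative")
    out = {m: float(distances[m]) for m in distances}
    pt_rows = [MODES.index(m) for m in PT_MODES]
    n_pt_commuters = float(table.counts[pt_rows, 1:].sum())
    out["walk"] = out.get("walk", 0.0) + walk_per_trip * n_pt_commuters
    return out


def pt_access_walk_km(table: CommuteBinTable, walk_per_trip: float = 1.0) -> float:
    """The walking distance added by :func:`add_pt_access_walk` alone."""
    if walk_per_trip < 0:
        raise ValueError("walk_per_trip must be non-negative")
    pt_rows = [MODES.index(m) for m in PT_MODES]
    return walk_per_trip * float(table.counts[pt_rows, 1:].sum())


def mode_shares(
    distances: Mapping[str, float], modes: Sequence[str] = MODES
) -> dict[str, float]:
    """Each included mode's fraction of the total commute distance.

    Shares sum to one; an all-zero input has no defined shares and is
    rejected.
    """
    vals = {m: float(distances.get(m, 0.0)) for m in modes}
    if any(v < 0 for v in vals.values()):
        raise ValueError("negative distance")
    total = sum(vals.values())
    if total <= 0:
        raise ValueError("cannot form mode shares: total distance is zero")
    return {m: v / total for m, v in vals.items()}


def build_exposure(
    table: CommuteBinTable,
    reps: Mapping[str, float] | None = None,
    walk_per_trip: float = 1.0,
    share_modes: Sequence[str] = MODES,
) -> ExposureTable:
    """Full exposure construction for one unit: distances, PT walk, shares."""
    base = total_mode_distance(table, reps)
    pt_walk = pt_access_walk_km(table, walk_per_trip)
    dist = add_pt_access_walk(table, base, walk_per_trip)
    return ExposureTable(
        unit_id=table.unit_id,
        distance_km=dist,
        pt_walk_km=pt_walk,
        shares=mode_shares(dist, share_modes),
    )


def load_commute_bins(path: str | Path) -> dict[str, CommuteBinTable]:
    """Read the long-format ``commute_bins.csv`` (unit_id, mode, bin, workers).

    Modes outside the seven analysis modes (e.g. water transport, "any
    other") are dropped at ingest.
    """
    df = pd.read_csv(path, dtype={"unit_id": str, "mode": str, "bin_label": str})
    required = {"unit_id", "mode", "bin_label", "workers"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    df = df[df["mode"].isin(MODES)]
    bad_bins = set(df["bin_label"]) - set(BINS)
    if bad_bins:
        raise ValueError(f"{path}: unknown bin label(s) {sorted(bad_bins)}")
    tables: dict[str, CommuteBinTable] = {}
    for unit_id, grp in df.groupby("unit_id", sort=False):
        counts = np.zeros((len(MODES), len(BINS)))
        for _, row in grp.iterrows():
            counts[MODES.index(row["mode"]), BINS.index(row["bin_label"])] += float(
                row["workers"]
            )
        tables[unit_id] = CommuteBinTable(unit_id=unit_id, counts=counts)
    return tables


def commute_bins_to_frame(tables: Mapping[str, CommuteBinTable]) -> pd.DataFrame:
    """Long-format DataFrame round-trippable through :func:`load_commute_bins`."""
    rows = []
    for unit_id, t in tables.items():
        for m_i, mode in enumerate(MODES):
            for b_i, bin_label in enumerate(BINS):
                rows.append(
                    {
                        "unit_id": unit_id,
                        "mode": mode,
                        "bin_label": bin_label,
                        "workers": t.counts[m_i, b_i],
                    }
                )
    return pd.DataFrame(rows)


def exposure_to_frame(exposures: Sequence[ExposureTable]) -> pd.DataFrame:
    """Wide ``exposure.csv`` layout: distances, pt walk and shares per unit."""
    rows = []
    for e in exposures:
        row: dict = {"unit_id": e.unit_id}
        for m in MODES:
            row[f"dist_{m}_km"] = e.distance_km.get(m, 0.0)
        row["pt_walk_km"] = e.pt_walk_km
        for m in MODES:
            if m in e.shares:
                row[f"share_{m}"] = e.shares[m]
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "MODES",
    "PT_MODES",
    "ROAD_MODES",
    "BINS",
    "DEFAULT_OPEN_BIN_KM",
    "CommuteBinTable",
    "ExposureTable",
    "bin_representative_distances",
    "total_mode_distance",
    "add_pt_access_walk",
    "pt_access_walk_km",
    "mode_shares",
    "build_exposure",
    "load_commute_bins",
    "commute_bins_to_frame",
    "exposure_to_frame",
]
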