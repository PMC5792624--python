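"""End-to-end pipeline: ingest → exposure → clustering → models → scenarios.

Each stage writes plain CSV/JSON artifacts into the output directory and a
manifest records input hashes, seeds and settings so any output can be
re-derived. A failure in any stage aborts with the stage named.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .clustering import (
    DEFAULT_RESTARTS,
    DEFAULT_SEED,
    choose_k,
    cluster_profile,
    kmeans,
    share_rate_correlation,
)
from .data import (
    DEFAULT_YEARS,
    StudyFrame,
    fatality_rate,
    filter_units,
    load_area_units,
    validation_report,
    write_canonical,
)
from .exposure import (
    MODES,
    bin_representative_distances,
    build_exposure,
    exposure_to_frame,
    load_commute_bins,
)
from .model import SamplerConfig, fit_model_sequence, sequence_report
from .scenarios import EQ_EXPONENTS, run_standard_scenarios


@dataclass
class RunConfig:
    """Explicit settings for one pipeline run; all seeds are explicit."""

    units_csv: str
    commute_csv: str
    out_dir: str
    years: tuple[int, ...] = DEFAULT_YEARS
    subtract_rail: bool = True
    walk_per_trip: float = 1.0
    walk_grid: tuple[float, ...] = (0.0, 1.0, 1.5)
    open_bin_km: float = 60.0
    bin_overrides: Mapping[str, float] | None = None
    k_range: tuple[int, ...] = tuple(range(1, 11))
    cluster_seed: int = DEFAULT_SEED
    restarts: int = DEFAULT_RESTARTS
    elbow_threshold: float = 0.01
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    scenario_step_pp: float = 0.5
    scenario_steps: int = 10
    exponents: Mapping[str, float] = field(default_factory=lambda: dict(EQ_EXPONENTS))

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "sampler" in d and isinstance(d["sampler"], Mapping):
            d["sampler"] = SamplerConfig(**d["sampler"])
        for key in ("years", "walk_grid", "k_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "inputs": {},
        "settings": {
            "years": list(config.years),
            "subtract_rail": config.subtract_rail,
            "walk_per_trip": config.walk_per_trip,
            "walk_grid": list(config.walk_grid),
            "open_bin_km": config.open_bin_km,
            "k_range": list(config.k_range),
            "cluster_seed": config.cluster_seed,
            "restarts": config.restarts,
            "elbow_threshold": config.elbow_threshold,
            "sampler": vars(config.sampler).copy(),
            "scenario_step_pp": config.scenario_step_pp,
            "scenario_steps": config.scenario_steps,
            "exponents": dict(config.exponents),
        },
        "stages": [],
    }

    # ingest ---------------------------------------------------------------
    try:
        units_path = Path(config.units_csv)
        manifest["inputs"]["units_csv"] = {
            "path": str(units_path),
            "sha256": _sha256(units_path),
        }
        frame = load_area_units(units_path, config.years)
        frame = filter_units(frame)
        if len(frame) == 0:
            raise ValueError("no units remain after the island filter")
        write_canonical(frame, out / "units_validated.csv", out / "validation.json")
        manifest["stages"].append("ingest")
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError("ingest", e) from e

    # exposure -------------------------------------------------------------
    try:
        commute_path = Path(config.commute_csv)
        manifest["inputs"]["commute_csv"] = {
            "path": str(commute_path),
            "sha256": _sha256(commute_path),
        }
        tables = load_commute_bins(commute_path)
        missing = [u.unit_id for u in frame.units if u.unit_id not in tables]
        if missing:
            raise ValueError(f"no commute bins for units {missing}")
        reps = bin_representative_distances(
            config.bin_overrides, open_bin_km=config.open_bin_km
        )
        exposures = [
            build_exposure(
                tables[u.unit_id], reps=reps, walk_per_trip=config.walk_per_trip
            )
            for u in frame.units
        ]
        exposure_to_frame(exposures).to_csv(out / "exposure.csv", index=False)
        manifest["stages"].append("exposure")
    except Exception as e:  # noqa: BLE001
        raise StageError("exposure", e) from e

    # clustering -----------------------------------------------------------
    try:
        shares = pd.DataFrame(
            {m: [e.shares[m] for e in exposures] for m in MODES},
            index=[e.unit_id for e in exposures],
        )
        rates = pd.Series(
            [fatality_rate(u, frame.years, config.subtract_rail) for u in frame.units],
            index=[u.unit_id for u in frame.units],
        )
        k, curve = choose_k(
            shares,
            config.k_range,
            seed=config.cluster_seed,
            restarts=config.restarts,
            threshold=config.elbow_threshold,
        )
        result = kmeans(shares, k, seed=config.cluster_seed, restarts=config.restarts)
        pd.DataFrame(
            {"unit_id": list(result.assignments), "cluster": list(result.assignments.values())}
        ).to_csv(out / "clusters.csv", index=False)
        profiles = cluster_profile(result, shares, rates)
        profiles.to_csv(out / "cluster_profiles.csv")
        (out / "wss_curve.json").write_text(
            json.dumps({"chosen_k": k, "wss": {str(kk): v for kk, v in curve.items()}},
                       indent=2)
        )
        (out / "share_rate_correlations.json").write_text(
            json.dumps(share_rate_correlation(shares, rates), indent=2)
        )
        manifest["stages"].append("cluster")
    except Exception as e:  # noqa: BLE001
        raise StageError("cluster", e) from e

    # hierarchical model sequence -------------------------------------------
    try:
        table_dict = {u.unit_id: tables[u.unit_id] for u in frame.units}
        results = fit_model_sequence(
            frame,
            table_dict,
            config=config.sampler,
            walk_grid=config.walk_grid,
            subtract_rail=config.subtract_rail,
            reps=reps,
        )
        report = sequence_report(results)
        report.columns = [f"{m}_{s}" for m, s in report.columns]
        report.to_csv(out / "table3.csv")
        diag = {key: res.diagnostics() for key, res in results.items()}
        (out / "model_diagnostics.json").write_text(json.dumps(diag, indent=2))
        manifest["stages"].append("fit")
    except Exception as e:  # noqa: BLE001
        raise StageError("fit", e) from e

    # scenarios --------------------------------------------------------------
    try:
        baselines = {
            f"cluster{int(c)}": {
                m: profiles.loc[c, f"share_{m}"]
                for m in MODES
                if f"share_{m}" in profiles.columns
            }
            for c in profiles.index
        }
        rr = run_standard_scenarios(
            baselines,
            exponents=config.exponents,
            step_pp=config.scenario_step_pp,
            n_steps=config.scenario_steps,
        )
        rr.to_csv(out / "rr_curves.csv", index=False)
        manifest["stages"].append("scenarios")
    except Exception as e:  # noqa: BLE001
        raise StageError("scenarios", e) from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


__all__ = ["RunConfig", "StageError", "run_pipeline"]
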