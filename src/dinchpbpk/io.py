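"""Dataset containers, CSV/JSON readers and writers, and run configuration.

Void datasets are tidy CSV tables with one row per urine void:

    volunteer_id, time_h, interval_h, volume_L, creatinine_g_per_L,
    conc_OH_mg_per_g_creat, conc_cx_mg_per_g_creat, bw_kg, dose_mg_per_kg

Depletion curves are CSV tables (time_min, total_conc_uM, binding_conc_uM)
with the incubation metadata (volume, protein mass) in a sidecar JSON file.
Every artifact written by the pipeline embeds the seed, the configuration
hash and the package version so that deterministic stages are bit-for-bit
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .exceptions import ConfigError, InputError
from .ivive import DepletionCurve
from .params import (
    ParameterBundle,
    UrineParams,
    apply_overrides,
    default_bundle,
    parameter_names,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VoidDataset",
    "read_voids",
    "write_voids",
    "read_depletion",
    "write_depletion",
    "RunConfig",
    "load_config",
    "load_default_parameters",
    "default_parameter_file",
    "write_result_json",
]

VOID_COLUMNS = (
    "volunteer_id",
    "time_h",
    "interval_h",
    "volume_L",
    "creatinine_g_per_L",
    "conc_OH_mg_per_g_creat",
    "conc_cx_mg_per_g_creat",
    "bw_kg",
    "dose_mg_per_kg",
)


@dataclass
class VoidDataset:
    """Timed urine-void observations for one or more volunteers."""

    observations: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.observations
        missing = [c for c in VOID_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"void dataset missing columns: {missing}")
        for vid, grp in df.groupby("volunteer_id"):
            t = grp["time_h"].to_numpy()
            if not np.all(np.diff(t) > 0):
                raise InputError(f"void times not increasing for volunteer {vid!r}")
        for col in (
            "conc_OH_mg_per_g_creat",
            "conc_cx_mg_per_g_creat",
            "volume_L",
            "creatinine_g_per_L",
        ):
            if (df[col] < 0).any():
                raise InputError(f"negative values in column {col!r}")
        self.observations = df.reset_index(drop=True)

    @property
    def volunteers(self) -> list[str]:
        return list(dict.fromkeys(self.observations["volunteer_id"]))

    def covariates(self, volunteer_id: str) -> dict[str, float]:
        grp = self.observations[self.observations["volunteer_id"] == volunteer_id]
        if grp.empty:
            raise InputError(f"no rows for volunteer {volunteer_id!r}")
        return {
            "bw": float(grp["bw_kg"].iloc[0]),
            "dose": float(grp["dose_mg_per_kg"].iloc[0]),
        }

    def schedule(self, volunteer_id: str) -> tuple[float, ...]:
        grp = self.observations[self.observations["volunteer_id"] == volunteer_id]
        return tuple(float(t) for t in grp["time_h"])

    def long(self) -> pd.DataFrame:
        """One row per (void, metabolite) observation."""
        rows = []
        for _, r in self.observations.iterrows():
            for met, col in (
                ("OH", "conc_OH_mg_per_g_creat"),
                ("cx", "conc_cx_mg_per_g_creat"),
            ):
                rows.append(
                    {
                        "volunteer_id": r["volunteer_id"],
                        "time_h": r["time_h"],
                        "metabolite": met,
                        "concentration": r[col],
                    }
                )
        return pd.DataFrame(rows)


def read_voids(path: str | Path) -> VoidDataset:
    df = pd.read_csv(path)
    return VoidDataset(df)


def write_voids(dataset: VoidDataset, path: str | Path) -> None:
    dataset.observations.to_csv(path, index=False, columns=list(VOID_COLUMNS))


def read_depletion(
    path: str | Path, metadata_path: str | Path | None = None
) -> DepletionCurve:
    """Read a depletion CSV plus its incubation-metadata sidecar."""
    df = pd.read_csv(path)
    for col in ("time_min", "total_conc_uM", "binding_conc_uM"):
        if col not in df.columns:
            raise InputError(f"depletion file missing column {col!r}")
    volume, protein = 1.0, 0.5
    if metadata_path is None:
        candidate = Path(path).with_suffix(".json")
        metadata_path = candidate if candidate.exists() else None
    if metadata_path is not None:
        meta = json.loads(Path(metadata_path).read_text())
        volume = float(meta.get("incubation_volume_ml", volume))
        protein = float(meta.get("protein_mg", protein))
    return DepletionCurve(
        times=df["time_min"].to_numpy(dtype=float),
        total_conc=df["total_conc_uM"].to_numpy(dtype=float),
        binding_conc=df["binding_conc_uM"].to_numpy(dtype=float),
        incubation_volume=volume,
        protein_mass=protein,
    )


def write_depletion(curve: DepletionCurve, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {
            "time_min": curve.times,
            "total_conc_uM": curve.total_conc,
            "binding_conc_uM": curve.binding_conc,
        }
    ).to_csv(path, index=False)
    path.with_suffix(".json").write_text(
        json.dumps(
            {
                "incubation_volume_ml": curve.incubation_volume,
                "protein_mg": curve.protein_mass,
            },
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class RunConfig(BaseModel):
    """Validated run configuration for the pipeline stages."""

    model_config = ConfigDict(extra="forbid")

    stage: str = "simulate"
    seed: int = 0
    parameters: dict[str, float] = Field(default_factory=dict)
    void_times: list[float] = Field(default_factory=list)
    t_end: float = 50.0
    solver: str = "expm"
    rtol: float = 1e-8
    atol: float = 1e-10
    output_dir: str = "."

    def bundle(self) -> ParameterBundle:
        known = set(parameter_names())
        unknown = [k for k in self.parameters if k not in known]
        if unknown:
            raise ConfigError(f"unknown parameter names: {unknown}")
        b = apply_overrides(default_bundle(), self.parameters)
        if self.void_times:
            import dataclasses

            b = dataclasses.replace(
                b,
                urine=UrineParams(
                    r_urine=b.urine.r_urine,
                    creat=b.urine.creat,
                    void_times=tuple(self.void_times),
                ),
            )
        return b


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration.

    Unknown keys are rejected with the offending field named; absent fields
    take the published defaults.
    """
    try:
        raw = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        cfg = RunConfig(**raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(x) for x in first["loc"]) or "<root>"
        raise ConfigError(f"invalid config field {loc!r}: {first['msg']}") from exc
    cfg.bundle()  # validate parameter names eagerly
    return cfg


def default_parameter_file() -> Path:
    return Path(__file__).parent / "data" / "default_parameters.json"


def load_default_parameters() -> dict[str, float]:
    """The shipped default-parameter file (published point values)."""
    return json.loads(default_parameter_file().read_text())


def config_hash(obj: Any) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_result_json(
    payload: Mapping[str, Any],
    path: str | Path,
    seed: int | None = None,
    config: Mapping[str, Any] | None = None,
) -> None:
    """Write a result JSON with provenance metadata attached."""
    from . import __version__

    meta = {"package_version": __version__}
    if seed is not None:
        meta["seed"] = seed
    if config is not None:
        meta["config_hash"] = config_hash(dict(config))
    out = {"meta": meta, **payload}
    Path(path).write_text(json.dumps(out, indent=2, default=_jsonable))
    logger.info("wrote %s (seed=%s)", path, seed)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serialisable: {type(obj)}")
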