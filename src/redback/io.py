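"""Readers/writers and configuration for the pipeline.

All tables are plain CSV.  Output tables carry a header comment line with
the master seed and a hash of the configuration so runs are traceable.
Configuration and ground-truth sidecars are YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import StudyDesign
from .growth import GrowthObservation, GrowthParams
from .projection import ProjectionConfig
from .scr import CAPTURE_COLUMNS, CaptureTable, MCMCConfig, SCRParams

__all__ = [
    "PipelineConfig",
    "read_capture_csv",
    "write_capture_csv",
    "read_growth_csv",
    "write_growth_csv",
    "write_truth_yaml",
    "read_truth_yaml",
    "write_table",
    "read_table",
    "write_ascii_grid",
]


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings with embedded defaults."""

    out_dir: str = "results"
    master_seed: int = 20170315
    simulate: bool = True
    capture_csv: dict[str, str] = field(default_factory=dict)  # plot -> path
    growth_csv: str | None = None
    clutch_csv: str | None = None
    # design
    buffer_m: float = 10.5
    # simulation truth (per plot), defaults at the fitted field values
    scr_truth: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "mature": dict(phi=0.996, sigma=3.496, lam=0.019, density=0.613, tau=0.989),
            "successional": dict(
                phi=0.993, sigma=3.823, lam=0.015, density=0.432, tau=1.097
            ),
        }
    )
    growth_truth: dict[str, float] = field(
        default_factory=lambda: dict(
            L_male=43.569,
            L_female=52.164,
            beta0_K=0.237,
            beta1_K=0.102,
            beta2_K=0.434,
        )
    )
    n_growth_individuals: int = 200
    sigma_obs: float = 0.5
    # MCMC scale: "test" keeps everything desk-sized
    scale: str = "test"
    scr_mcmc: dict[str, int] = field(
        default_factory=lambda: dict(n_chains=1, n_iter=900, n_burn=300, thin=1)
    )
    rhat_threshold: float = 1.05
    # space use (desk-scale defaults; the field protocol uses 0.1-m cells,
    # 1000 use points and 1000 posterior draws)
    kernel: str = "halfnormal"
    raster_cell: float = 0.2
    n_use_points: int = 500
    n_spaceuse_draws: int = 2
    spaceuse_region: float = 5.0  # margin (m) around the boards in the window
    # projection
    projection: dict = field(default_factory=dict)

    def design(self) -> StudyDesign:
        return StudyDesign(buffer=self.buffer_m)

    def projection_config(self) -> ProjectionConfig:
        return ProjectionConfig(**self.projection)

    def scr_mcmc_config(self) -> MCMCConfig:
        return MCMCConfig(rhat_threshold=self.rhat_threshold, **self.scr_mcmc)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


# ---- capture tables -------------------------------------------------------


def write_capture_csv(table: CaptureTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def read_capture_csv(path: str | Path, design: StudyDesign | None = None) -> CaptureTable:
    """Read and validate a long-format capture table.

    Rows referencing boards outside the design or occasions outside the
    calendar are rejected with their row numbers.
    """
    df = pd.read_csv(path, comment="#")
    if len(df) == 0 and not set(CAPTURE_COLUMNS) <= set(df.columns):
        raise ValueError("capture CSV is missing required columns")
    for col in ("svl_mm", "sex"):
        if col not in df.columns:
            df[col] = np.nan if col == "svl_mm" else ""
    df["sex"] = df["sex"].fillna("")
    table = CaptureTable(df)
    if design is not None:
        table.validate_against(design)
    return table


# ---- growth tables --------------------------------------------------------


def write_growth_csv(obs: list[GrowthObservation], path: str | Path) -> None:
    rows = []
    for o in obs:
        for k, s in enumerate(o.svl):
            rows.append(
                {
                    "individual_id": o.individual_id,
                    "sex": o.sex,
                    "plot": o.plot,
                    "capture_index": k + 1,
                    "interval_days": 0.0 if k == 0 else float(o.intervals_days[k - 1]),
                    "svl_mm": float(s),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_growth_csv(path: str | Path) -> list[GrowthObservation]:
    df = pd.read_csv(path, comment="#")
    out = []
    for ind, g in df.sort_values(["individual_id", "capture_index"]).groupby(
        "individual_id", sort=True
    ):
        out.append(
            GrowthObservation(
                individual_id=str(ind),
                sex=g["sex"].iloc[0],
                plot=g["plot"].iloc[0],
                svl=g["svl_mm"].to_numpy(),
                intervals_days=g["interval_days"].to_numpy()[1:],
            )
        )
    return out


# ---- truth sidecars and generic tables ------------------------------------


def write_truth_yaml(path: str | Path, scr: SCRParams | None = None, growth: GrowthParams | None = None, seed: int | None = None) -> None:
    doc: dict = {}
    if scr is not None:
        doc["scr"] = asdict(scr)
    if growth is not None:
        doc["growth"] = asdict(growth)
    if seed is not None:
        doc["seed"] = seed
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_truth_yaml(path: str | Path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    out = dict(doc)
    if "scr" in doc:
        out["scr"] = SCRParams(**doc["scr"])
    if "growth" in doc:
        out["growth"] = GrowthParams(**doc["growth"])
    return out


def write_table(df: pd.DataFrame, path: str | Path, seed: int, config_hash: str, index: bool = False) -> None:
    """Write a CSV with a provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} config={config_hash}\n")
        df.to_csv(fh, index=index)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def write_ascii_grid(p: np.ndarray, x0: float, y0: float, cell: float, path: str | Path, nodata: float = -9999.0) -> None:
    """Write a raster as an ESRI ASCII grid (row 1 = northernmost row)."""
    ny, nx = p.shape
    header = (
        f"ncols {nx}\nnrows {ny}\nxllcorner {x0}\nyllcorner {y0}\n"
        f"cellsize {cell}\nNODATA_value {nodata}\n"
    )
    body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in p[::-1])
    Path(path).write_text(header + body + "\n")
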