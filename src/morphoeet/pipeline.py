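"""End-to-end orchestration: morphometry -> rates -> stereology -> k ->
delta c -> fractional differences -> MER.

The pipeline consumes a per-cell dimension table and an assay table
(either measured, or produced by the ``segment``/``simulate`` stages),
builds per-day population summaries for the test and control
conditions, and reports the per-day morphology effect ratio.  Choosing
a mass-transfer-limiting cell/mediator concentration combination is an
experimental-design step left to the user; the pipeline records the
concentrations used and warns when the cell concentration falls below
1e7 cells/ml, the order below which mass-transfer limitation is not
expected.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .eet import (
    AssayTimeSeries,
    CultureSnapshot,
    MERResult,
    ReductionRate,
    absorbance_to_conc,
    conc_difference,
    fractional_differences,
    mean_reduction_rate,
)
from .errors import PipelineStageError
from .io import (
    MER_COLUMNS,
    SNAPSHOT_COLUMNS,
    read_assays,
    read_dimensions,
    write_table,
)
from .mass_transfer import (
    PhysicalParams,
    mass_transfer_coefficient,
    propagate_k_error,
)
from .stereology import CellDimensions, bin_regress, predict_mean_property
from .imaging import weighted_population_stats
from .units import um2_to_m2

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

MASS_TRANSFER_LIMIT_CELLS_PER_ML = 1e7


class PhysicalParamsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    diffusivity_m2s: float = 7.44e-10
    rho_p_kgm3: float = 1040.0
    rho_c_kgm3: float = 995.65
    g_ms2: float = 9.80665
    mu_c_kgms: float = 7.9735e-4

    def to_params(self) -> PhysicalParams:
        return PhysicalParams(**self.model_dump())


class QCSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_eccentricity: float = 0.6
    max_minor_axis_um: float = 2.0
    min_area_px: int = 20
    exclude_border: bool = True


class RegressionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bin_width_um: float = 0.4
    min_bin_count: int = 50
    degree: int = 1


class ConventionsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    doubling_time: str = "decadic"
    test_label: str = "diluted"
    control_label: str = "control"


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    physical_params: PhysicalParamsConfig = Field(
        default_factory=PhysicalParamsConfig
    )
    qc: QCSection = Field(default_factory=QCSection)
    regression: RegressionSection = Field(default_factory=RegressionSection)
    conventions: ConventionsSection = Field(default_factory=ConventionsSection)
    output_dir: str = "morphoeet_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    snapshots: List[CultureSnapshot]
    mer: Dict[float, MERResult]
    provenance: dict
    output_files: Dict[str, str]


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage(name):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, str(exc)) from exc
        return wrapper
    return decorate


@_stage("read-dimensions")
def _load_dimensions(path):
    return read_dimensions(path)


@_stage("read-assays")
def _load_assays(path):
    return read_assays(path)


@_stage("morphometry-stats")
def _population_stats(dims: pd.DataFrame) -> pd.DataFrame:
    """Per (condition, day) weighted mean length/width across images."""
    rows = []
    for (cond, day), group in dims.groupby(["sample_id", "day"]):
        per_image = group.groupby("image_id").agg(
            mean_length=("length_um", "mean"),
            mean_width=("width_um", "mean"),
            count=("length_um", "size"),
        )
        mean_l, _, sem_l = weighted_population_stats(
            per_image["mean_length"], per_image["count"]
        )
        mean_w, _, _ = weighted_population_stats(
            per_image["mean_width"], per_image["count"]
        )
        rows.append(
            {
                "condition": cond,
                "day": day,
                "mean_length_um": mean_l,
                "sem_length": sem_l,
                "mean_width_um": mean_w,
                "n_cells": int(per_image["count"].sum()),
            }
        )
    return pd.DataFrame(rows)


@_stage("length-regression")
def _area_regressions(dims: pd.DataFrame, reg_cfg: RegressionSection):
    """Pooled (all-days) length->area regression per condition."""
    regs = {}
    for cond, group in dims.groupby("sample_id"):
        cells = [
            CellDimensions(length_um=l, width_um=w)
            for l, w in zip(group["length_um"], group["width_um"])
        ]
        regs[cond] = bin_regress(
            cells,
            "area",
            bin_width_um=reg_cfg.bin_width_um,
            min_bin_count=reg_cfg.min_bin_count,
            degree=reg_cfg.degree,
        )
    return regs


@_stage("assay-rates")
def _assay_rates(assays: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (cond, day), group in assays.groupby(["sample_id", "day"]):
        replicates = []
        for _, rep in group.groupby("replicate"):
            rep = rep.sort_values("time_min")
            conc = [
                absorbance_to_conc(a, e, p)
                for a, e, p in zip(
                    rep["absorbance"], rep["extinction_mM_cm"], rep["path_cm"]
                )
            ]
            cell_conc = float(rep["cell_conc_per_ml"].iloc[0])
            if cell_conc < MASS_TRANSFER_LIMIT_CELLS_PER_ML:
                warnings.warn(
                    f"{cond} day {day}: cell concentration "
                    f"{cell_conc:.3g}/ml is below 1e7/ml; the assay may "
                    "not be mass-transfer limited",
                    UserWarning,
                    stacklevel=2,
                )
            replicates.append(
                AssayTimeSeries(
                    times_min=tuple(rep["time_min"]),
                    concentration_mM=tuple(conc),
                    cell_conc_per_ml=cell_conc,
                )
            )
        rate = mean_reduction_rate(replicates)
        rows.append(
            {
                "condition": cond,
                "day": day,
                "rate_mol_cell_s": rate.rate_mol_per_cell_s,
                "sem_rate": rate.sem,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    cfg: PipelineConfig,
    dimensions_csv: str | Path,
    assay_csv: str | Path,
) -> RunReport:
    """Execute the full analysis and write all outputs.

    Any stage failure raises :class:`PipelineStageError` carrying the
    stage name.  Outputs (snapshot, MER and rejection-log CSVs plus a
    JSON report) are written under ``cfg.output_dir``.
    """
    dimensions_csv = Path(dimensions_csv)
    assay_csv = Path(assay_csv)
    for path, stage in ((dimensions_csv, "read-dimensions"),
                        (assay_csv, "read-assays")):
        if not path.exists():
            raise PipelineStageError(stage, f"input file not found: {path}")

    dims = _load_dimensions(dimensions_csv)
    assays = _load_assays(assay_csv)
    stats = _population_stats(dims)
    regs = _area_regressions(dims, cfg.regression)
    rates = _assay_rates(assays)
    params = cfg.physical_params.to_params()

    try:
        merged = stats.merge(rates, on=["condition", "day"], how="inner")
        if merged.empty:
            raise ValueError(
                "no (condition, day) pair has both dimension and assay data"
            )
        snapshots: List[CultureSnapshot] = []
        for row in merged.itertuples(index=False):
            reg = regs[row.condition]
            area_pred, area_unc = predict_mean_property(
                reg, [row.mean_length_um]
            )
            area_um2 = float(area_pred[0])
            sem_area = float(area_unc[0])
            ktr = mass_transfer_coefficient(row.mean_length_um, params)
            sem_k = propagate_k_error(
                row.mean_length_um, row.sem_length, params
            )
            dc = conc_difference(
                r=ReductionRate(row.rate_mol_cell_s, row.sem_rate),
                k=ktr.k_ms,
                area_m2=um2_to_m2(area_um2),
                k_sem=sem_k,
                area_sem_m2=um2_to_m2(sem_area),
            )
            snapshots.append(
                CultureSnapshot(
                    day=float(row.day),
                    condition=row.condition,
                    mean_length_um=row.mean_length_um,
                    sem_length=row.sem_length,
                    mean_width_um=row.mean_width_um,
                    mean_area_um2=area_um2,
                    sem_area=sem_area,
                    k_ms=ktr.k_ms,
                    sem_k=sem_k,
                    rate_mol_cell_s=row.rate_mol_cell_s,
                    sem_rate=row.sem_rate,
                    delta_c_molm3=dc.delta_c_molm3,
                    sem_delta_c=dc.sem,
                )
            )
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("conc-difference", str(exc)) from exc

    try:
        test_label = cfg.conventions.test_label
        control_label = cfg.conventions.control_label
        by_key = {(s.condition, s.day): s for s in snapshots}
        days = sorted(
            {s.day for s in snapshots if s.condition == test_label}
            & {s.day for s in snapshots if s.condition == control_label}
        )
        if not days:
            raise ValueError(
                f"no day has snapshots for both '{test_label}' and "
                f"'{control_label}'"
            )
        mer: Dict[float, MERResult] = {}
        for day in days:
            mer[day] = fractional_differences(
                by_key[(test_label, day)], by_key[(control_label, day)]
            )
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("fractional-differences", str(exc)) from exc

    try:
        out_dir = Path(cfg.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        snap_df = pd.DataFrame([asdict(s) for s in snapshots])
        snap_df = snap_df[SNAPSHOT_COLUMNS].sort_values(
            ["condition", "day"]
        ).reset_index(drop=True)
        snap_path = write_table(snap_df, out_dir / "snapshots.csv")
        mer_df = pd.DataFrame(
            [{"day": day, **asdict(m)} for day, m in mer.items()]
        )[MER_COLUMNS]
        mer_path = write_table(mer_df, out_dir / "mer.csv")
        rejection_path = write_table(
            pd.DataFrame(
                columns=["image_id", "region_id", "rule_failed", "value"]
            ),
            out_dir / "rejections.csv",
        )
        provenance = {
            "software_version": __version__,
            "config_hash": cfg.content_hash(),
            "inputs": {
                "dimensions_csv": _file_digest(dimensions_csv),
                "assay_csv": _file_digest(assay_csv),
            },
            "seed": cfg.seed,
        }
        report = {
            "provenance": provenance,
            "days": days,
            "mer": {str(day): asdict(m) for day, m in mer.items()},
        }
        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    except Exception as exc:
        raise PipelineStageError("write-outputs", str(exc)) from exc

    return RunReport(
        snapshots=snapshots,
        mer=mer,
        provenance=provenance,
        output_files={
            "snapshots": str(snap_path),
            "mer": str(mer_path),
            "rejections": str(rejection_path),
            "report": str(report_path),
        },
    )
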