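"""End-to-end orchestration: stacks → per-punctum/per-cell tables → group stats.

`run_pipeline` drives segmentation and quantification over a manifest of
input stacks (real files or simulated scenes), producing per-punctum,
per-cell and per-construct summary tables with a provenance block (config
hash, package and library versions, seed).  Outputs are deterministic for
a fixed config + seed.

Table conventions follow the figure-caption bookkeeping used for this kind
of data: zero-punctum cells are included in puncta-density tables and
excluded from V_p/K_p/ΔG_Tr tables (their fields stay empty, never 0).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import yaml

from . import __version__ as _pkg_version
from .errors import StageError
from .io import ImageStack, read_stack, write_tables
from .metrics import CalibrationModel, CellMetrics, ThermoParams, cell_metrics
from .nuclei import measure_nuclei, segment_nuclei
from .puncta import DEFAULT_SCALES_UM, detect_puncta, log_response, measure_puncta
from .synth import SceneParams, generate_cell_stack

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "GroupComparison", "TrendFit", "analyze_stack",
           "run_pipeline", "compare_groups", "linear_trend"]

#: per-cell metric columns that exclude zero-punctum cells
PUNCTA_ONLY_METRICS = ("v_p", "dp", "k_p", "delta_g_tr", "periphery_fraction")


@dataclass
class RunConfig:
    """Manifest plus all stage parameters for one pipeline run.

    Each manifest entry is a dict with a ``construct`` label and either a
    ``path`` (TIFF/OME-TIFF) or a ``simulate`` block of
    :class:`~punctaquant.synth.SceneParams` overrides.
    """

    manifest: list[dict] = field(default_factory=list)
    seed: int = 0
    output_dir: str | None = None
    voxel_size_override: tuple[float, float, float] | None = None
    # nuclei
    smoothing_sigma_um: float = 0.25
    min_nucleus_volume_um3: float = 50.0
    # puncta
    scales_um: tuple[float, ...] = DEFAULT_SCALES_UM
    threshold_policy: str = "otsu"
    threshold_value: float | None = None
    min_seed_separation_um: float = 0.3
    include_cytoplasm: bool = False
    # metrics
    dp_method: str = "peak_corrected"
    psf_sigma_um: tuple[float, float, float] | None = None
    calibration_slope: float = 1.0
    calibration_offset: float = 0.0
    temperature_K: float = 310.15
    periphery_cutoff_um: float = 0.5
    # reporting
    test: str = "mannwhitney"

    def config_hash(self) -> str:
        blob = yaml.safe_dump(_plain(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("scales_um", "psf_sigma_um", "voxel_size_override"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        for entry in cfg.manifest:
            if "path" in entry and not Path(entry["path"]).exists():
                raise FileNotFoundError(f"manifest path {entry['path']} does not exist")
        return cfg


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class GroupComparison:
    metric: str
    group_a: str
    group_b: str
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    degenerate: bool = False


@dataclass
class TrendFit:
    slope: float
    intercept: float
    ci_lower: np.ndarray     # pointwise 95% band at the input x
    ci_upper: np.ndarray
    log_y: bool = False


def analyze_stack(stack: ImageStack, config: RunConfig) -> tuple[list, list, list[CellMetrics]]:
    """Segment and quantify one stack; returns (nuclei, puncta, cell metrics)."""
    nuclei_labels = segment_nuclei(
        stack, smoothing_sigma_um=config.smoothing_sigma_um,
        min_volume_um3=config.min_nucleus_volume_um3,
    )
    nucleus_records = measure_nuclei(nuclei_labels, stack)
    response = log_response(stack, scales_um=config.scales_um)
    puncta_labels = detect_puncta(
        response, stack, nuclei_labels,
        threshold_policy=config.threshold_policy,
        threshold_value=config.threshold_value,
        min_seed_separation_um=config.min_seed_separation_um,
        include_cytoplasm=config.include_cytoplasm,
    )
    punctum_records = measure_puncta(puncta_labels, stack, nuclei_labels,
                                     include_cytoplasm=config.include_cytoplasm)
    calib = CalibrationModel(config.calibration_slope, config.calibration_offset)
    thermo = ThermoParams(T=config.temperature_K)
    cells = [
        cell_metrics(nuc, punctum_records, nuclei_labels, puncta_labels, stack,
                     calib=calib, thermo=thermo, dp_method=config.dp_method,
                     psf_sigma_um=config.psf_sigma_um,
                     periphery_cutoff_um=config.periphery_cutoff_um)
        for nuc in nucleus_records
    ]
    return nucleus_records, punctum_records, cells


def _load_entry(entry: dict, config: RunConfig, index: int) -> tuple[str, ImageStack]:
    if "path" in entry:
        source = str(entry["path"])
        stack = read_stack(entry["path"],
                           voxel_size_override=config.voxel_size_override)
    elif "simulate" in entry:
        overrides = dict(entry["simulate"] or {})
        overrides.setdefault("seed", config.seed + index)
        for key in ("nucleus_semi_axes", "psf_sigma", "voxel_size", "shape"):
            if key in overrides and overrides[key] is not None:
                overrides[key] = tuple(overrides[key])
        params = SceneParams(**overrides)
        source = f"simulated[{index}](seed={params.seed})"
        stack, _ = generate_cell_stack(params)
    else:
        raise KeyError("manifest entry needs 'path' or 'simulate'")
    return source, stack


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full pipeline over the manifest.

    Returns ``{"puncta", "cells", "vp_kp", "summary", "provenance"}`` —
    per-punctum rows, all per-cell rows (zero-punctum cells included),
    the puncta-bearing subset used for V_p/K_p statistics, per-construct
    summaries (mean ± standard error), and a one-row provenance table.
    Tables are also written as CSV when ``config.output_dir`` is set.
    """
    puncta_rows, cell_rows = [], []
    for index, entry in enumerate(config.manifest):
        construct = entry.get("construct", "unlabelled")
        try:
            source, stack = _load_entry(entry, config, index)
            _, punctum_records, cells = analyze_stack(stack, config)
        except Exception as exc:
            raise StageError("analyze", entry.get("path", f"manifest[{index}]"),
                             str(exc)) from exc
        for rec in punctum_records:
            row = asdict(rec)
            row.update(construct=construct, source=source)
            puncta_rows.append(row)
        for cm in cells:
            row = asdict(cm)
            row.update(construct=construct, source=source)
            cell_rows.append(row)

    puncta_df = pd.DataFrame(puncta_rows)
    cells_df = pd.DataFrame(cell_rows)
    if not cells_df.empty:
        vp_kp_df = cells_df[cells_df["puncta_count"] > 0].reset_index(drop=True)
    else:
        vp_kp_df = cells_df.copy()

    summaries = []
    if not cells_df.empty:
        for construct, grp in cells_df.groupby("construct", sort=True):
            with_puncta = grp[grp["puncta_count"] > 0]
            row = {"construct": construct, "n_cells": len(grp),
                   "n_cells_with_puncta": len(with_puncta)}
            row["puncta_density_mean"] = grp["puncta_density"].mean()
            row["puncta_density_sem"] = scipy.stats.sem(grp["puncta_density"]) \
                if len(grp) > 1 else np.nan
            for metric in PUNCTA_ONLY_METRICS:
                vals = with_puncta[metric].dropna()
                row[f"{metric}_mean"] = vals.mean() if len(vals) else np.nan
                row[f"{metric}_sem"] = scipy.stats.sem(vals) if len(vals) > 1 else np.nan
            summaries.append(row)
    summary_df = pd.DataFrame(summaries)

    provenance = pd.DataFrame([{
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": _pkg_version,
        "numpy_version": np.__version__,
        "n_inputs": len(config.manifest),
    }])

    tables = {"puncta": puncta_df, "cells": cells_df, "vp_kp": vp_kp_df,
              "summary": summary_df, "provenance": provenance}
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in tables.items():
            frame.to_csv(out / f"{name}.csv", index=False, na_rep="")
    return tables


def compare_groups(
    values_a, values_b,
    test: str = "mannwhitney",
    metric: str = "",
    group_a: str = "A",
    group_b: str = "B",
) -> GroupComparison:
    """Two-sided two-sample comparison (Mann–Whitney U or Welch t test)."""
    a = np.asarray(pd.Series(values_a).dropna(), float)
    b = np.asarray(pd.Series(values_b).dropna(), float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    degenerate = np.ptp(a) < 1e-12 and np.ptp(b) < 1e-12
    if test == "mannwhitney":
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "ttest":
        res = scipy.stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    if degenerate:
        logger.warning("both groups are constant; p-value is not meaningful")
    return GroupComparison(metric=metric, group_a=group_a, group_b=group_b,
                           test=test, statistic=float(res.statistic),
                           p_value=float(res.pvalue), n_a=a.size, n_b=b.size,
                           degenerate=degenerate)


def linear_trend(x, y, log_y: bool = False) -> TrendFit:
    """Descriptive OLS fit with a pointwise 95% confidence band.

    With ``log_y`` the response is log10-transformed first (semi-log
    presentation); the returned band is on the transformed scale.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) < 1e-12:
        raise ValueError("constant x; fit is singular")
    if log_y:
        if np.any(y <= 0):
            raise ValueError("log_y requires positive y values")
        y = np.log10(y)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    pred = model.get_prediction(sm.add_constant(x)).conf_int(alpha=0.05)
    return TrendFit(slope=float(model.params[1]), intercept=float(model.params[0]),
                    ci_lower=pred[:, 0], ci_upper=pred[:, 1], log_y=log_y)
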