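"""Configuration documents, tabular readers/writers and run logging.

Configs are JSON or YAML documents with a ``design`` block mirroring the
trial-design fields, plus optional ``data``, ``estimator`` and ``output``
blocks.  Tables are strict comma-separated text: UTF-8, ``.`` decimal,
header required, no dialect sniffing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import DesignError, StageSummary, TrialDesign, build_design, subpop_from_partitions
from .estimators import ShrinkageConfig

log = logging.getLogger("enrichest")

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "design_from_dict",
    "design_to_dict",
    "read_summary_table",
    "summaries_from_table",
    "write_report",
    "log_run",
]


class ConfigError(ValueError):
    pass


_DESIGN_KEYS = {
    "prevalences",
    "sigma",
    "futility_b",
    "n1",
    "n2",
    "n2_total",
    "thresholds",
    "allocation_ratio",
    "higher_biomarker_smaller_effect",
}
_ESTIMATOR_KEYS = {"c_variant", "target", "clip_upper", "mi_tol", "mi_max_iter", "mi_dropped"}
_TOP_KEYS = {"design", "data", "estimator", "output", "seed"}


def design_from_dict(block: dict) -> TrialDesign:
    unknown = set(block) - _DESIGN_KEYS
    if unknown:
        raise ConfigError(f"unknown design keys: {sorted(unknown)}")
    if ("n2" in block) == ("n2_total" in block):
        raise ConfigError("design requires exactly one of 'n2' or 'n2_total'")
    n2_plan = block.get("n2", block.get("n2_total"))
    try:
        return build_design(
            block["prevalences"],
            block["sigma"],
            block["futility_b"],
            block["n1"],
            n2_plan,
            thresholds=block.get("thresholds"),
            allocation_ratio=block.get("allocation_ratio", 1.0),
            higher_biomarker_smaller_effect=block.get(
                "higher_biomarker_smaller_effect", True
            ),
        )
    except KeyError as exc:
        raise ConfigError(f"design block missing required key {exc}") from exc


def design_to_dict(design: TrialDesign) -> dict:
    out = {
        "prevalences": list(design.prevalences),
        "sigma": design.sigma,
        "futility_b": design.futility_b,
        "n1": list(design.n1),
        "allocation_ratio": design.allocation_ratio,
        "higher_biomarker_smaller_effect": design.higher_biomarker_smaller_effect,
    }
    if design.stage2.kind == "fixed":
        out["n2"] = list(design.stage2.n2)
    else:
        out["n2_total"] = design.stage2.total
    if design.thresholds is not None:
        out["thresholds"] = list(design.thresholds)
    return out


@dataclass(frozen=True)
class RunConfig:
    design: TrialDesign
    data: dict
    shrinkage: ShrinkageConfig
    mi_tol: float
    mi_max_iter: int
    mi_dropped: str
    output: dict
    seed: int


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "design" not in doc:
        raise ConfigError("config requires a 'design' block")
    est = doc.get("estimator", {}) or {}
    unknown = set(est) - _ESTIMATOR_KEYS
    if unknown:
        raise ConfigError(f"unknown estimator keys: {sorted(unknown)}")
    shrink = ShrinkageConfig(
        c_variant=est.get("c_variant", "auto"),
        target=est.get("target", "unweighted"),
        clip_upper=est.get("clip_upper", True),
    )
    data = doc.get("data", {}) or {}
    for key, p in data.items():
        if not Path(p).exists():
            raise ConfigError(f"data path for {key!r} does not exist: {p}")
    return RunConfig(
        design=design_from_dict(doc["design"]),
        data=data,
        shrinkage=shrink,
        mi_tol=float(est.get("mi_tol", 0.001)),
        mi_max_iter=int(est.get("mi_max_iter", 100)),
        mi_dropped=est.get("mi_dropped", "plugin"),
        output=doc.get("output", {}) or {},
        seed=int(doc.get("seed", 0)),
    )


_SUMMARY_COLS = {"stage", "partition", "n_control", "n_treatment", "mean_diff"}
_PATIENT_COLS = {"id", "biomarker", "arm", "stage", "outcome"}


def read_summary_table(path: str | Path) -> pd.DataFrame:
    """Read a stage/partition summary table or a patient-level table.

    Patient-level input is aggregated to per-partition mean differences
    (logged); the returned frame always has the summary columns.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ConfigError(f"{path}: no data rows")
    cols = set(df.columns)
    if _SUMMARY_COLS <= cols:
        return _validate_summary(df, path)
    if _PATIENT_COLS <= cols:
        log.info("aggregating patient-level table %s", path)
        return _aggregate_patients(df, path)
    raise ConfigError(
        f"{path}: columns {sorted(cols)} match neither the summary header "
        f"{sorted(_SUMMARY_COLS)} nor the patient header {sorted(_PATIENT_COLS)}"
    )


def _validate_summary(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    for col in ("stage", "partition", "n_control", "n_treatment", "mean_diff"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if not bad.empty:
            rows = ", ".join(str(i + 2) for i in bad.index[:5])  # header = line 1
            raise ConfigError(f"{path}: non-numeric {col!r} at line(s) {rows}")
    dup = df.duplicated(subset=["stage", "partition"])
    if dup.any():
        rows = ", ".join(str(i + 2) for i in df.index[dup][:5])
        raise ConfigError(f"{path}: duplicate (stage, partition) at line(s) {rows}")
    return df.sort_values(["stage", "partition"]).reset_index(drop=True)


def _aggregate_patients(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    bad = df[pd.to_numeric(df["outcome"], errors="coerce").isna()]
    if not bad.empty:
        rows = ", ".join(str(i + 2) for i in bad.index[:5])
        raise ConfigError(f"{path}: non-numeric 'outcome' at line(s) {rows}")
    if "partition" not in df.columns:
        raise ConfigError(f"{path}: patient-level table requires a 'partition' column")
    rows = []
    for (stage, part), grp in df.groupby(["stage", "partition"]):
        means = grp.groupby("arm")["outcome"].mean()
        counts = grp.groupby("arm")["outcome"].size()
        rows.append(
            {
                "stage": stage,
                "partition": part,
                "n_control": counts.get("control", 0),
                "n_treatment": counts.get("experimental", 0),
                "mean_diff": means.get("experimental", np.nan) - means.get("control", np.nan),
            }
        )
    return pd.DataFrame(rows).sort_values(["stage", "partition"]).reset_index(drop=True)


def summaries_from_table(
    table: pd.DataFrame, design: TrialDesign
) -> tuple[StageSummary, StageSummary | None]:
    """Build stage summaries from a validated summary frame."""
    s1 = table[table["stage"] == 1]
    if len(s1) != design.K:
        raise ConfigError(
            f"stage 1 needs {design.K} partition rows, found {len(s1)}"
        )
    if list(s1["partition"]) != list(range(1, design.K + 1)):
        raise ConfigError("stage 1 partitions must be 1..K with none missing")
    stage1 = subpop_from_partitions(s1["mean_diff"].to_numpy(), design, 1)
    s2 = table[table["stage"] == 2]
    stage2 = None
    if len(s2):
        s = len(s2)
        if list(s2["partition"]) != list(range(1, s + 1)):
            raise ConfigError("stage 2 partitions must be 1..s with none missing")
        stage2 = subpop_from_partitions(s2["mean_diff"].to_numpy(), design, 2, s=s)
    return stage1, stage2


def write_report(report: dict, path: str | Path, fmt: str = "json") -> None:
    """Write a structured report as JSON or aligned text.

    JSON round-trips all numeric fields exactly (no rounding).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        path.write_text(json.dumps(report, indent=2, default=_jsonify) + "\n")
    elif fmt == "text":
        path.write_text(_render_text(report))
    else:
        raise ConfigError(f"unknown report format {fmt!r}")


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _render_text(report: dict, indent: int = 0) -> str:
    lines = []
    pad = "  " * indent
    for key, val in report.items():
        if isinstance(val, dict):
            lines.append(f"{pad}{key}:")
            lines.append(_render_text(val, indent + 1))
        elif isinstance(val, (list, tuple)):
            vals = ", ".join(_fmt(v) for v in val)
            lines.append(f"{pad}{key:<18} [{vals}]")
        else:
            lines.append(f"{pad}{key:<18} {_fmt(val)}")
    return "\n".join(lines) + ("\n" if indent == 0 else "")


def _fmt(v):
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def design_hash(design: TrialDesign) -> str:
    blob = json.dumps(design_to_dict(design), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def log_run(design: TrialDesign, seed: int | None, **params) -> None:
    """Log everything needed to reproduce a run bit-identically."""
    log.info(
        "run: version=%s design=%s seed=%s params=%s",
        __version__,
        design_hash(design),
        seed,
        params,
    )
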