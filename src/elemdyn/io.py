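"""Cohort file plumbing: per-series CSVs plus a manifest, and config parsing."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .series import BiomarkerSeries, Subject
from .synthetic import CohortSpec, GeneratorSpec

MANIFEST_COLUMNS = ["subject_id", "group", "sex", "age", "element", "path"]


def write_cohort(subjects: list[Subject], outdir) -> Path:
    """One CSV per subject-element plus ``manifest.csv``; returns the
    manifest path."""
    outdir = Path(outdir)
    series_dir = outdir / "series"
    series_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for subj in subjects:
        for el, series in subj.series.items():
            rel = Path("series") / f"{subj.subject_id}_{el}.csv"
            series.to_csv(outdir / rel)
            row = {
                "subject_id": subj.subject_id,
                "group": subj.group,
                "element": el,
                "path": str(rel),
            }
            row.update(subj.covariates)
            rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_cohort(manifest_path) -> list[Subject]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    if df.empty:
        raise ValueError(f"manifest {manifest_path} is empty")
    missing = {"subject_id", "group", "element", "path"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    covariate_cols = [c for c in df.columns if c not in ("subject_id", "group", "element", "path")]
    subjects: dict[str, Subject] = {}
    for _, row in df.iterrows():
        sid = row["subject_id"]
        if sid not in subjects:
            subjects[sid] = Subject(
                subject_id=sid,
                group=row["group"],
                covariates={c: row[c] for c in covariate_cols},
            )
        series_path = manifest_path.parent / row["path"]
        if not series_path.exists():
            raise FileNotFoundError(f"series file {series_path} referenced by manifest is missing")
        subjects[sid].series[row["element"]] = BiomarkerSeries.from_csv(
            series_path, subject_id=sid, element=row["element"]
        )
    return list(subjects.values())


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    elif path.suffix == ".json":
        cfg = json.loads(text)
    else:
        raise ValueError(f"unsupported config format {path.suffix!r} (use YAML or JSON)")
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    return cfg


def cohort_spec_from_config(cfg: dict) -> CohortSpec:
    """Build a CohortSpec from a config mapping; unknown keys are rejected."""
    known = {
        "n_cases", "n_controls", "elements", "assignments", "sex_p",
        "age_mean", "age_sd", "smoking_p", "length_range",
        "sampling_interval", "seed",
    }
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
    cfg = dict(cfg)
    if "assignments" in cfg:
        cfg["assignments"] = {
            el: {
                grp: GeneratorSpec(g["name"], g.get("params", {}))
                for grp, g in groups.items()
            }
            for el, groups in cfg["assignments"].items()
        }
    if "length_range" in cfg:
        cfg["length_range"] = tuple(cfg["length_range"])
    return CohortSpec(**cfg)
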