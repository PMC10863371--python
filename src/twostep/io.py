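"""TSV / JSON serialization for every pipeline artifact.

All tables are tab-separated with a fixed column order and ``NA`` as the
missing-value sentinel; manifests are JSON.  Round-trips are lossless,
including missing trials.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .cohort import CohortData, CohortSpec, Prior
from .task import TRIAL_COLUMNS, TaskConfig

NA = "NA"


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA)


def write_trials(trials: pd.DataFrame, path) -> None:
    _write_tsv(trials[TRIAL_COLUMNS], path)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        na_values=[NA],
        keep_default_na=False,
        dtype={
            "subject_id": "string",
            "intervention": "string",
            "transition": "string",
        },
    )
    missing_cols = set(TRIAL_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"trial table missing columns: {sorted(missing_cols)}")
    for col in ("choice1", "state2", "choice2"):
        df[col] = df[col].astype("Int64")
    df["reward"] = df["reward"].astype(int)
    df["missing"] = df["missing"].astype(bool)
    return df[TRIAL_COLUMNS]


def write_table(df: pd.DataFrame, path) -> None:
    _write_tsv(df, path)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)


def _spec_to_jsonable(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["interventions"] = list(spec.interventions)
    d["missing_rate_beta"] = list(spec.missing_rate_beta)
    d["param_prior"] = {
        name: {"dist": p.dist, "args": list(p.args)} for name, p in spec.param_prior.items()
    }
    return d


def _spec_from_jsonable(d: dict) -> CohortSpec:
    known = {f.name for f in dataclasses.fields(CohortSpec)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown CohortSpec keys: {sorted(unknown)}")
    d = dict(d)
    if "interventions" in d:
        d["interventions"] = tuple(d["interventions"])
    if "missing_rate_beta" in d:
        d["missing_rate_beta"] = tuple(d["missing_rate_beta"])
    if "param_prior" in d:
        d["param_prior"] = {
            name: Prior(p["dist"], tuple(p["args"])) for name, p in d["param_prior"].items()
        }
    return CohortSpec(**d)


def write_manifest(cohort: CohortData, path) -> None:
    manifest = {
        "task": cohort.task_config.to_dict(),
        "cohort": _spec_to_jsonable(cohort.spec),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")


def read_manifest(path) -> tuple[TaskConfig, CohortSpec]:
    manifest = json.loads(Path(path).read_text())
    return TaskConfig.from_dict(manifest["task"]), _spec_from_jsonable(manifest["cohort"])


def write_cohort(cohort: CohortData, out_dir) -> dict:
    """Write trials.tsv, true_params.tsv, blood.tsv, manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": out / "trials.tsv",
        "true_params": out / "true_params.tsv",
        "blood": out / "blood.tsv",
        "manifest": out / "manifest.json",
    }
    write_trials(cohort.trials, paths["trials"])
    _write_tsv(cohort.true_params, paths["true_params"])
    _write_tsv(cohort.blood, paths["blood"])
    write_manifest(cohort, paths["manifest"])
    return {k: str(v) for k, v in paths.items()}
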