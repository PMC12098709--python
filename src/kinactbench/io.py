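"""Readers and writers for the TSV dialects used across the package.

All tables are UTF-8 TSV with a header row; the first column holds row
identifiers. Empty cells and the token ``NA`` denote missing values.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import pandas as pd

from .activity import ActivityMatrix, PhosphoMatrix
from .library import KSLibrary, standardize_library
from .perturb import MetricResult, PerturbationAnnotation
from .sites import SiteID, parse_site_id

PathLike = Union[str, Path]

_SIGN_TOKENS = {
    "+1": 1,
    "1": 1,
    "activation": 1,
    "overexpression": 1,
    "-1": -1,
    "inhibition": -1,
    "knockout": -1,
}


def _read_tsv_matrix(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""], keep_default_na=True)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row ids: {dups}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad][0]
                raise ValueError(
                    f"{path}: non-numeric value at row {row!r}, column {col!r}"
                ) from None
        raise
    df.index = df.index.astype(str)
    return df


def read_matrix(path: PathLike, kind: str = "sites"):
    """Read a matrix TSV.

    ``kind='sites'`` returns a :class:`PhosphoMatrix` (row ids parsed
    as site identifiers); ``'proteins'`` and ``'activities'`` return a
    plain DataFrame with gene / kinase symbols uppercased.
    """
    df = _read_tsv_matrix(path)
    if kind == "sites":
        return PhosphoMatrix(data=df)
    if kind in ("proteins", "activities"):
        df.index = df.index.str.upper()
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"{path}: duplicate row ids after canonicalization: {dups}")
        return df
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(df_or_mat, path: PathLike) -> None:
    df = df_or_mat.data if isinstance(df_or_mat, PhosphoMatrix) else df_or_mat
    df.to_csv(path, sep="\t", na_rep="NA")


def read_library(path: PathLike, **kwargs) -> KSLibrary:
    """Read a standardized library TSV (kinase, gene, residue, position, flank, source)."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lib, _dropped = standardize_library(raw, **kwargs)
    return lib


def write_library(lib: KSLibrary, path: PathLike) -> None:
    lib.to_frame().to_csv(path, sep="\t", index=False)


def read_annotations(path: PathLike) -> PerturbationAnnotation:
    """Read a perturbation annotation TSV (experiment, kinase, sign).

    Sign tokens ``+1``/``activation``/``overexpression`` map to +1 and
    ``-1``/``inhibition``/``knockout`` to -1; anything else errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    req = {"experiment", "kinase", "sign"}
    if not req.issubset(df.columns):
        raise ValueError(f"{path}: annotation TSV needs columns {sorted(req)}")
    signs = []
    for tok in df["sign"]:
        key = str(tok).strip().lower()
        if key not in _SIGN_TOKENS:
            raise ValueError(f"{path}: unknown sign token {tok!r}")
        signs.append(_SIGN_TOKENS[key])
    out = pd.DataFrame(
        {
            "experiment": df["experiment"].astype(str),
            "kinase": df["kinase"].str.upper(),
            "sign": signs,
        }
    )
    return PerturbationAnnotation(records=out)


def write_annotations(ann: PerturbationAnnotation, path: PathLike) -> None:
    ann.records.to_csv(path, sep="\t", index=False)


def write_activity(acts: ActivityMatrix, path: PathLike) -> None:
    """Write an activity matrix with a sidecar of per-cell target counts."""
    path = Path(path)
    acts.scores.to_csv(path, sep="\t", na_rep="NA")
    acts.n_targets.to_csv(path.with_suffix(".ntargets.tsv"), sep="\t")


def write_benchmark_report(
    results: List[MetricResult], out_prefix: PathLike, method: str = "", library: str = ""
) -> Dict[str, float]:
    """Write a long-format TSV of repeat values plus a JSON summary.

    The TSV has one row per (metric, repeat) — metrics without a repeat
    distribution contribute a single row — and the JSON records each
    metric's point estimate and the number of kinases evaluated.
    Returns the summary dict.
    """
    if not results:
        raise ValueError("no metric results to report")
    out_prefix = Path(out_prefix)
    rows = []
    summary: Dict[str, dict] = {}
    for res in results:
        if res.distribution is not None:
            for i, v in enumerate(res.distribution):
                rows.append(
                    {
                        "method": method,
                        "library": library,
                        "metric": res.metric,
                        "repeat": i,
                        "value": float(v),
                    }
                )
        else:
            rows.append(
                {
                    "method": method,
                    "library": library,
                    "metric": res.metric,
                    "repeat": 0,
                    "value": res.value,
                }
            )
        summary[res.metric] = {"value": res.value, "n_kinases": res.n_kinases}
    pd.DataFrame(rows, columns=["method", "library", "metric", "repeat", "value"]).to_csv(
        f"{out_prefix}.tsv", sep="\t", index=False
    )
    with open(f"{out_prefix}.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
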