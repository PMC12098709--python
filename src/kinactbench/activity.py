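"""Kinase activity inference over a phosphosite matrix.

Combines a measured site matrix (log fold-changes per perturbation
experiment, or centered log2 intensities per tumor sample) with a
kinase-substrate library and one of the cataloged scoring methods to
produce a kinases x columns activity matrix. A kinase receives a score
in a column only when at least ``min_targets`` of its library targets
carry a finite measurement there (default 5); otherwise the cell is NA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Set

import numpy as np
import pandas as pd

from . import methods as M
from .library import KSLibrary, filter_min_targets, map_sites
from .sites import SiteID, parse_site_id

#: every method name accepted by :func:`infer_activity`
METHOD_CATALOG = (
    "mean",
    "median",
    "sum",
    "uq",
    "ksea",
    "zscore",
    "karp",
    "ks",
    "mwu",
    "fisher",
    "chisq",
    "ulm",
    "mlm",
    "lm_rokai",
    "fgsea",
    "norm_mean",
    "ptmsea",
    "viper",
    "pca",
    "number_of_targets",
)

#: methods whose score depends on pseudo-random permutations
PERMUTATION_METHODS = frozenset({"norm_mean", "ptmsea", "viper"})


@dataclass
class PhosphoMatrix:
    """Sites x columns numeric matrix with missing values allowed.

    ``data`` rows are indexed by site-id strings (``GENE|S9`` or
    ``GENE|S9|FLANK``); ``site_ids`` maps each row id to its parsed
    :class:`SiteID`. ``value_kind`` records whether values are log
    fold-changes or centered log intensities.
    """

    data: pd.DataFrame
    site_ids: Dict[str, SiteID] = field(default_factory=dict)
    value_kind: str = "logFC"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate site row ids: {dups}")
        if not self.site_ids:
            self.site_ids = {rid: parse_site_id(rid) for rid in self.data.index}

    @property
    def columns(self) -> List[str]:
        return list(self.data.columns)

    def drop_empty_rows(self) -> "PhosphoMatrix":
        keep = self.data.index[self.data.notna().any(axis=1)]
        return PhosphoMatrix(
            data=self.data.loc[keep],
            site_ids={r: self.site_ids[r] for r in keep},
            value_kind=self.value_kind,
        )


@dataclass
class ActivityMatrix:
    """Kinases x columns activity scores with per-cell measured-target counts."""

    scores: pd.DataFrame
    n_targets: pd.DataFrame
    method: str = ""

    def __post_init__(self) -> None:
        assert self.scores.shape == self.n_targets.shape


@dataclass
class MethodConfig:
    """Tunable parameters shared across the method catalog.

    min_targets
        Minimum measured library targets for a kinase to be scored in a
        column (default 5).
    ora_cutoff
        Deregulation cutoff tau on |value| for the over-representation
        tests (default 1, the conventional log fold-change cutoff).
    n_perm
        Permutations for the permutation-normalized methods (>= 100).
    ridge_lambda
        Ridge penalty of the RoKAI-style linear model.
    uq_prob
        Quantile for the upper-quantile statistic.
    karp_scale
        Multiplicative constant of the KARP K-score; ranks unaffected.
    """

    method: str = "zscore"
    min_targets: int = 5
    ora_cutoff: float = 1.0
    n_perm: int = 1000
    ridge_lambda: float = 0.1
    seed: int = 0
    uq_prob: float = 0.75
    karp_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in METHOD_CATALOG:
            raise ValueError(
                f"unknown method {self.method!r}; choose from {sorted(METHOD_CATALOG)}"
            )
        if self.method in PERMUTATION_METHODS and self.n_perm < 100:
            raise ValueError("permutation methods require n_perm >= 100")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")

    def with_method(self, method: str) -> "MethodConfig":
        return replace(self, method=method)


def infer_activity(mat: PhosphoMatrix, lib: KSLibrary, cfg: MethodConfig) -> ActivityMatrix:
    """Score every kinase in every column of the matrix.

    Per column, rows with missing values are dropped before scoring;
    the measured-target count m therefore varies by column, and cells
    with m < ``cfg.min_targets`` are NA. Permutation-based methods are
    deterministic given ``cfg.seed``.
    """
    mapping, _ = map_sites(mat.site_ids, lib)
    target_rows: Dict[str, Set[str]] = {}
    for kinase, keys in lib.target_keys().items():
        rows = {mapping[k] for k in keys if k in mapping}
        if rows:
            target_rows[kinase] = rows
    total_targets = {k: len(v) for k, v in lib.target_keys().items()}

    kinases = sorted(target_rows)
    columns = mat.columns
    scores = pd.DataFrame(np.nan, index=kinases, columns=columns, dtype=float)
    n_targets = pd.DataFrame(0, index=kinases, columns=columns, dtype=int)

    if not kinases:
        warnings.warn("no library site maps onto the matrix; returning all-NA activities")
        return ActivityMatrix(scores=scores, n_targets=n_targets, method=cfg.method)

    if cfg.method == "pca":
        _score_pca_method(mat, target_rows, cfg, scores, n_targets)
        return ActivityMatrix(scores=scores, n_targets=n_targets, method=cfg.method)

    rng_root = np.random.default_rng(cfg.seed)
    col_seeds = rng_root.integers(0, 2**31 - 1, size=len(columns))

    for ci, col in enumerate(columns):
        series = mat.data[col].dropna()
        measured = set(series.index)
        per_kinase = filter_min_targets(
            lib, measured, cfg.min_targets, site_mapping=mapping
        )
        for kinase in kinases:
            rows = target_rows[kinase] & measured
            n_targets.loc[kinase, col] = len(rows)
        if not per_kinase:
            continue
        if cfg.method in ("mlm", "lm_rokai"):
            _score_joint_column(series, per_kinase, cfg, scores, col)
            continue
        values_all = series.to_numpy(dtype=float)
        col_rng = np.random.default_rng(col_seeds[ci])
        for kinase, rows in sorted(per_kinase.items()):
            vt = series.loc[sorted(rows)].to_numpy(dtype=float)
            vn = series.drop(index=sorted(rows)).to_numpy(dtype=float)
            scores.loc[kinase, col] = _score_one(
                cfg, kinase, vt, vn, values_all, series, rows, total_targets, col_rng
            )
    return ActivityMatrix(scores=scores, n_targets=n_targets, method=cfg.method)


def _score_one(
    cfg: MethodConfig,
    kinase: str,
    vt: np.ndarray,
    vn: np.ndarray,
    values_all: np.ndarray,
    series: pd.Series,
    rows: Set[str],
    total_targets: Mapping[str, int],
    rng: np.random.Generator,
) -> float:
    method = cfg.method
    if method in ("mean", "median", "sum"):
        return M.score_location(vt, method)
    if method == "uq":
        return float(np.quantile(vt, cfg.uq_prob, method="linear"))
    if method == "ksea":
        return M.score_ksea(vt, values_all)
    if method == "zscore":
        return M.score_zscore_rokai(vt, values_all)
    if method == "karp":
        return M.score_karp(
            vt, values_all, t_known=max(total_targets.get(kinase, len(rows)), len(rows)),
            scale=cfg.karp_scale,
        )
    if method in ("ks", "mwu"):
        return M.score_rank_test(vt, vn, test=method)
    if method in ("fisher", "chisq"):
        return M.score_overrep(vt, vn, test=method, tau=cfg.ora_cutoff)
    if method == "ulm":
        membership = series.index.isin(rows).astype(float)
        return M.score_ulm(values_all, membership)
    if method == "fgsea":
        return M.score_fgsea_es(values_all, series.index.isin(rows))
    if method == "norm_mean":
        return M.score_norm_mean(vt, values_all, n_perm=cfg.n_perm, rng=rng)
    if method == "ptmsea":
        return M.score_ptmsea(values_all, series.index.isin(rows), n_perm=cfg.n_perm, rng=rng)
    if method == "viper":
        return M.score_viper(values_all, series.index.isin(rows), n_perm=cfg.n_perm, rng=rng)
    if method == "number_of_targets":
        return float(len(rows))
    raise ValueError(f"unknown method {method!r}")  # pragma: no cover


def _score_joint_column(
    series: pd.Series,
    per_kinase: Mapping[str, Set[str]],
    cfg: MethodConfig,
    scores: pd.DataFrame,
    col: str,
) -> None:
    kin_list = sorted(per_kinase)
    design = np.zeros((series.size, len(kin_list)))
    row_pos = {rid: i for i, rid in enumerate(series.index)}
    for j, kinase in enumerate(kin_list):
        for rid in per_kinase[kinase]:
            design[row_pos[rid], j] = 1.0
    y = series.to_numpy(dtype=float)
    if cfg.method == "mlm":
        t_vals, _ = M.score_mlm(y, design, kin_list)
        for j, kinase in enumerate(kin_list):
            scores.loc[kinase, col] = t_vals[j]
    else:  # lm_rokai
        acts = M.score_lm_rokai(y, design, lam=cfg.ridge_lambda)
        for j, kinase in enumerate(kin_list):
            scores.loc[kinase, col] = acts[j]


def _score_pca_method(
    mat: PhosphoMatrix,
    target_rows: Mapping[str, Set[str]],
    cfg: MethodConfig,
    scores: pd.DataFrame,
    n_targets: pd.DataFrame,
) -> None:
    """PCA runs across all columns at once per kinase.

    Only target rows measured in every column enter the block (the
    decomposition needs a complete matrix), so the per-cell m is the
    number of complete target rows.
    """
    for kinase, rows in sorted(target_rows.items()):
        block = mat.data.loc[sorted(rows)].dropna(axis=0, how="any")
        m = block.shape[0]
        n_targets.loc[kinase, :] = m
        if m < cfg.min_targets or block.shape[1] < 2:
            continue
        pcs, _var = M.score_pca(block.to_numpy(dtype=float))
        scores.loc[kinase, :] = pcs


def count_targets(lib: KSLibrary, measured_sites: Mapping[str, SiteID] | Set[str]) -> Dict[str, int]:
    """Per-kinase number of measured library targets (the control 'method')."""
    if isinstance(measured_sites, Mapping):
        mapping, _ = map_sites(measured_sites, lib)
        mapped_keys = set(mapping)
    else:
        mapped_keys = set(measured_sites)
    return {
        kinase: len(keys & mapped_keys) for kinase, keys in lib.target_keys().items()
    }
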