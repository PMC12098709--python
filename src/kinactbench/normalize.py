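"""Normalization of phosphosite levels to host-protein levels.

A phosphosite's measured intensity mixes two signals: how abundant the
host protein is and how heavily it is phosphorylated. Four strategies
remove the protein-abundance component before activity inference:

* ``subtract`` — site minus protein, elementwise per sample (both on
  the log2 scale, so this is a ratio in linear space);
* ``lm_global`` — residuals of one pooled regression of all site
  values on their host-protein values;
* ``lm_protein`` — residuals of one regression per host protein,
  pooling that protein's sites;
* ``lm_site`` — residuals of one regression per individual site row.

All regressions include an intercept and are fitted on paired finite
(site, protein) observations; cells whose host protein is missing stay
missing in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .activity import PhosphoMatrix

STRATEGIES = ("none", "subtract", "lm_global", "lm_protein", "lm_site")


@dataclass
class NormalizationSpec:
    strategy: str = "subtract"
    min_meas: int = 30

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown normalization strategy {self.strategy!r}; choose from {STRATEGIES}"
            )


def _ols_residuals(x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, bool]:
    """Residuals of y ~ intercept + x. Returns (residuals, fitted_ok)."""
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        return y - y.mean(), False
    beta = float(xc @ (y - y.mean())) / sxx
    alpha = y.mean() - beta * x.mean()
    return y - (alpha + beta * x), True


def normalize_sites(
    sites: PhosphoMatrix,
    proteins: pd.DataFrame,
    spec: NormalizationSpec,
) -> Tuple[PhosphoMatrix, Dict[str, int]]:
    """Adjust site levels for host-protein abundance.

    Sites are paired with the protein row matching their gene symbol;
    sites without a measured host protein, and rows with fewer than
    ``spec.min_meas`` finite paired observations, are removed. Returns
    the normalized matrix and a small accounting dict (rows dropped for
    missing protein / low coverage, per-site fallbacks).

    For ``lm_site``, a site whose host protein has zero variance over
    the paired samples cannot be regressed; it falls back to the
    subtract strategy and is counted in ``n_fallback_subtract``.
    """
    data = sites.data
    info = {"n_no_host": 0, "n_low_coverage": 0, "n_fallback_subtract": 0}

    paired_rows = []
    for rid in data.index:
        gene = sites.site_ids[rid].gene
        if gene not in proteins.index:
            info["n_no_host"] += 1
            continue
        paired_rows.append((rid, gene))

    if spec.strategy == "none":
        keep = [rid for rid, _ in paired_rows]
        out = data.loc[keep].copy()
        return _repack(sites, out), info

    # aligned site/protein frames on paired finite entries
    site_rows, prot_rows, kept = [], [], []
    for rid, gene in paired_rows:
        s = data.loc[rid]
        p = proteins.loc[gene]
        paired = s.notna() & p.notna()
        if int(paired.sum()) < spec.min_meas:
            info["n_low_coverage"] += 1
            continue
        kept.append((rid, gene))
        site_rows.append(s.where(paired))
        prot_rows.append(p.where(paired))
    if not kept:
        raise ValueError("no site row has enough paired measurements")

    S = pd.DataFrame(site_rows, index=[rid for rid, _ in kept])
    P = pd.DataFrame(prot_rows, index=[rid for rid, _ in kept])

    if spec.strategy == "subtract":
        out = S - P
    elif spec.strategy == "lm_global":
        out = _residualize(S, P, groups={None: list(S.index)})
    elif spec.strategy == "lm_protein":
        groups: Dict[Optional[str], list] = {}
        for rid, gene in kept:
            groups.setdefault(gene, []).append(rid)
        out = _residualize(S, P, groups=groups)
    elif spec.strategy == "lm_site":
        out = S.copy()
        for rid in S.index:
            s = S.loc[rid]
            p = P.loc[rid]
            mask = s.notna()
            resid, ok = _ols_residuals(
                p[mask].to_numpy(dtype=float), s[mask].to_numpy(dtype=float)
            )
            if not ok:
                warnings.warn(
                    f"site {rid!r}: zero host-protein variance; falling back to subtract"
                )
                info["n_fallback_subtract"] += 1
                out.loc[rid, mask] = (s[mask] - p[mask]).to_numpy()
            else:
                out.loc[rid, mask] = resid
    else:  # pragma: no cover
        raise AssertionError(spec.strategy)

    return _repack(sites, out), info


def _residualize(S: pd.DataFrame, P: pd.DataFrame, groups: Dict) -> pd.DataFrame:
    """Pooled OLS residuals per group of site rows (None = all rows)."""
    out = S.copy()
    for _, rids in groups.items():
        sub_s = S.loc[rids]
        sub_p = P.loc[rids]
        mask = sub_s.notna().to_numpy()
        x = sub_p.to_numpy(dtype=float)[mask]
        y = sub_s.to_numpy(dtype=float)[mask]
        resid, ok = _ols_residuals(x, y)
        if not ok:
            resid = y - x  # degenerate pool: subtract
        block = sub_s.to_numpy(dtype=float)
        block[mask] = resid
        out.loc[rids] = block
    return out


def _repack(sites: PhosphoMatrix, data: pd.DataFrame) -> PhosphoMatrix:
    return PhosphoMatrix(
        data=data,
        site_ids={rid: sites.site_ids[rid] for rid in data.index},
        value_kind=sites.value_kind,
    )
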