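"""Tumor-cohort benchmark built from extreme kinase protein levels.

The premise: in a tumor cohort, samples with the highest protein level
of a kinase (or of its activating phosphosites) should also show the
highest activity of that kinase. Kinase-sample pairs in the extreme
upper/lower tail of the cohort's protein distribution form the gold
standard positive (GS+) and negative (GS-) sets; a method is then
scored by how well its cohort-z-scored activities separate GS+ from
GS- pairs, pooled across kinases and cohorts, with 1000x 80%
subsampling of each class to quantify variability.

Leakage control: before inferring activities the kinase-substrate
library must be censored of self-sites (phosphosites on the kinase
itself), since those sites track the quantity the gold standard was
built from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .activity import ActivityMatrix, MethodConfig, PhosphoMatrix, infer_activity
from .library import KSLibrary, has_self_sites
from .perturb import MetricResult, rank_auroc
from .sites import SiteID

__all__ = [
    "CohortDataset",
    "GoldStandard",
    "TAIL_PRESETS",
    "tail_z_cutoff",
    "build_gold_standard",
    "cohort_activity_zscores",
    "evaluate_gs_auroc",
]

#: named tail presets: percent of the normal tail -> one-sided z cutoff,
#: as conventionally printed (top 5% -> 1.645, 2.5% -> 1.96, 10% -> 1.282,
#: 15% -> 1.036)
TAIL_PRESETS = {5.0: 1.645, 2.5: 1.96, 10.0: 1.282, 15.0: 1.036}


def tail_z_cutoff(tail_percent: float, decimals: int = 3) -> float:
    """One-sided standard-normal quantile for a given upper-tail mass (%)."""
    if not 0 < tail_percent < 50:
        raise ValueError("tail_percent must be in (0, 50)")
    return float(round(stats.norm.ppf(1 - tail_percent / 100.0), decimals))


@dataclass
class CohortDataset:
    """Matched protein and phosphosite matrices for one tumor cohort.

    ``proteins``: proteins x samples log2 abundances (row ids are gene
    symbols, kinase rows included). ``sites``: phosphosite matrix on
    the same samples. ``activating_sites`` optionally maps kinase
    symbols to phosphosites whose phosphorylation activates them.
    """

    cohort: str
    proteins: pd.DataFrame
    sites: PhosphoMatrix
    activating_sites: Dict[str, List[SiteID]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.proteins.columns) != list(self.sites.data.columns):
            raise ValueError(
                f"cohort {self.cohort!r}: protein and site matrices must share sample ids"
            )


@dataclass
class GoldStandard:
    """Labeled (kinase, sample, cohort) pairs with the tail spec used."""

    pairs: pd.DataFrame  # columns: kinase, sample, cohort, label (+1/-1)
    z_cutoff: float
    basis: str = "protein"

    def __post_init__(self) -> None:
        dup = self.pairs.duplicated(subset=["kinase", "sample", "cohort"], keep=False)
        if dup.any():
            conflicting = self.pairs.loc[dup]
            if conflicting.groupby(["kinase", "sample", "cohort"])["label"].nunique().gt(1).any():
                raise ValueError("a (kinase, sample, cohort) pair carries both labels")

    @property
    def n_positive(self) -> int:
        return int((self.pairs["label"] == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.pairs["label"] == -1).sum())


def _extreme_pairs(
    vector: pd.Series, z_star: float
) -> Optional[pd.DataFrame]:
    """Label samples in the upper (+) / lower (-) z tail of one kinase vector."""
    finite = vector.dropna()
    z = (finite - finite.mean()) / finite.std(ddof=1)
    pos = z.index[z > z_star]
    neg = z.index[z < -z_star]
    rows = [{"sample": s, "label": 1} for s in pos] + [
        {"sample": s, "label": -1} for s in neg
    ]
    return pd.DataFrame(rows) if rows else None


def build_gold_standard(
    cohorts: Sequence[CohortDataset],
    basis: str = "protein",
    z_star: float = 1.645,
    min_meas: int = 30,
    min_var: float = 0.1,
    kinases: Optional[Sequence[str]] = None,
) -> GoldStandard:
    """Construct GS+/GS- kinase-sample pairs from cohort extremes.

    Per cohort and kinase, the basis vector (the kinase's protein row,
    or its best-covered activating site) is dropped when it has fewer
    than ``min_meas`` finite values or variance below ``min_var``;
    surviving vectors are z-scored across samples and samples beyond
    ``+/-z_star`` labeled. Samples with a missing value for a kinase
    never enter that kinase's pairs.
    """
    if z_star <= 0:
        raise ValueError("z_star must be positive")
    frames = []
    for cohort in cohorts:
        if basis == "protein":
            vectors = {
                k: cohort.proteins.loc[k]
                for k in (kinases or cohort.proteins.index)
                if k in cohort.proteins.index
            }
        elif basis == "activating_site":
            if not cohort.activating_sites:
                raise ValueError(
                    f"cohort {cohort.cohort!r} has no activating-site annotation"
                )
            vectors = {}
            for k, site_list in cohort.activating_sites.items():
                if kinases is not None and k not in kinases:
                    continue
                # several annotated sites: keep the best-covered one
                best, best_n = None, -1
                for site in site_list:
                    rid = _find_site_row(cohort.sites, site)
                    if rid is None:
                        continue
                    n = int(cohort.sites.data.loc[rid].notna().sum())
                    if n > best_n:
                        best, best_n = rid, n
                if best is not None:
                    vectors[k] = cohort.sites.data.loc[best]
        else:
            raise ValueError(f"unknown gold-standard basis {basis!r}")

        for kinase, vec in vectors.items():
            finite = vec.dropna()
            if finite.size < min_meas:
                continue
            if float(finite.var(ddof=1)) < min_var:
                continue
            labeled = _extreme_pairs(vec, z_star)
            if labeled is None:
                continue
            labeled["kinase"] = kinase
            labeled["cohort"] = cohort.cohort
            frames.append(labeled)
    if not frames:
        pairs = pd.DataFrame(columns=["kinase", "sample", "cohort", "label"])
    else:
        pairs = pd.concat(frames, ignore_index=True)[
            ["kinase", "sample", "cohort", "label"]
        ]
    return GoldStandard(pairs=pairs, z_cutoff=z_star, basis=basis)


def _find_site_row(mat: PhosphoMatrix, site: SiteID) -> Optional[str]:
    want_flank = site.flank_key
    want_pos = site.position_key
    for rid, sid in mat.site_ids.items():
        if want_flank is not None and sid.flank_key == want_flank:
            return rid
        if sid.position_key == want_pos:
            return rid
    return None


def cohort_activity_zscores(
    cohort: CohortDataset,
    lib: KSLibrary,
    cfg: MethodConfig,
    min_scores: int = 30,
) -> pd.DataFrame:
    """Median-center sites, infer per-sample activities, z-score per kinase.

    Each site row is centered on its cohort median, activities are
    inferred per sample (NA below the min-target rule), kinases with
    fewer than ``min_scores`` finite scores in the cohort are dropped,
    and each surviving kinase row is converted to z-scores across
    samples. The library must already be self-site-censored.
    """
    if has_self_sites(lib):
        raise ValueError(
            "library contains self-sites; censor_self_sites() must be applied "
            "before tumor benchmarking to avoid leakage"
        )
    centered = cohort.sites.data.sub(cohort.sites.data.median(axis=1), axis=0)
    mat = PhosphoMatrix(
        data=centered, site_ids=dict(cohort.sites.site_ids), value_kind="centered_log_intensity"
    )
    acts = infer_activity(mat, lib, cfg)
    scores = acts.scores
    keep = scores.notna().sum(axis=1) >= min_scores
    scores = scores.loc[keep]
    z = scores.sub(scores.mean(axis=1), axis=0).div(scores.std(axis=1, ddof=1), axis=0)
    return z


def evaluate_gs_auroc(
    zacts: Dict[str, pd.DataFrame],
    gs: GoldStandard,
    n_rep: int = 1000,
    frac: float = 0.8,
    seed: int = 0,
) -> MetricResult:
    """Subsampled ROC of z-scored activities against the gold standard.

    GS pair z-scores are pooled across kinases and cohorts; per repeat
    ``floor(frac * n)`` pairs are drawn without replacement from each
    label class and a midrank AUROC computed. Returns the repeat
    distribution and its median.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    pos_scores: List[float] = []
    neg_scores: List[float] = []
    for _, row in gs.pairs.iterrows():
        z = zacts.get(row["cohort"])
        if z is None or row["kinase"] not in z.index or row["sample"] not in z.columns:
            continue
        val = z.loc[row["kinase"], row["sample"]]
        if not np.isfinite(val):
            continue
        (pos_scores if row["label"] == 1 else neg_scores).append(float(val))
    pos = np.asarray(pos_scores)
    neg = np.asarray(neg_scores)
    if pos.size < 1 or neg.size < 1:
        raise ValueError("gold standard needs finite scores in both classes")
    n_pos = max(1, int(np.floor(frac * pos.size)))
    n_neg = max(1, int(np.floor(frac * neg.size)))
    rng = np.random.default_rng(seed)
    dist = np.empty(n_rep)
    for i in range(n_rep):
        sp = rng.choice(pos, size=n_pos, replace=False)
        sn = rng.choice(neg, size=n_neg, replace=False)
        dist[i] = rank_auroc(sp, sn)
    return MetricResult(
        metric="gs_auroc",
        value=float(np.median(dist)),
        distribution=dist,
        n_kinases=int(gs.pairs["kinase"].nunique()),
        details={"n_pos": int(pos.size), "n_neg": int(neg.size)},
    )
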