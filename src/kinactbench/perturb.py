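"""Perturbation-based benchmark of kinase activity scores.

Experiments in which a known kinase was inhibited/knocked out or
activated/overexpressed provide ground truth: a good inference method
should rank the perturbed kinase at the top once scores are multiplied
by the perturbation sign. Three complementary metrics are computed on
the sign-corrected, per-experiment SD-scaled score matrix:

* down-sampled AUROC — all (experiment, kinase) cells are flattened;
  perturbed kinases are true positives, every other scored kinase a
  true negative; per repeat an equal-size random subset of negatives
  is drawn to neutralize class imbalance and a midrank AUROC computed;
* scaled rank — the perturbed kinase's rank divided by the number of
  scored kinases (lower is better), averaged first within and then
  across kinases;
* P_Hit(k) — the frequency at which the perturbed kinase lands in the
  top k, averaged the same two-level way.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .activity import ActivityMatrix

__all__ = [
    "PerturbationAnnotation",
    "MetricResult",
    "prepare_signed_scaled_scores",
    "rank_auroc",
    "auroc_downsampled",
    "scaled_rank",
    "p_hit",
    "concordance_stats",
]


@dataclass
class PerturbationAnnotation:
    """Which kinase(s) each experiment perturbed and in which direction.

    ``records`` holds (experiment, kinase, sign) rows; sign is +1 for
    activation/overexpression and -1 for inhibition/knockout. Several
    kinases may be annotated for one experiment (e.g. multi-target
    inhibitors) but the sign must be consistent within an experiment.
    """

    records: pd.DataFrame  # columns: experiment, kinase, sign

    def __post_init__(self) -> None:
        req = {"experiment", "kinase", "sign"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"annotation needs columns {sorted(req)}")
        bad = set(self.records["sign"]) - {1, -1}
        if bad:
            raise ValueError(f"signs must be +1/-1, got {bad}")
        signs = self.records.groupby("experiment")["sign"].nunique()
        mixed = signs[signs > 1].index.tolist()
        if mixed:
            raise ValueError(f"experiments with inconsistent signs: {mixed}")

    @property
    def experiments(self) -> List[str]:
        return self.records["experiment"].unique().tolist()

    def sign_of(self, experiment: str) -> int:
        return int(self.records.loc[self.records["experiment"] == experiment, "sign"].iloc[0])

    def targets_of(self, experiment: str) -> List[str]:
        sel = self.records["experiment"] == experiment
        return self.records.loc[sel, "kinase"].tolist()


@dataclass
class MetricResult:
    """A benchmark metric with its repeat distribution where applicable."""

    metric: str
    value: float
    distribution: Optional[np.ndarray] = None
    n_kinases: int = 0
    k: Optional[int] = None
    per_kinase: Optional[pd.Series] = None
    details: dict = field(default_factory=dict)


def prepare_signed_scaled_scores(
    acts: ActivityMatrix | pd.DataFrame, ann: PerturbationAnnotation
) -> pd.DataFrame:
    """Sign-correct and SD-scale activity scores per experiment.

    Each annotated experiment's column is multiplied by the
    perturbation sign (so expected changes rank highest regardless of
    direction) and divided by the sample SD of its finite scores.
    Experiments whose annotated kinases all lack a score (the
    min-targets rule) and zero-spread experiments are excluded with a
    warning; annotated kinases without a score are dropped from the
    truth set for the remaining experiments.
    """
    scores = acts.scores if isinstance(acts, ActivityMatrix) else acts
    missing = [e for e in ann.experiments if e not in scores.columns]
    if missing:
        raise ValueError(f"annotated experiments absent from activity matrix: {missing}")

    prepared = {}
    for exp in ann.experiments:
        col = scores[exp] * ann.sign_of(exp)
        finite = col.dropna()
        if finite.size < 2:
            warnings.warn(f"experiment {exp!r}: fewer than 2 finite scores; excluded")
            continue
        if not any(np.isfinite(col.get(k, np.nan)) for k in ann.targets_of(exp)):
            warnings.warn(
                f"experiment {exp!r}: no annotated kinase has a score; excluded"
            )
            continue
        sd = float(finite.std(ddof=1))
        if sd == 0:
            warnings.warn(f"experiment {exp!r}: zero score spread; excluded")
            continue
        prepared[exp] = col / sd
    if not prepared:
        raise ValueError("no experiment survived preparation")
    return pd.DataFrame(prepared)


def rank_auroc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Midrank (Mann-Whitney U) AUROC of positives vs negatives."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    n_pos, n_neg = pos.size, neg.size
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _flatten_cells(
    prepared: pd.DataFrame, ann: PerturbationAnnotation
) -> Tuple[np.ndarray, np.ndarray]:
    """Flatten finite (experiment, kinase) cells into TP and TN score vectors."""
    tp_scores: List[float] = []
    tn_scores: List[float] = []
    for exp in prepared.columns:
        col = prepared[exp].dropna()
        targets = set(ann.targets_of(exp))
        for kinase, val in col.items():
            (tp_scores if kinase in targets else tn_scores).append(float(val))
    return np.asarray(tp_scores), np.asarray(tn_scores)


def auroc_downsampled(
    prepared: pd.DataFrame,
    ann: PerturbationAnnotation,
    n_rep: int = 1000,
    seed: int = 0,
) -> MetricResult:
    """Class-balanced AUROC over n_rep random negative subsets.

    Per repeat, |TP| true negatives are sampled without replacement
    (with replacement, flagged, when negatives are scarcer than
    positives) and a midrank AUROC computed; the point estimate is the
    median of the repeat distribution.
    """
    tp, tn = _flatten_cells(prepared, ann)
    if tp.size == 0 or tn.size == 0:
        raise ValueError("need at least one TP and one TN cell")
    rng = np.random.default_rng(seed)
    replace = tn.size < tp.size
    if replace:
        warnings.warn("fewer TNs than TPs; down-sampling with replacement")
    dist = np.empty(n_rep)
    for i in range(n_rep):
        sub = rng.choice(tn, size=tp.size, replace=replace)
        dist[i] = rank_auroc(tp, sub)
    return MetricResult(
        metric="auroc",
        value=float(np.median(dist)),
        distribution=dist,
        n_kinases=int(tp.size),
        details={"n_tp": int(tp.size), "n_tn": int(tn.size)},
    )


def _per_instance_ranks(
    prepared: pd.DataFrame, ann: PerturbationAnnotation
) -> pd.DataFrame:
    """Rank of each annotated kinase in its experiment (midranks, best = 1)."""
    rows = []
    skipped = 0
    for exp in prepared.columns:
        col = prepared[exp].dropna()
        n = col.size
        ranks = pd.Series(stats.rankdata(-col.to_numpy()), index=col.index)
        for kinase in ann.targets_of(exp):
            if kinase not in ranks.index:
                skipped += 1
                continue
            rows.append(
                {
                    "experiment": exp,
                    "kinase": kinase,
                    "rank": float(ranks[kinase]),
                    "n_finite": n,
                }
            )
    if skipped:
        warnings.warn(f"{skipped} annotated kinase(s) had no score and were skipped")
    if not rows:
        raise ValueError("no annotated kinase has a finite score")
    return pd.DataFrame(rows)


def scaled_rank(prepared: pd.DataFrame, ann: PerturbationAnnotation) -> MetricResult:
    """Mean scaled rank of perturbed kinases (rank / number scored).

    Lower is better; 0 < value <= 1. Instances are averaged per kinase
    first so heavily-perturbed kinases do not dominate, then across
    kinases.
    """
    tab = _per_instance_ranks(prepared, ann)
    tab["scaled_rank"] = tab["rank"] / tab["n_finite"]
    per_kinase = tab.groupby("kinase")["scaled_rank"].mean()
    return MetricResult(
        metric="scaled_rank",
        value=float(per_kinase.mean()),
        n_kinases=int(per_kinase.size),
        per_kinase=per_kinase,
        details={"per_instance": tab},
    )


def p_hit(
    prepared: pd.DataFrame, ann: PerturbationAnnotation, k: int = 10
) -> MetricResult:
    """Probability that the perturbed kinase ranks in the top k."""
    tab = _per_instance_ranks(prepared, ann)
    short = tab["n_finite"] < k
    if short.any():
        warnings.warn(f"{int(short.sum())} instance(s) scored fewer than k={k} kinases")
    tab["hit"] = (tab["rank"] <= k).astype(float)
    per_kinase = tab.groupby("kinase")["hit"].mean()
    return MetricResult(
        metric=f"phit_{k}",
        value=float(per_kinase.mean()),
        n_kinases=int(per_kinase.size),
        k=k,
        per_kinase=per_kinase,
    )


def concordance_stats(
    matrices: Dict[str, pd.DataFrame], top_k: int = 10, min_shared: int = 3
) -> Dict[str, pd.DataFrame]:
    """Pairwise agreement between activity matrices from different runs.

    For every experiment shared by a pair: Pearson and Spearman
    correlation over shared finite kinases, plus the Jaccard index of
    the top-k upregulated and top-k downregulated kinase sets; values
    averaged across experiments. Pairs with fewer than ``min_shared``
    shared kinases in an experiment skip that experiment.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to compare")
    names = sorted(matrices)
    out = {
        key: pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
        for key in ("pearson", "spearman", "jaccard_up", "jaccard_down")
    }
    for name in names:
        for key in out:
            out[key].loc[name, name] = 1.0
    for a, b in itertools.combinations(names, 2):
        ma, mb = matrices[a], matrices[b]
        shared_cols = [c for c in ma.columns if c in mb.columns]
        acc = {key: [] for key in out}
        for col in shared_cols:
            sa, sb = ma[col].dropna(), mb[col].dropna()
            shared = sa.index.intersection(sb.index)
            if shared.size < min_shared:
                continue
            va, vb = sa[shared], sb[shared]
            if va.std() > 0 and vb.std() > 0:
                acc["pearson"].append(float(va.corr(vb)))
                acc["spearman"].append(float(va.corr(vb, method="spearman")))
            k = min(top_k, shared.size)
            up_a = set(va.nlargest(k).index)
            up_b = set(vb.nlargest(k).index)
            dn_a = set(va.nsmallest(k).index)
            dn_b = set(vb.nsmallest(k).index)
            acc["jaccard_up"].append(len(up_a & up_b) / len(up_a | up_b))
            acc["jaccard_down"].append(len(dn_a & dn_b) / len(dn_a | dn_b))
        for key, vals in acc.items():
            if vals:
                mean = float(np.mean(vals))
                out[key].loc[a, b] = mean
                out[key].loc[b, a] = mean
    return out
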