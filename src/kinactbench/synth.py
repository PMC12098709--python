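"""Synthetic data with the statistical structure the benchmarks assume.

Three generators make every pipeline stage testable offline:

* :func:`generate_library` — a kinase-substrate bipartite graph with a
  requested per-kinase target-count range and a controllable fraction
  of sites shared between kinases;
* :func:`simulate_perturbation_dataset` — per-experiment log
  fold-change vectors: Gaussian background noise plus an additive
  shift of ``effect_size`` noise-SD units on the perturbed kinase's
  target sites, with missingness masked at random;
* :func:`simulate_tumor_cohort` — a cohort where each kinase's true
  activity is correlated (coupling ``rho``) with its protein level,
  site intensities are host-protein baseline plus the targeting
  kinases' activities plus noise, and activating sites read out
  activity rather than protein.

Defaults reflect the regimes the benchmarks were designed for: a
perturbation compendium of modest size with a clear 3-sigma effect,
and a ~200-sample cohort whose protein-activity coupling is strong but
imperfect. Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import numpy as np
import pandas as pd

from .activity import PhosphoMatrix
from .library import KSEdge, KSLibrary
from .perturb import PerturbationAnnotation
from .sites import SiteID, format_site_id
from .tumor import CohortDataset

_RESIDUES = np.array(["S", "T", "Y"])


@dataclass
class SimConfig:
    """Knobs of the synthetic generators.

    effect_size is expressed in units of the noise SD; overlap_prob is
    the probability that a target assignment reuses a site already
    claimed by another kinase; protein_site_coupling (rho) is the
    correlation between a kinase's protein level and its true activity
    in tumor cohorts.
    """

    n_kinases: int = 20
    n_sites: int = 500
    targets_per_kinase: Tuple[int, int] = (10, 25)
    overlap_prob: float = 0.1
    effect_size: float = 3.0
    noise_sd: float = 1.0
    missing_rate: float = 0.1
    n_experiments: int = 20
    n_samples: int = 200
    protein_site_coupling: float = 0.9
    baseline_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.protein_site_coupling <= 1:
            raise ValueError("protein_site_coupling must be in [0, 1]")
        lo, hi = self.targets_per_kinase
        if not 1 <= lo <= hi:
            raise ValueError("targets_per_kinase must be an increasing range from >= 1")
        if self.n_sites < hi:
            raise ValueError("n_sites must cover the largest requested target count")


def _site_pool(cfg: SimConfig, rng: np.random.Generator) -> List[SiteID]:
    sites = []
    for i in range(cfg.n_sites):
        sites.append(
            SiteID(
                gene=f"SUB{i:04d}",
                residue=str(rng.choice(_RESIDUES)),
                position=int(rng.integers(1, 2000)),
            )
        )
    return sites


def generate_library(cfg: SimConfig) -> Tuple[KSLibrary, Dict[str, Set[str]]]:
    """Random kinase-substrate library with controlled structure.

    Each kinase draws a target count uniformly from
    ``targets_per_kinase``; each assignment reuses an already-claimed
    site with probability ``overlap_prob`` (creating multi-kinase
    sites) and otherwise claims a fresh one. With ``overlap_prob=0``
    target sets are disjoint, which requires enough sites for the total
    demand.

    Returns the library and the ground-truth map kinase -> set of site
    row ids (as written by the matrix generators).
    """
    rng = np.random.default_rng(cfg.seed)
    sites = _site_pool(cfg, rng)
    lo, hi = cfg.targets_per_kinase
    degrees = rng.integers(lo, hi + 1, size=cfg.n_kinases)

    unused = list(range(cfg.n_sites))
    rng.shuffle(unused)
    used: List[int] = []
    edges: List[KSEdge] = []
    truth: Dict[str, Set[str]] = {}
    for ki in range(cfg.n_kinases):
        kinase = f"KIN{ki:03d}"
        chosen: Set[int] = set()
        for _ in range(int(degrees[ki])):
            reuse_pool = [s for s in used if s not in chosen]
            if reuse_pool and rng.random() < cfg.overlap_prob:
                chosen.add(int(rng.choice(reuse_pool)))
            elif unused:
                chosen.add(unused.pop())
            elif reuse_pool:
                chosen.add(int(rng.choice(reuse_pool)))
            else:
                raise ValueError(
                    "infeasible library request: site pool exhausted "
                    f"(n_sites={cfg.n_sites}, demand ~{degrees.sum()})"
                )
        for s in chosen:
            if s not in used:
                used.append(s)
            edges.append(KSEdge(kinase=kinase, site=sites[s], source="synthetic"))
        truth[kinase] = {format_site_id(sites[s]) for s in chosen}
    return KSLibrary(edges=edges), truth


def simulate_perturbation_dataset(
    lib: KSLibrary, cfg: SimConfig
) -> Tuple[PhosphoMatrix, PerturbationAnnotation, pd.DataFrame]:
    """Log fold-change matrix for single-kinase perturbation experiments.

    Each experiment perturbs one kinase (cycling through the catalog)
    with a random sign: its target sites are shifted by
    ``sign * effect_size * noise_sd`` on top of N(0, noise_sd^2)
    background; sites targeted by several kinases would take the
    largest shift among perturbed ones (a single kinase is perturbed
    per experiment, so this reduces to its own shift). Entries are then
    masked at ``missing_rate``.

    Returns the matrix, the annotation, and a truth table with the
    injected shift per experiment.
    """
    kinases = lib.kinases
    if len(kinases) < 2:
        raise ValueError("need at least two kinases to simulate perturbations")
    rng = np.random.default_rng(cfg.seed + 1)

    # union of library sites plus background-only sites up to n_sites
    lib_rows: Dict[str, SiteID] = {}
    for e in lib.edges:
        lib_rows[format_site_id(e.site)] = e.site
    extra_rng = np.random.default_rng(cfg.seed + 2)
    all_rows = dict(lib_rows)
    i = 0
    while len(all_rows) < cfg.n_sites:
        sid = SiteID(
            gene=f"BKG{i:04d}",
            residue=str(extra_rng.choice(_RESIDUES)),
            position=int(extra_rng.integers(1, 2000)),
        )
        all_rows[format_site_id(sid)] = sid
        i += 1
    row_ids = sorted(all_rows)

    target_rows = {
        k: {format_site_id(e.site) for e in lib.edges if e.kinase == k} for k in kinases
    }

    values = rng.normal(0.0, cfg.noise_sd, size=(len(row_ids), cfg.n_experiments))
    ann_rows = []
    truth_rows = []
    row_pos = {rid: i for i, rid in enumerate(row_ids)}
    for e in range(cfg.n_experiments):
        kinase = kinases[e % len(kinases)]
        sign = int(rng.choice([-1, 1]))
        shift = sign * cfg.effect_size * cfg.noise_sd
        for rid in target_rows[kinase]:
            values[row_pos[rid], e] += shift
        exp_id = f"exp{e:03d}"
        ann_rows.append({"experiment": exp_id, "kinase": kinase, "sign": sign})
        truth_rows.append(
            {"experiment": exp_id, "kinase": kinase, "sign": sign, "shift": shift}
        )
    if cfg.missing_rate > 0:
        mask = rng.random(values.shape) < cfg.missing_rate
        values[mask] = np.nan

    exp_ids = [f"exp{e:03d}" for e in range(cfg.n_experiments)]
    data = pd.DataFrame(values, index=row_ids, columns=exp_ids)
    mat = PhosphoMatrix(
        data=data, site_ids={rid: all_rows[rid] for rid in row_ids}, value_kind="logFC"
    ).drop_empty_rows()
    ann = PerturbationAnnotation(records=pd.DataFrame(ann_rows))
    return mat, ann, pd.DataFrame(truth_rows)


def simulate_tumor_cohort(
    lib: KSLibrary, cfg: SimConfig, cohort: str = "SYN"
) -> Tuple[CohortDataset, pd.DataFrame]:
    """A tumor cohort where activity tracks kinase protein level.

    Per sample: kinase protein levels ~ N(0,1); true activity =
    rho * protein + sqrt(1-rho^2) * latent; each substrate gene gets a
    baseline protein level ~ N(0,1); a site's intensity is
    ``baseline_weight * host_protein + sum(activities of targeting
    kinases)/multiplicity + N(0, noise_sd^2)``. One activating site per
    kinase is added on the kinase's own gene, reading out activity (not
    protein) plus noise. Missingness applies to sites and proteins
    alike.

    Returns the cohort dataset and the true activity matrix
    (kinases x samples).
    """
    rng = np.random.default_rng(cfg.seed + 3)
    kinases = lib.kinases
    n = cfg.n_samples
    samples = [f"s{i:04d}" for i in range(n)]
    rho = cfg.protein_site_coupling

    kin_protein = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(len(kinases), n)), index=kinases, columns=samples
    )
    latent = rng.normal(0.0, 1.0, size=(len(kinases), n))
    activity = pd.DataFrame(
        rho * kin_protein.to_numpy() + np.sqrt(1 - rho**2) * latent,
        index=kinases,
        columns=samples,
    )

    # site rows from the library
    site_ids: Dict[str, SiteID] = {}
    site_kinases: Dict[str, List[str]] = {}
    for e in lib.edges:
        rid = format_site_id(e.site)
        site_ids[rid] = e.site
        site_kinases.setdefault(rid, []).append(e.kinase)
    genes = sorted({s.gene for s in site_ids.values()})
    host_protein = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(len(genes), n)), index=genes, columns=samples
    )

    rows = []
    row_ids = sorted(site_ids)
    for rid in row_ids:
        gene = site_ids[rid].gene
        ks = site_kinases[rid]
        signal = activity.loc[ks].mean(axis=0)
        noise = rng.normal(0.0, cfg.noise_sd, size=n)
        rows.append(cfg.baseline_weight * host_protein.loc[gene] + signal + noise)
    site_data = pd.DataFrame(np.vstack(rows), index=row_ids, columns=samples)

    # activating sites: phosphosites on the kinase itself tracking activity
    activating: Dict[str, List[SiteID]] = {}
    act_rows = []
    act_ids = []
    for k in kinases:
        sid = SiteID(gene=k, residue="T", position=197)
        activating[k] = [sid]
        rid = format_site_id(sid)
        act_ids.append(rid)
        site_ids[rid] = sid
        act_rows.append(
            activity.loc[k].to_numpy() + rng.normal(0.0, cfg.noise_sd, size=n)
        )
    site_data = pd.concat(
        [site_data, pd.DataFrame(np.vstack(act_rows), index=act_ids, columns=samples)]
    )

    proteins = pd.concat([kin_protein, host_protein])
    proteins = proteins[~proteins.index.duplicated(keep="first")]

    if cfg.missing_rate > 0:
        m1 = rng.random(site_data.shape) < cfg.missing_rate
        site_data = site_data.mask(m1)
        m2 = rng.random(proteins.shape) < cfg.missing_rate
        proteins = proteins.mask(m2)

    mat = PhosphoMatrix(
        data=site_data,
        site_ids={rid: site_ids[rid] for rid in site_data.index},
        value_kind="centered_log_intensity",
    ).drop_empty_rows()
    dataset = CohortDataset(
        cohort=cohort, proteins=proteins, sites=mat, activating_sites=activating
    )
    return dataset, activity
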