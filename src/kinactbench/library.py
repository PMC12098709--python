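"""Kinase-substrate libraries: loading, merging, filtering, randomization.

A kinase-substrate library is a bipartite edge set linking kinases to
the phosphosites they are known (or predicted) to phosphorylate. All
inference methods consume the library through per-kinase target sets.
Libraries from different resources are standardized to a common schema
(kinase symbol, substrate gene, residue, position, optional flank,
source tag), deduplicated on the canonical site key, and can be
combined, self-site-censored (to avoid leakage into benchmarks built
from kinase-level measurements) or degree-preservingly randomized to
serve as a negative-control prior.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .sites import VALID_RESIDUES, SiteID

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KSEdge:
    """One kinase -> substrate-site relationship with provenance."""

    kinase: str
    site: SiteID
    source: str = ""

    @property
    def key(self) -> Tuple[str, str]:
        return (self.kinase, self.site.canonical_key())


@dataclass
class KSLibrary:
    """A deduplicated kinase-substrate edge set.

    Edges are unique on ``(kinase, canonical site key)``; merging two
    records of the same edge concatenates their source tags.
    """

    edges: List[KSEdge] = field(default_factory=list)
    kinase_class: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = _dedup_edges(self.edges)

    # -- basic views ---------------------------------------------------

    @property
    def kinases(self) -> List[str]:
        return sorted({e.kinase for e in self.edges})

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def targets(self, kinase: str) -> List[SiteID]:
        return [e.site for e in self.edges if e.kinase == kinase]

    def target_keys(self) -> Dict[str, Set[str]]:
        """Per-kinase sets of canonical site keys."""
        out: Dict[str, Set[str]] = {}
        for e in self.edges:
            out.setdefault(e.kinase, set()).add(e.site.canonical_key())
        return out

    def degree_sequence(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for e in self.edges:
            out[e.kinase] = out.get(e.kinase, 0) + 1
        return out

    def site_multiplicities(self) -> Dict[str, int]:
        """How many kinases target each canonical site."""
        out: Dict[str, int] = {}
        for e in self.edges:
            k = e.site.canonical_key()
            out[k] = out.get(k, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "kinase": e.kinase,
                "gene": e.site.gene,
                "residue": e.site.residue,
                "position": e.site.position,
                "flank": e.site.flank or "",
                "source": e.source,
            }
            for e in self.edges
        ]
        return pd.DataFrame(
            rows, columns=["kinase", "gene", "residue", "position", "flank", "source"]
        )


def _dedup_edges(edges: Iterable[KSEdge]) -> List[KSEdge]:
    seen: Dict[Tuple[str, str], KSEdge] = {}
    for e in edges:
        k = e.key
        if k in seen:
            prev = seen[k]
            srcs = [s for s in prev.source.split(";") if s]
            if e.source and e.source not in srcs:
                seen[k] = KSEdge(prev.kinase, prev.site, ";".join(srcs + [e.source]))
        else:
            seen[k] = e
    return list(seen.values())


class LibrarySchemaError(ValueError):
    """Raised when a raw library table cannot be mapped to the common schema."""


class EmptyLibraryError(ValueError):
    """Raised when standardization yields no usable edges."""


DEFAULT_SCHEMA = {
    "kinase": "kinase",
    "gene": "gene",
    "residue": "residue",
    "position": "position",
    "flank": "flank",
    "source": "source",
}


def standardize_library(
    raw_table: pd.DataFrame,
    schema: Optional[Mapping[str, str]] = None,
    kinase_whitelist: Optional[Set[str]] = None,
    source: str = "",
) -> Tuple[KSLibrary, int]:
    """Convert a raw resource table to a standardized :class:`KSLibrary`.

    Parameters
    ----------
    raw_table
        Tabular kinase-substrate records.
    schema
        Mapping from the common field names (``kinase``, ``gene``,
        ``residue``, ``position``, and optionally ``flank``, ``source``)
        to the raw table's column names. Defaults to identity.
    kinase_whitelist
        Optional set of kinase symbols to retain (e.g. a curated kinome
        list); applied after symbol canonicalization.
    source
        Fallback provenance tag when the table has no source column.

    Returns
    -------
    (library, n_dropped)
        The library and the number of rows dropped because residue or
        position could not be parsed.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    for mandatory in ("kinase", "gene", "residue", "position"):
        if schema[mandatory] not in raw_table.columns:
            raise LibrarySchemaError(
                f"missing mandatory column {schema[mandatory]!r} for field {mandatory!r}"
            )
    has_flank = schema.get("flank") in raw_table.columns
    has_source = schema.get("source") in raw_table.columns

    edges: List[KSEdge] = []
    dropped = 0
    for _, row in raw_table.iterrows():
        kinase = str(row[schema["kinase"]]).strip().upper()
        gene = str(row[schema["gene"]]).strip().upper()
        residue = str(row[schema["residue"]]).strip().upper()
        try:
            position = int(row[schema["position"]])
        except (TypeError, ValueError):
            dropped += 1
            continue
        if residue not in VALID_RESIDUES or position < 1 or not kinase or not gene:
            dropped += 1
            continue
        flank = None
        if has_flank:
            raw_flank = row[schema["flank"]]
            if isinstance(raw_flank, str) and raw_flank.strip():
                flank = raw_flank.strip().upper()
        src = str(row[schema["source"]]) if has_source else source
        try:
            site = SiteID(gene=gene, residue=residue, position=position, flank=flank)
        except ValueError:
            dropped += 1
            continue
        if kinase_whitelist is not None and kinase not in kinase_whitelist:
            continue
        edges.append(KSEdge(kinase=kinase, site=site, source=src))

    if not edges:
        raise EmptyLibraryError("standardization produced an empty library")
    return KSLibrary(edges=edges), dropped


def map_sites(
    matrix_sites: Mapping[str, SiteID], lib: KSLibrary
) -> Tuple[Dict[str, str], List[str]]:
    """Map library sites onto measured matrix rows.

    Match precedence follows the two-tier identity convention: a
    (gene, flank) exact match on the centered 11-mer core when both
    sides carry flanks, with (gene, residue, position) as the fallback.

    Parameters
    ----------
    matrix_sites
        Mapping from matrix row id to its :class:`SiteID`.
    lib
        The library whose sites should be located in the matrix.

    Returns
    -------
    (mapping, unmatched)
        ``mapping`` maps each library site's canonical key to a matrix
        row id; ``unmatched`` lists canonical keys of library sites with
        no matrix counterpart. When several matrix rows carry the same
        identity the first occurrence wins and a warning is emitted.
    """
    by_flank: Dict[str, str] = {}
    by_pos: Dict[str, str] = {}
    for row_id, site in matrix_sites.items():
        fk = site.flank_key
        if fk is not None:
            if fk in by_flank:
                warnings.warn(f"matrix rows share flank identity {fk}; keeping first")
            else:
                by_flank[fk] = row_id
        pk = site.position_key
        if pk in by_pos:
            warnings.warn(f"matrix rows share positional identity {pk}; keeping first")
        else:
            by_pos[pk] = row_id

    mapping: Dict[str, str] = {}
    unmatched: List[str] = []
    seen_lib: Set[str] = set()
    for edge in lib.edges:
        key = edge.site.canonical_key()
        if key in seen_lib:
            continue
        seen_lib.add(key)
        row = None
        fk = edge.site.flank_key
        if fk is not None and fk in by_flank:
            row = by_flank[fk]
        elif edge.site.position_key in by_pos:
            row = by_pos[edge.site.position_key]
        if row is None:
            unmatched.append(key)
        else:
            mapping[key] = row
    return mapping, unmatched


def combine_libraries(libs: Sequence[KSLibrary]) -> KSLibrary:
    """Union of several libraries, deduplicated on (kinase, site key)."""
    if not libs:
        raise ValueError("combine_libraries requires at least one library")
    all_edges: List[KSEdge] = []
    kinase_class: Dict[str, str] = {}
    for lib in libs:
        all_edges.extend(lib.edges)
        kinase_class.update(lib.kinase_class)
    return KSLibrary(edges=all_edges, kinase_class=kinase_class)


def randomize_library(lib: KSLibrary, seed: int) -> KSLibrary:
    """Shuffle which site carries which kinase assignments.

    Sites are grouped by multiplicity class (number of kinases that
    target them) and the site labels are permuted within each class.
    This exactly preserves both conserved quantities of the original
    bipartite graph: every kinase keeps its target-set size and the
    multiset of per-site kinase counts is unchanged, while the actual
    kinase -> site assignments are randomized. Deterministic per seed.
    """
    if not lib.edges:
        raise ValueError("cannot randomize an empty library")
    rng = np.random.default_rng(seed)

    site_by_key: Dict[str, SiteID] = {}
    kinases_per_site: Dict[str, List[str]] = {}
    for e in lib.edges:
        k = e.site.canonical_key()
        site_by_key[k] = e.site
        kinases_per_site.setdefault(k, []).append(e.kinase)

    by_mult: Dict[int, List[str]] = {}
    for key, ks in kinases_per_site.items():
        by_mult.setdefault(len(ks), []).append(key)

    relabel: Dict[str, str] = {}
    for mult in sorted(by_mult):
        keys = sorted(by_mult[mult])
        perm = rng.permutation(len(keys))
        for i, key in enumerate(keys):
            relabel[key] = keys[perm[i]]

    new_edges = [
        KSEdge(e.kinase, site_by_key[relabel[e.site.canonical_key()]], "randomized")
        for e in lib.edges
    ]
    return KSLibrary(edges=new_edges, kinase_class=dict(lib.kinase_class))


def censor_self_sites(lib: KSLibrary) -> KSLibrary:
    """Drop every edge whose substrate gene equals the kinase symbol.

    Autophosphorylation sites sit on the kinase itself; keeping them
    would let kinase-level measurements leak into target-set scores, so
    benchmarks built from kinase protein or activating-site levels must
    run on a censored library.
    """
    kept = [e for e in lib.edges if e.site.gene != e.kinase]
    if not kept and lib.edges:
        warnings.warn("censor_self_sites removed every edge (library was all self-sites)")
    return KSLibrary(edges=kept, kinase_class=dict(lib.kinase_class))


def has_self_sites(lib: KSLibrary) -> bool:
    return any(e.site.gene == e.kinase for e in lib.edges)


def filter_min_targets(
    lib: KSLibrary,
    measured_keys: Set[str],
    min_targets: int = 5,
    site_mapping: Optional[Mapping[str, str]] = None,
) -> Dict[str, Set[str]]:
    """Per-kinase measured-target sets for kinases meeting the coverage rule.

    Only kinases with at least ``min_targets`` of their library targets
    present among the measured sites are retained; everything downstream
    (activity scoring, benchmarks) relies on this filter.

    Parameters
    ----------
    measured_keys
        Identifiers of the measured sites. When ``site_mapping`` is
        given these are matrix row ids; otherwise canonical site keys.
    site_mapping
        Optional library-site-key -> matrix-row-id mapping from
        :func:`map_sites`; when provided the returned sets contain
        matrix row ids.
    """
    if min_targets < 1:
        raise ValueError("min_targets must be >= 1")
    out: Dict[str, Set[str]] = {}
    for kinase, keys in lib.target_keys().items():
        if site_mapping is not None:
            measured = {site_mapping[k] for k in keys if k in site_mapping} & measured_keys
        else:
            measured = keys & measured_keys
        if len(measured) >= min_targets:
            out[kinase] = measured
    return out


def library_to_gmt(lib: KSLibrary) -> str:
    """GMT text export: one line per kinase, members = canonical site keys."""
    lines = []
    for kinase in lib.kinases:
        keys = sorted({e.site.canonical_key() for e in lib.edges if e.kinase == kinase})
        lines.append("\t".join([kinase, "kinase_targets"] + keys))
    return "\n".join(lines) + "\n"
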