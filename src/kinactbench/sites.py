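"""Phosphosite identities and their canonical string keys.

A phosphosite is identified by the HGNC-style gene symbol of its host
protein together with either (a) the amino-acid window flanking the
phosphorylated residue (a 15-mer or 11-mer centered on the site) or
(b) the residue type and its 1-based position within the protein.
Flank-based keys are preferred for matching library sites to measured
sites because they survive isoform position shifts; residue+position is
the fallback when no flank is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

#: residues that can carry a phosphate group in this context
VALID_RESIDUES = frozenset("STYH")

#: pad character used at protein termini in flanking windows
FLANK_PAD = "_"


@dataclass(frozen=True)
class SiteID:
    """A single phosphorylation site.

    Parameters
    ----------
    gene
        Host-protein gene symbol (uppercase HGNC style).
    residue
        Phosphorylated amino acid, one of ``S``, ``T``, ``Y``, ``H``.
    position
        1-based residue position within the protein.
    flank
        Optional odd-length amino-acid window centered on the residue
        (conventionally a 15-mer or 11-mer), uppercase, with ``_``
        padding at protein ends.
    """

    gene: str
    residue: str
    position: int
    flank: Optional[str] = None

    def __post_init__(self) -> None:
        if self.residue not in VALID_RESIDUES:
            raise ValueError(f"invalid residue {self.residue!r} (expected one of S/T/Y/H)")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.flank is not None:
            f = self.flank
            if len(f) % 2 != 1:
                raise ValueError(f"flank must have odd length, got {len(f)}")
            center = f[len(f) // 2]
            if center != FLANK_PAD and center.upper() != self.residue:
                raise ValueError(
                    f"flank center {center!r} does not match residue {self.residue!r}"
                )

    @property
    def flank_core(self) -> Optional[str]:
        """The centered 11 characters of the flank, lowercase.

        A 15-mer and an 11-mer describing the same site agree on this
        core, so it is the unit of flank comparison.
        """
        if self.flank is None:
            return None
        f = self.flank
        if len(f) > 11:
            trim = (len(f) - 11) // 2
            f = f[trim : len(f) - trim]
        return f.lower()

    @property
    def position_key(self) -> str:
        """Canonical gene|residue|position key."""
        return f"{self.gene}|{self.residue}|{self.position}"

    @property
    def flank_key(self) -> Optional[str]:
        """Canonical gene|flank-core key, or None when no flank is known."""
        core = self.flank_core
        if core is None:
            return None
        return f"{self.gene}|{core}"

    def canonical_key(self) -> str:
        """Canonical key: flank-based when a flank is present, else positional."""
        return self.flank_key or self.position_key

    def __str__(self) -> str:  # pragma: no cover - convenience only
        return self.canonical_key()


def parse_site_id(text: str) -> SiteID:
    """Parse a matrix row identifier into a :class:`SiteID`.

    Accepted forms (fields separated by ``|``)::

        GENE|S9
        GENE|S9|RSRHSSYPAGTED

    i.e. gene symbol, residue letter immediately followed by the
    position, and an optional flanking window.
    """
    parts = text.strip().split("|")
    if len(parts) < 2:
        raise ValueError(f"cannot parse site id {text!r}: expected GENE|<res><pos>[|flank]")
    gene = parts[0].upper()
    respos = parts[1].strip()
    residue, pos_s = respos[:1].upper(), respos[1:]
    try:
        position = int(pos_s)
    except ValueError as exc:
        raise ValueError(f"cannot parse position in site id {text!r}") from exc
    flank = parts[2].upper() if len(parts) > 2 and parts[2] else None
    return SiteID(gene=gene, residue=residue, position=position, flank=flank)


def format_site_id(site: SiteID) -> str:
    """Inverse of :func:`parse_site_id`."""
    base = f"{site.gene}|{site.residue}{site.position}"
    if site.flank is not None:
        return f"{base}|{site.flank}"
    return base
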