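"""Seed extraction, seed-match motifs and UTR site scanning.

The seed is nucleotides 2-8 of the mature miRNA (5'->3'); two miRNAs with an
identical seed belong to the same family.  A target site in a 3'-UTR is an
occurrence of the reverse complement of (part of) the seed, classified in
the usual way:

* ``6mer``     — match to seed positions 2-7 only;
* ``7mer-m8``  — 6mer plus a match to seed position 8 (5' of the core on the UTR);
* ``7mer-A1``  — 6mer plus an A immediately 3' of the core (opposite miRNA nt 1);
* ``8mer``     — both.

UTRs are stored 5'->3'; DNA input is transliterated T->U at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "MatureMiRNA",
    "SeedSite",
    "SITE_TYPES",
    "extract_seed",
    "reverse_complement",
    "seed_match_motif",
    "scan_utr",
    "catalog_from_fasta",
    "family_partition",
]

_RNA = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")


def _check_rna(sequence: str, what: str = "sequence") -> str:
    seq = sequence.upper()
    bad = set(seq) - _RNA
    if bad:
        raise ValueError(f"{what} contains non-RNA characters: {sorted(bad)}")
    return seq


def extract_seed(sequence: str) -> str:
    """Seed = positions 2-8 (1-based, inclusive) of a mature RNA sequence."""
    seq = _check_rna(sequence, "mature sequence")
    if len(seq) < 8:
        raise ValueError(f"mature sequence must be >= 8 nt (got {len(seq)})")
    return seq[1:8]


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the RNA alphabet (A<->U, C<->G)."""
    return _check_rna(sequence)[::-1].translate(_COMPLEMENT)


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence with its derived seed and family id."""

    mirna_id: str
    sequence: str
    seed: str = ""
    family_id: str = ""

    def __post_init__(self) -> None:
        seq = _check_rna(self.sequence, f"miRNA {self.mirna_id!r}")
        object.__setattr__(self, "sequence", seq)
        seed = extract_seed(seq)
        if self.seed and self.seed != seed:
            raise ValueError(f"seed {self.seed!r} inconsistent with sequence")
        object.__setattr__(self, "seed", seed)
        object.__setattr__(self, "family_id", seed)


@dataclass(frozen=True)
class SeedSite:
    """A classified seed-match site in a UTR (start is 0-based, 5'->3')."""

    utr_id: str
    start: int
    site_type: str
    mirna_id: str

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")


def seed_match_motif(mirna: MatureMiRNA) -> str:
    """The 7-nt UTR motif fully pairing the seed (the 7mer-m8 match)."""
    return reverse_complement(mirna.seed)


def scan_utr(utr: str, mirna: MatureMiRNA, utr_id: str = "") -> list[SeedSite]:
    """Find and classify every seed-match site of ``mirna`` in a UTR.

    The UTR may be RNA or DNA; DNA is transliterated T->U.  Overlapping
    occurrences are all reported.  The reported ``start`` is the start of the
    matched substring implied by the site type (8mer and 7mer-m8 include the
    m8-match nucleotide 5' of the 6mer core).
    """
    seq = utr.upper()
    if "T" in seq:
        if "U" in seq:
            raise ValueError(f"UTR {utr_id!r} mixes T and U")
        logger.debug("UTR %r: DNA input transliterated T->U", utr_id)
        seq = seq.replace("T", "U")
    if seq:
        _check_rna(seq, f"UTR {utr_id!r}")

    motif7 = seed_match_motif(mirna)   # pairs miRNA nt 2-8; core6 = motif7[1:]
    m8_nt, core6 = motif7[0], motif7[1:]
    sites: list[SeedSite] = []
    pos = seq.find(core6)
    while pos != -1:
        has_m8 = pos >= 1 and seq[pos - 1] == m8_nt
        has_a1 = pos + 6 < len(seq) and seq[pos + 6] == "A"
        if has_m8 and has_a1:
            site_type, start = "8mer", pos - 1
        elif has_m8:
            site_type, start = "7mer-m8", pos - 1
        elif has_a1:
            site_type, start = "7mer-A1", pos
        else:
            site_type, start = "6mer", pos
        sites.append(SeedSite(utr_id, start, site_type, mirna.mirna_id))
        pos = seq.find(core6, pos + 1)
    return sites


def catalog_from_fasta(seqs: Mapping[str, str]) -> list[MatureMiRNA]:
    """Build a mature-miRNA catalog from an id->sequence mapping."""
    return [MatureMiRNA(mirna_id, seq) for mirna_id, seq in seqs.items()]


def family_partition(catalog: Iterable[MatureMiRNA]) -> dict[str, list[str]]:
    """Group a catalog into seed families (seed -> sorted member ids)."""
    families: dict[str, list[str]] = {}
    for m in catalog:
        families.setdefault(m.family_id, []).append(m.mirna_id)
    return {seed: sorted(ids) for seed, ids in families.items()}


def sites_to_rows(sites: Sequence[SeedSite]) -> list[dict]:
    """Rows for a sites TSV (utr_id, mirna_id, start, site_type)."""
    return [
        {"utr_id": s.utr_id, "mirna_id": s.mirna_id, "start": s.start, "site_type": s.site_type}
        for s in sites
    ]
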