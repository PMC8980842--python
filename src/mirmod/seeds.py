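"""Canonical microRNA seed-site matching.

A miRNA seed is nucleotides 2-7 (6mer) or 2-8 (7mer core) of the mature
sequence, read 5'->3'.  Canonical target sites on the 3'UTR sense strand are
the reverse complements of the seed, optionally followed by an adenosine
opposite miRNA position 1:

* ``6mer``     — reverse complement of positions 2-7 (6 nt)
* ``7mer-A1``  — 6mer followed by an A (7 nt)
* ``7mer-m8``  — reverse complement of positions 2-8 (7 nt)
* ``8mer``     — 7mer-m8 followed by an A (8 nt)

Each occurrence of the 6mer core is reported exactly once with its
highest-priority type (8mer > 7mer-m8 > 7mer-A1 > 6mer).  Coordinates are
0-based, half-open, on the UTR sense strand.  U and T are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SeedSite", "find_seed_sites", "site_sequence", "SITE_TYPES", "SequenceError"]

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_PRIORITY = {t: i for i, t in enumerate(SITE_TYPES)}

_DNA_COMP = str.maketrans("ACGT", "TGCA")


class SequenceError(ValueError):
    """Raised for sequences outside the ACGT/ACGU alphabet."""


@dataclass(frozen=True)
class SeedSite:
    """One canonical seed match in a UTR (0-based half-open interval)."""

    site_type: str
    start: int
    end: int
    mir_id: str = ""
    gene_id: str = ""


def _to_dna(seq: str, what: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise SequenceError(f"{what} contains non-ACGU/ACGT characters: {sorted(bad)}")
    return s


def _revcomp(dna: str) -> str:
    return dna.translate(_DNA_COMP)[::-1]


def site_sequence(mir_sequence: str, site_type: str) -> str:
    """DNA sequence of a perfect canonical site of the given type.

    Used both to scan UTRs and to plant ground-truth sites in synthetic UTRs.
    """
    m = _to_dna(mir_sequence, "miR sequence")
    if len(m) < 8:
        raise SequenceError("miR sequence must be at least 8 nt")
    core6 = _revcomp(m[1:7])
    core7 = _revcomp(m[1:8])
    if site_type == "6mer":
        return core6
    if site_type == "7mer-A1":
        return core6 + "A"
    if site_type == "7mer-m8":
        return core7
    if site_type == "8mer":
        return core7 + "A"
    raise ValueError(f"unknown site type {site_type!r}")


def find_seed_sites(mir_sequence: str, utr_sequence: str) -> list[SeedSite]:
    """Scan a UTR for canonical seed sites of one miRNA.

    Returns sites sorted by position; each 6mer-core occurrence appears once
    with its highest-priority extension.
    """
    m = _to_dna(mir_sequence, "miR sequence")
    if len(m) < 8:
        raise SequenceError("miR sequence must be at least 8 nt")
    utr = _to_dna(utr_sequence, "UTR sequence")
    if len(utr) < 6:
        return []

    core6 = _revcomp(m[1:7])
    # base pairing miR position 8 (m[7]) contributes the first UTR nucleotide
    # of a 7mer-m8/8mer site, immediately 5' of the core match
    m8_base = _revcomp(m[7])

    sites: list[SeedSite] = []
    pos = utr.find(core6)
    while pos != -1:
        has_m8 = pos >= 1 and utr[pos - 1] == m8_base
        has_a1 = pos + 6 < len(utr) and utr[pos + 6] == "A"
        if has_m8 and has_a1:
            sites.append(SeedSite("8mer", pos - 1, pos + 7))
        elif has_m8:
            sites.append(SeedSite("7mer-m8", pos - 1, pos + 6))
        elif has_a1:
            sites.append(SeedSite("7mer-A1", pos, pos + 7))
        else:
            sites.append(SeedSite("6mer", pos, pos + 6))
        pos = utr.find(core6, pos + 1)
    return sites
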