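"""Synthetic transposase references and back-translation tables.

Tc1/mariner transposases carry a DDE/D catalytic triad whose family label
(DD34D, DD37D, DD40D, DD41D, DD34E, ...) encodes the number of residues
strictly between the second and third acidic residue plus the identity of
the third (aspartate vs glutamate).  This module builds deterministic
synthetic transposases with a realistic domain layout — an N-terminal
helix-turn-helix (HTH) DNA-binding region, a nuclear localisation signal
(NLS), the WVPHEL and YSPDLA mariner motifs, and the catalytic triad at a
chosen spacing.  They serve as query panels for translated homology
searches and as annotated references for triad projection.

All filler residues are drawn from a seeded generator over an alphabet
that excludes D, E, G, P and R.  Excluding the acidic residues keeps the
catalytic triad unambiguous, excluding the helix breakers G/P makes the
designed HTH the only window that can satisfy the HTH heuristic, and
excluding R keeps basic-rich NLS windows confined to the designed signal.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

# Fixed most-frequent-codon table (insect-biased) used for deterministic
# back-translation of ORFs.
MOST_FREQUENT_CODON = {
    "A": "GCC", "R": "CGC", "N": "AAC", "D": "GAC", "C": "TGC",
    "Q": "CAG", "E": "GAG", "G": "GGC", "H": "CAC", "I": "ATC",
    "L": "CTG", "K": "AAG", "M": "ATG", "F": "TTC", "P": "CCC",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTG",
    "*": "TAA",
}

#: filler alphabet for synthetic transposases (see module docstring)
FILLER_ALPHABET = "ACFHIKLMNQSTVWY"

#: designed domain sequences
NLS_SEQ = "PKKKRKV"
HTH_SEQ = "SQLKRELGVSQRTISRILQKAG"  # 22-mer helix-turn-helix cassette
WVPHEL = "WVPHEL"
YSPDLA = "YSPDLA"

# 0-based positions of the designed domains within every synthetic ORF
NLS_POS = 20
HTH_POS = 86
WVPHEL_POS = 118
YSPDLA_POS = 150
D1_POS = 170
INNER1_DEFAULT = 90  # residues strictly between the 1st and 2nd D


def back_translate(aa: str) -> str:
    """Back-translate a protein with the fixed most-frequent-codon table."""
    try:
        return "".join(MOST_FREQUENT_CODON[res] for res in aa)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"no codon for residue {exc}") from exc


def parse_family_label(label: str) -> tuple[int, str]:
    """Split a triad family label such as 'DD34D' into (inner spacing, 3rd residue)."""
    if not (label.startswith("DD") and label[-1] in "DE"):
        raise ValueError(f"unrecognised triad family label: {label!r}")
    return int(label[2:-1]), label[-1]


@dataclass(frozen=True)
class RefTransposase:
    """A reference transposase with annotated catalytic-triad columns."""

    id: str
    family: str
    aa: str
    triad_positions: tuple[int, int, int]  # 0-based


def make_transposase_aa(
    family_label: str,
    length: int = 354,
    inner1: int = INNER1_DEFAULT,
    with_hth: bool = True,
    with_nls: bool = True,
    seed_key: str | None = None,
) -> tuple[str, tuple[int, int, int]]:
    """Build a deterministic synthetic transposase for one triad family.

    Returns the amino-acid sequence and the 0-based positions of the
    three catalytic residues.  ``inner1``/``inner2`` count residues
    strictly between consecutive catalytic positions.
    """
    inner2, res3 = parse_family_label(family_label)
    d1 = D1_POS
    d2 = d1 + inner1 + 1
    d3 = d2 + inner2 + 1
    if length < d3 + 10:
        raise ValueError("ORF too short for the requested triad spacing")
    key = seed_key if seed_key is not None else f"{family_label}|{length}"
    rng = np.random.default_rng(zlib.crc32(key.encode()) & 0x7FFFFFFF)
    aa = list(rng.choice(list(FILLER_ALPHABET), size=length))
    aa[0] = "M"
    if with_nls:
        aa[NLS_POS:NLS_POS + len(NLS_SEQ)] = list(NLS_SEQ)
    if with_hth:
        aa[HTH_POS:HTH_POS + len(HTH_SEQ)] = list(HTH_SEQ)
    aa[WVPHEL_POS:WVPHEL_POS + len(WVPHEL)] = list(WVPHEL)
    aa[YSPDLA_POS:YSPDLA_POS + len(YSPDLA)] = list(YSPDLA)
    aa[d1] = "D"
    aa[d2] = "D"
    aa[d3] = res3
    return "".join(aa), (d1, d2, d3)


def _protected_positions(length: int, triad: tuple[int, int, int]) -> set[int]:
    prot = {0, *triad}
    for start, motif in [(NLS_POS, NLS_SEQ), (HTH_POS, HTH_SEQ),
                         (WVPHEL_POS, WVPHEL), (YSPDLA_POS, YSPDLA)]:
        prot.update(range(start, start + len(motif)))
    return prot


def make_lineage_transposase(
    family_label: str, lineage_name: str, length: int = 354,
    variation: float = 0.25, with_hth: bool = True, with_nls: bool = True,
) -> tuple[str, tuple[int, int, int]]:
    """Derive a lineage-specific transposase from its family archetype.

    A fraction ``variation`` of the filler positions is substituted with
    other filler residues (seeded by the lineage name), leaving the
    designed domains and the catalytic triad untouched.  Lineages of one
    family therefore share ~75% of their transposase — coherent at the
    family level yet distinct below the nucleotide-lineage threshold.
    """
    aa, triad = make_transposase_aa(family_label, length=length,
                                    with_hth=with_hth, with_nls=with_nls)
    prot = _protected_positions(length, triad)
    rng = np.random.default_rng(zlib.crc32(f"lin|{lineage_name}".encode()) & 0x7FFFFFFF)
    out = list(aa)
    for i in range(length):
        if i in prot or rng.random() >= variation:
            continue
        choices = [c for c in FILLER_ALPHABET if c != out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out), triad


#: canonical transposase length per family archetype
FAMILY_LENGTHS = {"DD34D": 354, "DD37D": 346, "DD40D": 351,
                  "DD41D": 361, "DD34E": 343, "DD37E": 339}


def default_reference_panel() -> list[RefTransposase]:
    """Synthetic references covering the DD-x-D and DD-x-E families.

    The DDxE members stand in for Tc1-like transposases so that
    candidate filtering can compare best scores against the two
    sub-panels.
    """
    panel = []
    for family, length in FAMILY_LENGTHS.items():
        aa, triad = make_transposase_aa(family, length=length)
        panel.append(RefTransposase(f"ref_{family}", family, aa, triad))
    return panel


def ddxd_panel() -> list[RefTransposase]:
    return [r for r in default_reference_panel() if r.family.endswith("D")]


def ddxe_panel() -> list[RefTransposase]:
    return [r for r in default_reference_panel() if r.family.endswith("E")]


def default_query_panel() -> dict[str, str]:
    """Protein query panel for translated mining (DD-x-D families only)."""
    return {r.id: r.aa for r in ddxd_panel()}
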