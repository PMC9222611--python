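"""Codon-degeneracy classification of coding sites.

Every position of an in-frame coding sequence is classified by how many of
the three possible nucleotide substitutions at that position preserve the
encoded amino acid: 0 preserved -> 0-fold degenerate, 1 -> 2-fold,
2 -> 3-fold, 3 -> 4-fold.  The hard partition of CDS positions into
synonymous and nonsynonymous site classes (the denominators of per-site
substitution abundances) is derived from these degeneracy classes; a
fractional (Nei–Gojobori style) weighting is also available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping

from Bio.Data import CodonTable

log = logging.getLogger(__name__)

BASES = "ACGT"

#: number of amino-acid-preserving substitutions -> degeneracy class
_FOLD = {0: 0, 1: 2, 2: 3, 3: 4}

SYN_SITE = "SYN_SITE"
NONSYN_SITE = "NONSYN_SITE"

Mode = Literal["fourfold", "any_syn", "fractional"]


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table as a complete 64-entry codon -> amino acid map.

    Stop codons map to ``*``.
    """

    table_id: int
    codon_to_aa: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(
                f"genetic code must have 64 codons, got {len(self.codon_to_aa)}"
            )

    @classmethod
    def from_ncbi(cls, table_id: int = 1) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        return cls(table_id=table_id, codon_to_aa=mapping)

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon) == "*"


STANDARD_CODE = GeneticCode.from_ncbi(1)


def codon_degeneracy(codon: str, position: int, code: GeneticCode = STANDARD_CODE) -> int:
    """Degeneracy class (0, 2, 3 or 4) of one position of a sense codon.

    The class is the conventional name for the count of substitutions at
    ``position`` that leave the amino acid unchanged: 0 preserved -> 0-fold,
    1 -> 2-fold, 2 -> 3-fold, 3 -> 4-fold.  Substitutions creating a stop
    codon never count as preserving.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    if position not in (0, 1, 2):
        raise ValueError(f"codon position must be 0, 1 or 2, got {position}")
    aa = code.codon_to_aa[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no degeneracy class")
    preserved = 0
    for base in BASES:
        if base == codon[position]:
            continue
        mutant = codon[:position] + base + codon[position + 1 :]
        if code.codon_to_aa[mutant] == aa:
            preserved += 1
    return _FOLD[preserved]


def _synonymous_fraction(codon: str, position: int, code: GeneticCode) -> float:
    """Fraction (out of 3) of substitutions at this position that are synonymous."""
    aa = code.codon_to_aa[codon]
    preserved = sum(
        1
        for base in BASES
        if base != codon[position]
        and code.codon_to_aa[codon[:position] + base + codon[position + 1 :]] == aa
    )
    return preserved / 3.0


@dataclass
class SiteClassification:
    """Per-position site classes for one in-frame coding sequence."""

    mode: Mode
    classes: list[str] = field(default_factory=list)  # hard modes
    weights: list[float] = field(default_factory=list)  # fractional mode

    @property
    def n_syn(self) -> int:
        return sum(1 for c in self.classes if c == SYN_SITE)

    @property
    def n_nonsyn(self) -> int:
        return sum(1 for c in self.classes if c == NONSYN_SITE)

    @property
    def syn_sites(self) -> float:
        """Total synonymous sites (integer in hard modes, NG86 sum otherwise)."""
        if self.mode == "fractional":
            return sum(self.weights)
        return float(self.n_syn)


def classify_cds_sites(
    cds_sequence: str,
    mode: Mode = "fourfold",
    code: GeneticCode = STANDARD_CODE,
    strict: bool = True,
) -> SiteClassification:
    """Partition every position of an in-frame CDS into site classes.

    fourfold  — SYN_SITE iff the position is 4-fold degenerate;
    any_syn   — SYN_SITE iff at least one substitution is synonymous (>= 2-fold);
    fractional — per-position synonymous weight in [0, 1], NG86 style.

    Positions of a terminal stop codon and of codons containing ambiguous
    bases are counted NONSYN_SITE (weight 0) so that class totals always sum
    to the annotated CDS length.
    """
    seq = cds_sequence.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    result = SiteClassification(mode=mode)
    n_codons = len(seq) // 3
    for ci in range(n_codons):
        codon = seq[3 * ci : 3 * ci + 3]
        ambiguous = any(b not in BASES for b in codon)
        is_stop = not ambiguous and code.is_stop(codon)
        if is_stop and ci < n_codons - 1 and strict:
            raise ValueError(f"internal stop codon {codon} at codon {ci}")
        if ambiguous:
            log.warning("codon %r contains ambiguous bases; counted nonsynonymous", codon)
        for pos in range(3):
            if ambiguous or is_stop:
                result.classes.append(NONSYN_SITE)
                result.weights.append(0.0)
                continue
            frac = _synonymous_fraction(codon, pos, code)
            result.weights.append(frac)
            if mode == "fourfold":
                cls = SYN_SITE if frac == 1.0 else NONSYN_SITE
            else:  # any_syn and fractional both record the lax hard class
                cls = SYN_SITE if frac > 0.0 else NONSYN_SITE
            result.classes.append(cls)
    return result


def translate(cds_sequence: str, code: GeneticCode = STANDARD_CODE, strict: bool = True) -> str:
    """Translate an in-frame CDS; a trailing stop appears as ``*``."""
    seq = cds_sequence.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    aas = []
    n_codons = len(seq) // 3
    for ci in range(n_codons):
        codon = seq[3 * ci : 3 * ci + 3]
        aa = code.codon_to_aa.get(codon, "X")
        if aa == "*" and ci < n_codons - 1 and strict:
            raise ValueError(f"internal stop codon at codon {ci}")
        aas.append(aa)
    return "".join(aas)
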