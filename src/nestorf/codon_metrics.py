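"""Codon counting and relative synonymous codon usage (RSCU).

RSCU expresses how far a codon's use departs from uniform use within its
synonym family: ``RSCU_c = n_c * |F(c)| / sum_{c' in F(c)} n_{c'}``.  A
value of 1 means no bias; family values sum to the family size whenever
the family was observed at all.

Synonym families default to the standard code (table 1) for *all*
vectors, including mitochondrial reference tables, so that gene and
reference vectors are commensurable on a common 59-codon basis (the 61
sense codons minus the single-codon families ATG and TGG).  A table-2
basis is available for sensitivity analysis; its families differ (ATA
joins Met, TGA joins Trp, AGA/AGG leave Arg).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np

from .genetic_code import GeneticCode, get_code, _check_alphabet
from .io_formats import CodonUsageTable

__all__ = [
    "CodonCounts",
    "RscuVector",
    "codon_counts",
    "synonym_families",
    "default_included",
    "rscu",
]


@dataclass(frozen=True)
class CodonCounts:
    counts: Mapping[str, int]
    source_id: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class RscuVector:
    """RSCU values over an ordered, included codon set."""

    values: Mapping[str, float]
    code_basis: int
    included: Tuple[str, ...]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[c] for c in self.included], dtype=float)


def codon_counts(seq: str, source_id: str = "") -> CodonCounts:
    """Tally the codons of an in-frame sequence (length must be 3n)."""
    seq = _check_alphabet(seq)
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not divisible by 3")
    tally = Counter(seq[i : i + 3] for i in range(0, len(seq), 3))
    return CodonCounts(counts=dict(tally), source_id=source_id)


@lru_cache(maxsize=None)
def synonym_families(code_basis: int = 1) -> Dict[str, Tuple[str, ...]]:
    """Amino acid -> sorted tuple of its sense codons under the basis code."""
    code = get_code(code_basis)
    fams: Dict[str, list] = {}
    for codon, aa in code.codon_to_aa.items():
        if aa == "*":
            continue
        fams.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cs)) for aa, cs in fams.items()}


@lru_cache(maxsize=None)
def default_included(code_basis: int = 1) -> Tuple[str, ...]:
    """Sense codons excluding single-codon families, sorted."""
    fams = synonym_families(code_basis)
    codons = [c for fam in fams.values() if len(fam) > 1 for c in fam]
    return tuple(sorted(codons))


def _as_count_map(counts) -> Mapping[str, float]:
    if isinstance(counts, CodonCounts):
        return counts.counts
    if isinstance(counts, CodonUsageTable):
        return counts.codon_counts
    if isinstance(counts, Mapping):
        return counts
    raise TypeError(f"cannot read codon counts from {type(counts).__name__}")


def rscu(
    counts,
    code_basis: int = 1,
    included: Optional[Iterable[str]] = None,
) -> RscuVector:
    """RSCU vector of a gene's codon counts or a usage table.

    Families with zero total count receive the neutral value 1 for all
    members rather than NaN (short genes can miss amino acids entirely).
    """
    cmap = _as_count_map(counts)
    fams = synonym_families(code_basis)
    if included is None:
        inc = default_included(code_basis)
    else:
        inc = tuple(sorted(included))
        sense = {c for fam in fams.values() for c in fam}
        bad = [c for c in inc if c not in sense]
        if bad:
            raise ValueError(
                f"included codons not sense under table {code_basis}: {bad}"
            )
    values: Dict[str, float] = {}
    for fam in fams.values():
        members = [c for c in fam if c in inc]
        if not members:
            continue
        total = sum(cmap.get(c, 0) for c in fam)
        if total <= 0:
            for c in members:
                values[c] = 1.0
            continue
        size = len(fam)
        for c in members:
            values[c] = cmap.get(c, 0) * size / total
    return RscuVector(values=values, code_basis=code_basis, included=inc)
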