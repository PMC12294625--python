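"""Dual genetic codes and frame-aware translation.

Mammalian cells run two translation systems side by side: cytosolic
ribosomes read the standard genetic code (NCBI table 1), mitochondrial
ribosomes read the vertebrate mitochondrial code (NCBI table 2).  The two
codes disagree at exactly four codons: TGA (stop vs. Trp), AGA/AGG
(Arg vs. stop) and ATA (Ile vs. Met, also a mitochondrial start).  A
nucleotide stretch that terminates early under one code can therefore
remain an open reading frame under the other — the property the rest of
this package is built around.

Coordinates are 1-based and inclusive throughout.  Frame ``k`` (1, 2 or 3)
places codons starting at nucleotide ``k`` of the supplied sequence, with
frame 1 being the annotated host CDS frame.  The internal alphabet is DNA;
any ``U`` in input is normalised to ``T`` on entry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Tuple

from Bio.Data import CodonTable

__all__ = [
    "GeneticCode",
    "InvalidAlphabetError",
    "STANDARD_CODE",
    "MITO_CODE",
    "get_code",
    "normalize_seq",
    "translate",
    "first_stop",
    "is_start",
]

_VALID = re.compile(r"[ACGT]*\Z")
_OFFENDER = re.compile(r"[^ACGT]")


class InvalidAlphabetError(ValueError):
    """Raised when a sequence contains a base outside A/C/G/T.

    ``position`` is the 1-based index of the first offending character.
    """

    def __init__(self, position: int, char: str):
        self.position = position
        self.char = char
        super().__init__(
            f"invalid base {char!r} at position {position} (expected A/C/G/T)"
        )


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA ``U`` to DNA ``T``."""
    return seq.upper().replace("U", "T")


def _check_alphabet(seq: str) -> str:
    seq = normalize_seq(seq)
    if not _VALID.match(seq):
        m = _OFFENDER.search(seq)
        raise InvalidAlphabetError(m.start() + 1, m.group())
    return seq


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table with its start and stop codon sets.

    ``codon_to_aa`` maps all 64 DNA trinucleotides to a one-letter amino
    acid, with ``'*'`` for stop codons; ``stop_codons`` is exactly the set
    of codons mapping to ``'*'``.
    """

    table_id: int
    codon_to_aa: dict
    start_codons: frozenset
    stop_codons: frozenset

    @classmethod
    def from_ncbi(cls, table_id: int) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(t.forward_table)
        for codon in t.stop_codons:
            mapping[codon] = "*"
        if len(mapping) != 64:  # pragma: no cover - NCBI tables are complete
            raise ValueError(f"table {table_id} does not define all 64 codons")
        return cls(
            table_id=table_id,
            codon_to_aa=mapping,
            start_codons=frozenset(t.start_codons),
            stop_codons=frozenset(t.stop_codons),
        )


STANDARD_CODE = GeneticCode.from_ncbi(1)
MITO_CODE = GeneticCode.from_ncbi(2)


@lru_cache(maxsize=None)
def get_code(table_id: int) -> GeneticCode:
    """Return the :class:`GeneticCode` for NCBI table 1 or 2."""
    if table_id not in (1, 2):
        raise ValueError(f"unsupported translation table {table_id}; use 1 or 2")
    return STANDARD_CODE if table_id == 1 else MITO_CODE


def translate(seq: str, code: GeneticCode, frame: int = 1) -> str:
    """Translate ``seq`` in the given frame, writing ``'*'`` for stops.

    Translation runs through internal stop codons (full-frame translation);
    a trailing partial codon is ignored.  Output length is
    ``floor((len(seq) - frame + 1) / 3)``.
    """
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be 1, 2 or 3, got {frame}")
    seq = _check_alphabet(seq)
    aa = code.codon_to_aa
    sub = seq[frame - 1 :]
    return "".join(aa[sub[i : i + 3]] for i in range(0, len(sub) - len(sub) % 3, 3))


def first_stop(
    seq: str, code: GeneticCode, frame: int = 1
) -> Optional[Tuple[int, int]]:
    """1-based inclusive nucleotide span of the first in-frame stop codon.

    Returns ``None`` when the frame contains no stop codon.
    """
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be 1, 2 or 3, got {frame}")
    seq = _check_alphabet(seq)
    stops = code.stop_codons
    for i in range(frame - 1, len(seq) - 2, 3):
        if seq[i : i + 3] in stops:
            return (i + 1, i + 3)
    return None


def is_start(codon: str, code: GeneticCode) -> bool:
    """True iff ``codon`` is an initiation codon under ``code``."""
    codon = _check_alphabet(codon)
    if len(codon) != 3:
        raise ValueError(f"expected a trinucleotide, got {codon!r}")
    return codon in code.start_codons
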