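"""Readers and writers for the formats the pipeline touches.

Three kinds of file move through the analysis: multi-record FASTA of CDS
nucleotide sequences, per-species codon-usage tables for nuclear or
mitochondrial gene sets, and tabular reports.  Codon-usage tables come in
three dialects:

``canonical_tsv``
    The package's interchange format: ``#``-prefixed metadata lines
    (``species``, ``gene_set``, ``n_cds``, ``avg_cds_len_codons``) followed
    by a header row and one ``codon<TAB>count`` row per codon.
``cocoputs_tsv``
    A wide CoCoPUTs-style export: a header row whose columns include the
    64 codons plus metadata columns (``Species``, ``# CDS``, ``# Codons``),
    and a single data row of counts.  The reader is written against the
    fixture documented in the test suite; exact column layouts of live
    database exports vary.
``kazusa_text``
    The classic Kazusa codon-usage block, fields like
    ``UUU 17.6( 714298)``; counts are taken from the parenthesised totals.
    This dialect carries no CDS metadata.

Reference tables are screened with :func:`table_is_robust` before being
used for adaptation statistics: a table qualifies when it derives from at
least 30 coding sequences whose average length exceeds 100 codons.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import normalize_seq

__all__ = [
    "CdsRecord",
    "CodonUsageTable",
    "MissingTableMetadata",
    "ALL_CODONS",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "read_codon_table",
    "write_codon_table",
    "table_is_robust",
]

log = logging.getLogger(__name__)

_BASES = "TCAG"
#: The 64 DNA codons in TCAG order (the order codon-usage tables print).
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)
_CODON_SET = frozenset(ALL_CODONS)
_ACGT = re.compile(r"[ACGT]+\Z")


@dataclass
class CdsRecord:
    """One coding sequence with its provenance labels."""

    id: str
    species: str = ""
    group: str = ""
    seq: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CodonUsageTable:
    """64 codon counts plus the metadata the robustness filter needs.

    ``n_cds`` and ``avg_cds_len_codons`` may be ``None`` when the source
    dialect does not carry them (e.g. Kazusa text blocks); robustness is
    then indeterminate rather than silently true.
    """

    codon_counts: Dict[str, float]
    gene_set: str = ""  # "nuclear" or "mitochondrial"
    n_cds: Optional[int] = None
    avg_cds_len_codons: Optional[float] = None
    species: str = ""

    def __post_init__(self):
        counts = {c: 0.0 for c in ALL_CODONS}
        for codon, n in self.codon_counts.items():
            codon = normalize_seq(codon)
            if codon not in _CODON_SET:
                raise ValueError(f"unknown codon token {codon!r}")
            if n < 0:
                raise ValueError(f"negative count for codon {codon}")
            counts[codon] = float(n)
        if not any(counts.values()):
            raise ValueError("codon usage table has no positive counts")
        self.codon_counts = counts

    @property
    def total(self) -> float:
        return sum(self.codon_counts.values())


class MissingTableMetadata(ValueError):
    """Robustness cannot be decided because CDS metadata is absent."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_metadata(path) -> Dict[str, dict]:
    """Read a sidecar TSV with columns ``id``, ``species``, ``group``."""
    meta: Dict[str, dict] = {}
    lines = Path(path).read_text().splitlines()
    if not lines:
        return meta
    header = lines[0].rstrip("\n").split("\t")
    for line in lines[1:]:
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        meta[row["id"]] = row
    return meta


def read_fasta(path, *, clean: bool = True, metadata: Optional[Dict[str, dict]] = None
               ) -> List[CdsRecord]:
    """Read CDS records, uppercasing and converting U to T.

    Headers are parsed as ``accession [whitespace] free text``.  Species and
    group come from ``metadata`` (a mapping as returned by
    :func:`read_metadata`) when supplied, else species falls back to the
    first two description tokens.  With ``clean=True`` records containing
    any non-A/C/G/T base are dropped and the number of removals logged,
    matching the ambiguity filter applied to the study datasets.
    """
    records: List[CdsRecord] = []
    seen: Dict[str, int] = {}
    dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_seq(str(rec.seq))
        acc = rec.id
        seen[acc] = seen.get(acc, 0) + 1
        species = group = ""
        if metadata and acc in metadata:
            species = metadata[acc].get("species", "")
            group = metadata[acc].get("group", "")
        else:
            tokens = rec.description.split()
            if len(tokens) >= 3:
                species = " ".join(tokens[1:3])
        if clean and not _ACGT.match(seq):
            dropped += 1
            continue
        if not seq:
            dropped += 1
            continue
        records.append(CdsRecord(id=acc, species=species, group=group, seq=seq))
    if not seen:
        raise ValueError(f"no FASTA records found in {path}")
    dups = sorted(acc for acc, n in seen.items() if n > 1)
    if dups:
        raise ValueError(f"duplicate record ids in {path}: {', '.join(dups)}")
    if dropped:
        log.info("read_fasta: dropped %d record(s) with ambiguous/empty sequence", dropped)
    return records


def write_fasta(records: Iterable[CdsRecord], path, *, width: int = 70) -> None:
    seqs = [
        SeqRecord(Seq(r.seq), id=r.id, description=" ".join(
            t for t in (r.species, r.group) if t))
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# Codon usage tables
# ---------------------------------------------------------------------------

_KAZUSA_FIELD = re.compile(r"([ACGUT]{3})\s+[\d.]+\s*\(\s*(\d+)\s*\)")


def _read_canonical(path) -> CodonUsageTable:
    meta: Dict[str, str] = {}
    counts: Dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line:
                key, val = line.lstrip("#").split(":", 1)
                meta[key.strip()] = val.strip()
            continue
        parts = line.split("\t")
        if parts[0].lower() == "codon":
            continue
        counts[normalize_seq(parts[0])] = float(parts[1])
    n_cds = int(meta["n_cds"]) if "n_cds" in meta else None
    avg = float(meta["avg_cds_len_codons"]) if "avg_cds_len_codons" in meta else None
    table = CodonUsageTable(
        codon_counts=counts,
        gene_set=meta.get("gene_set", ""),
        n_cds=n_cds,
        avg_cds_len_codons=avg,
        species=meta.get("species", ""),
    )
    return table, len(counts)


def _read_cocoputs(path) -> CodonUsageTable:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if len(lines) < 2:
        raise ValueError(f"CoCoPUTs-style table {path} needs a header and a data row")
    header = lines[0].split("\t")
    row = dict(zip(header, lines[1].split("\t")))
    counts = {}
    for col, val in row.items():
        token = normalize_seq(col.strip())
        if len(token) == 3 and token in _CODON_SET:
            counts[token] = float(val)
    n_cds = None
    n_codons = None
    for col, val in row.items():
        key = col.strip().lower()
        if key in ("# cds", "#cds", "n_cds", "cds"):
            n_cds = int(float(val))
        elif key in ("# codons", "#codons", "n_codons", "codons"):
            n_codons = float(val)
    avg = (n_codons / n_cds) if (n_cds and n_codons is not None) else None
    table = CodonUsageTable(
        codon_counts=counts,
        gene_set=row.get("GeneSet", row.get("gene_set", "")),
        n_cds=n_cds,
        avg_cds_len_codons=avg,
        species=row.get("Species", row.get("species", "")),
    )
    return table, len(counts)


def _read_kazusa(path) -> CodonUsageTable:
    text = Path(path).read_text()
    counts: Dict[str, float] = {}
    for codon, n in _KAZUSA_FIELD.findall(text):
        counts[normalize_seq(codon)] = float(n)
    if not counts:
        raise ValueError(f"no Kazusa-style codon fields found in {path}")
    return CodonUsageTable(codon_counts=counts), len(counts)


_DIALECTS = {
    "canonical_tsv": _read_canonical,
    "cocoputs_tsv": _read_cocoputs,
    "kazusa_text": _read_kazusa,
}


def read_codon_table(path, dialect: str = "canonical_tsv") -> CodonUsageTable:
    """Read a codon usage table in one of the supported dialects.

    Codons absent from the file are zero-filled with a warning; RNA codons
    are normalised to DNA.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    table, n_present = _DIALECTS[dialect](path)
    if n_present < 64:
        log.warning(
            "codon table %s: %d codon(s) absent from file, filled with 0",
            path, 64 - n_present,
        )
    return table


def write_codon_table(table: CodonUsageTable, path) -> None:
    """Write a table in the canonical TSV interchange format."""
    lines = [
        f"# species: {table.species}",
        f"# gene_set: {table.gene_set}",
    ]
    if table.n_cds is not None:
        lines.append(f"# n_cds: {table.n_cds}")
    if table.avg_cds_len_codons is not None:
        lines.append(f"# avg_cds_len_codons: {table.avg_cds_len_codons}")
    lines.append("codon\tcount")
    for codon in ALL_CODONS:
        count = table.codon_counts[codon]
        lines.append(f"{codon}\t{count:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def table_is_robust(
    t: CodonUsageTable, min_cds: int = 30, min_avg_len: float = 100.0
) -> bool:
    """Apply the reference-table depth filter.

    True iff the table derives from at least ``min_cds`` coding sequences
    AND the average CDS length strictly exceeds ``min_avg_len`` codons.
    Raises :class:`MissingTableMetadata` when the metadata needed to decide
    is absent, so an unknown table is never silently accepted.
    """
    if t.n_cds is None or t.avg_cds_len_codons is None:
        raise MissingTableMetadata(
            f"table for {t.species or '<unknown>'} lacks n_cds/avg length metadata"
        )
    return t.n_cds >= min_cds and t.avg_cds_len_codons > min_avg_len
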