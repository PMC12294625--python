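"""Nested-ORF screening inside a host CDS.

A nested alternative ORF is an ATG-initiated reading frame embedded in the
+2 or +3 frame of a host coding sequence and read under a (possibly
different) genetic code.  The screen applies four criteria: translation
under the requested code, scanning restricted to frames +2 and +3, a
minimum length (default 150 codons, stop-exclusive, so the threshold is a
protein length), and selection of the longest candidate per frame.

Within each stop-bounded segment of a frame the 5'-most ATG defines the
(maximal) ORF; internal ATGs are not reported separately.  ORFs lacking an
in-frame stop before the end of the CDS are excluded unless explicitly
retained as incomplete — the input is a lone CDS, so run-off ORFs cannot
be verified.

The module also analyses the host's own frame: :func:`ptc_scan` locates
the first premature termination codon the standard code would impose on a
mitochondrially encoded message, and asks whether any downstream in-frame
ATG could rescue a non-trivial product.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .genetic_code import GeneticCode, STANDARD_CODE, translate, _check_alphabet
from .io_formats import CdsRecord

__all__ = [
    "NestedOrf",
    "PtcReport",
    "scan_nested_orfs",
    "longest_per_frame",
    "dedupe_orfs",
    "ptc_scan",
]


@dataclass(frozen=True)
class NestedOrf:
    """A candidate nested ORF, coordinates 1-based inclusive on the host.

    ``length_codons`` excludes the stop codon and equals ``len(aa_seq)``,
    i.e. the length of the encoded protein including the initiator Met.
    """

    host_id: str
    frame: int
    start_nt: int
    end_nt: int
    length_codons: int
    nt_seq: str
    aa_seq: str
    complete: bool = True


@dataclass(frozen=True)
class PtcReport:
    """Host-frame premature-stop analysis under the standard code."""

    host_id: str
    first_stop_span: Optional[Tuple[int, int]]
    first_stop_codon: Optional[str]
    downstream_long_orf: bool
    longest_downstream_orf_codons: int


def scan_nested_orfs(
    rec: CdsRecord,
    code: GeneticCode = STANDARD_CODE,
    frames: Iterable[int] = (2, 3),
    min_codons: int = 150,
    *,
    include_incomplete: bool = False,
) -> List[NestedOrf]:
    """All maximal ATG-initiated ORFs of at least ``min_codons`` codons.

    Only ATG is accepted as initiator, even when scanning under the
    mitochondrial code (the downstream Kozak analysis presumes AUG).
    Results are ordered by frame then start position.
    """
    if min_codons < 1:
        raise ValueError(f"min_codons must be >= 1, got {min_codons}")
    frames = sorted(set(frames))
    if any(f not in (2, 3) for f in frames):
        raise ValueError(f"nested-ORF frames must be within {{2, 3}}, got {frames}")
    seq = _check_alphabet(rec.seq)
    stops = code.stop_codons
    out: List[NestedOrf] = []
    for frame in frames:
        open_start: Optional[int] = None  # 0-based nt index of segment's first ATG
        last_full = None
        for i in range(frame - 1, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            last_full = i
            if codon in stops:
                if open_start is not None:
                    out.extend(
                        _make_orf(rec.id, seq, frame, open_start, i, code,
                                  min_codons, True)
                    )
                open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = i
        if include_incomplete and open_start is not None and last_full is not None:
            out.extend(
                _make_orf(rec.id, seq, frame, open_start, last_full + 3, code,
                          min_codons, False)
            )
    return out


def _make_orf(host_id, seq, frame, start0, stop0, code, min_codons, complete):
    """Build a NestedOrf from 0-based start and stop-codon (or end) index."""
    length = (stop0 - start0) // 3
    if length < min_codons:
        return []
    end0 = stop0 + 3 if complete else stop0
    nt = seq[start0:end0]
    aa = translate(nt[: 3 * length], code, 1)
    return [
        NestedOrf(
            host_id=host_id,
            frame=frame,
            start_nt=start0 + 1,
            end_nt=end0,
            length_codons=length,
            nt_seq=nt,
            aa_seq=aa,
            complete=complete,
        )
    ]


def longest_per_frame(orfs: Iterable[NestedOrf]) -> List[NestedOrf]:
    """The single longest ORF per frame; ties go to the smallest start."""
    orfs = list(orfs)
    hosts = {o.host_id for o in orfs}
    if len(hosts) > 1:
        raise ValueError(f"orfs span multiple hosts: {sorted(hosts)}")
    best: Dict[int, NestedOrf] = {}
    for orf in orfs:
        cur = best.get(orf.frame)
        if (
            cur is None
            or orf.length_codons > cur.length_codons
            or (orf.length_codons == cur.length_codons and orf.start_nt < cur.start_nt)
        ):
            best[orf.frame] = orf
    return [best[f] for f in sorted(best)]


def dedupe_orfs(
    orfs: Iterable[NestedOrf],
) -> Tuple[List[NestedOrf], Dict[str, List[str]]]:
    """Consolidate ORFs with identical nucleotide sequences.

    Returns the unique representatives (lexicographically smallest host id
    per identity group, in input order of first appearance) and a map from
    representative host id to the sorted host ids it stands for.
    """
    groups: Dict[str, List[NestedOrf]] = defaultdict(list)
    order: List[str] = []
    for orf in orfs:
        if orf.nt_seq not in groups:
            order.append(orf.nt_seq)
        groups[orf.nt_seq].append(orf)
    unique: List[NestedOrf] = []
    mapping: Dict[str, List[str]] = {}
    for nt in order:
        members = sorted(groups[nt], key=lambda o: o.host_id)
        rep = members[0]
        unique.append(rep)
        mapping[rep.host_id] = [m.host_id for m in members]
    return unique, mapping


def ptc_scan(
    rec: CdsRecord,
    min_downstream_codons: int = 50,
    code: GeneticCode = STANDARD_CODE,
) -> PtcReport:
    """Locate the first frame-1 stop and probe for downstream rescue ORFs.

    After the first premature stop (if any), frame-1 ATGs strictly
    downstream of its span are examined; the longest ATG-initiated ORF
    (protein codons including the Met, stop-terminated or running to the
    sequence end) is reported.  ``downstream_long_orf`` is true when that
    length strictly exceeds ``min_downstream_codons``.
    """
    seq = _check_alphabet(rec.seq)
    stops = code.stop_codons
    span = None
    stop_codon = None
    for i in range(0, len(seq) - 2, 3):
        if seq[i : i + 3] in stops:
            span = (i + 1, i + 3)
            stop_codon = seq[i : i + 3]
            break
    scan_from = span[1] if span is not None else 0  # 0-based index of next codon
    longest = 0
    open_start: Optional[int] = None
    for i in range(scan_from, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in stops:
            if open_start is not None:
                longest = max(longest, (i - open_start) // 3)
            open_start = None
        elif codon == "ATG" and open_start is None:
            open_start = i
    if open_start is not None:
        n_full = (len(seq) - open_start) // 3
        longest = max(longest, n_full)
    return PtcReport(
        host_id=rec.id,
        first_stop_span=span,
        first_stop_codon=stop_codon,
        downstream_long_orf=longest > min_downstream_codons,
        longest_downstream_orf_codons=longest,
    )
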