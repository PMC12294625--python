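"""Codon-usage cosine similarity, protein pairwise identity, and the
nonparametric tests used for the headline comparisons.

Codon usage of a gene and of a reference gene set are each summarised as
RSCU vectors on a common included-codon basis; their cosine similarity
``R(A,B)`` lies in [-1, 1] (in [0, 1] for the non-negative RSCU case) and
is 1 exactly for proportional vectors.  The derived index
``D(A,B) = (1 - R)/2`` is reported for reference only — ``R`` itself is
the similarity measure.

Paired species-level comparisons (e.g. a gene's similarity to the
mitochondrial versus the nuclear reference set) use the one-tailed
Wilcoxon signed-rank test: exact null enumeration when the effective
sample is small and untied, a tie- and continuity-corrected normal
approximation otherwise.  Monotone association between two similarity
profiles uses Spearman's rank correlation.

Pairwise identity/similarity of pre-aligned protein sequences follows the
column-scan convention of common sequence-manipulation toolkits, with
similar-residue groups {GAVLI, FYW, CM, ST, KRH, DENQ, P}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .codon_metrics import RscuVector, codon_counts, rscu
from .io_formats import (
    CdsRecord,
    CodonUsageTable,
    MissingTableMetadata,
    table_is_robust,
)
from .orf_screen import NestedOrf

__all__ = [
    "SimilarityRecord",
    "TestResult",
    "DEFAULT_SIMILAR_GROUPS",
    "cosine_similarity",
    "dissimilarity_index",
    "build_similarity_table",
    "run_similarity_tests",
    "wilcoxon_signed_rank",
    "spearman",
    "pairwise_identity_similarity",
]

log = logging.getLogger(__name__)

DEFAULT_SIMILAR_GROUPS: Tuple[str, ...] = ("GAVLI", "FYW", "CM", "ST", "KRH", "DENQ", "P")


@dataclass(frozen=True)
class SimilarityRecord:
    """Four RSCU cosine similarities for one species."""

    species: str
    sim_ncytb_nuclear: float
    sim_ncytb_mito: float
    sim_cytb_nuclear: float
    sim_cytb_mito: float


@dataclass(frozen=True)
class TestResult:
    comparison: str
    n: int
    statistic: float
    p_value: float
    alternative: str
    method: str  # "exact" or "normal_approx"


def cosine_similarity(a: RscuVector, b: RscuVector) -> float:
    """R(A,B) = A.B / (|A| |B|) over a shared included-codon ordering."""
    if a.included != b.included:
        raise ValueError("RSCU vectors use different included codon sets")
    va, vb = a.as_array(), b.as_array()
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(va @ vb / (na * nb))


def dissimilarity_index(a: RscuVector, b: RscuVector) -> float:
    """D(A,B) = (1 - R(A,B)) / 2, reported for reference only."""
    return (1.0 - cosine_similarity(a, b)) / 2.0


def build_similarity_table(
    orfs: Iterable[NestedOrf],
    hosts: Iterable[CdsRecord],
    nuclear_tables: Mapping[str, CodonUsageTable],
    mito_tables: Mapping[str, CodonUsageTable],
    *,
    require_robust_nuclear: bool = True,
    code_basis: int = 1,
) -> Tuple[List[SimilarityRecord], List[str]]:
    """Per-species cosine similarities of nested ORF and host vs. both
    reference sets.

    Species whose nuclear table is missing or fails the robustness filter
    (or whose mitochondrial table is missing) are skipped and returned in
    the second element.
    """
    host_by_id = {h.id: h for h in hosts}
    records: List[SimilarityRecord] = []
    skipped: List[str] = []
    for orf in orfs:
        host = host_by_id.get(orf.host_id)
        if host is None:
            skipped.append(f"{orf.host_id}: host sequence not supplied")
            continue
        species = host.species or host.id
        nuc = nuclear_tables.get(species)
        mito = mito_tables.get(species)
        if nuc is None or mito is None:
            skipped.append(f"{species}: reference table(s) missing")
            continue
        if require_robust_nuclear:
            try:
                robust = table_is_robust(nuc)
            except MissingTableMetadata:
                robust = False
            if not robust:
                skipped.append(f"{species}: nuclear table not robust")
                continue
        v_orf = rscu(codon_counts(orf.nt_seq), code_basis)
        v_host = rscu(codon_counts(host.seq), code_basis)
        v_nuc = rscu(nuc, code_basis)
        v_mito = rscu(mito, code_basis)
        records.append(
            SimilarityRecord(
                species=species,
                sim_ncytb_nuclear=cosine_similarity(v_orf, v_nuc),
                sim_ncytb_mito=cosine_similarity(v_orf, v_mito),
                sim_cytb_nuclear=cosine_similarity(v_host, v_nuc),
                sim_cytb_mito=cosine_similarity(v_host, v_mito),
            )
        )
    for msg in skipped:
        log.info("similarity: skipped %s", msg)
    return records, skipped


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "greater",
) -> TestResult:
    """Paired Wilcoxon signed-rank test for the stated direction.

    Zero differences are dropped (signed-rank convention).  The exact null
    is enumerated when the effective n is at most 25 with no tied absolute
    differences; otherwise a normal approximation with tie and continuity
    corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length non-empty 1-d sequences")
    d = x - y
    d = d[d != 0]
    n_eff = len(d)
    if n_eff == 0:
        raise ValueError("all paired differences are zero; test undefined")
    absd = np.abs(d)
    exact = n_eff <= 25 and len(np.unique(absd)) == n_eff
    method = "exact" if exact else "approx"
    res = stats.wilcoxon(
        d,
        alternative=alternative,
        method=method,
        correction=not exact,
    )
    return TestResult(
        comparison="",
        n=n_eff,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        method="exact" if exact else "normal_approx",
    )


#: The four species-paired comparisons of the similarity analysis, as
#: (label, attribute of the larger-under-H1 column, attribute of the other).
PAIRED_COMPARISONS: Tuple[Tuple[str, str, str], ...] = (
    ("cytb_mito_vs_cytb_nuclear", "sim_cytb_mito", "sim_cytb_nuclear"),
    ("cytb_nuclear_vs_ncytb_nuclear", "sim_cytb_nuclear", "sim_ncytb_nuclear"),
    ("cytb_mito_vs_ncytb_mito", "sim_cytb_mito", "sim_ncytb_mito"),
    ("ncytb_nuclear_vs_ncytb_mito", "sim_ncytb_nuclear", "sim_ncytb_mito"),
)


def run_similarity_tests(
    records: Sequence[SimilarityRecord],
) -> List[TestResult]:
    """One-tailed Wilcoxon tests for the four paired comparisons."""
    out: List[TestResult] = []
    for label, hi, lo in PAIRED_COMPARISONS:
        x = [getattr(r, hi) for r in records]
        y = [getattr(r, lo) for r in records]
        res = wilcoxon_signed_rank(x, y, alternative="greater")
        out.append(
            TestResult(
                comparison=label,
                n=res.n,
                statistic=res.statistic,
                p_value=res.p_value,
                alternative=res.alternative,
                method=res.method,
            )
        )
    return out


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman's rho with its t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def pairwise_identity_similarity(
    aligned_a: str,
    aligned_b: str,
    similar_groups: Iterable[str] = DEFAULT_SIMILAR_GROUPS,
) -> Tuple[float, float]:
    """Percent identity and similarity of two pre-aligned protein strings.

    Columns where both sequences are gapped are ignored; the denominator
    is every column with at least one residue.  Similarity counts columns
    whose residues are identical or share a similar-residue group.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    group_of: Dict[str, int] = {}
    for gi, grp in enumerate(similar_groups):
        for aa in grp:
            group_of[aa.upper()] = gi
    n_cols = 0
    n_ident = 0
    n_sim = 0
    for a, b in zip(aligned_a.upper(), aligned_b.upper()):
        a_gap = a in "-."
        b_gap = b in "-."
        if a_gap and b_gap:
            continue
        n_cols += 1
        if a_gap or b_gap:
            continue
        if a == b:
            n_ident += 1
            n_sim += 1
        elif group_of.get(a) is not None and group_of.get(a) == group_of.get(b):
            n_sim += 1
    if n_cols == 0:
        raise ValueError("alignment has no residue-bearing columns")
    return 100.0 * n_ident / n_cols, 100.0 * n_sim / n_cols
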