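"""Codon adaptation (CAI/eCAI) and deoptimization (RCDI/eRCDI) statistics.

CAI is the geometric mean, over a gene's codons, of relative-adaptiveness
weights ``w_c = n_c / max_{c' in F(c)} n_{c'}`` derived from a reference
usage table; it is 1 when every codon is its family's most frequent
reference codon.  Stop codons and the single-codon families ATG (Met) and
TGG (Trp) are excluded — their weights are 1 by construction and would
only dilute the index.  Zero-count reference codons receive a 0.5
pseudocount before normalisation so weights stay positive.

A raw CAI is uninterpretable without a null: a gene can score high purely
because of its amino-acid and base composition.  The expected CAI (eCAI)
therefore simulates ``n_random`` mock genes that preserve the query's
amino-acid composition exactly and draw each codon from its synonym
family with probability proportional to the product of the query's global
mononucleotide frequencies over the codon's three positions.  The mean
mock CAI is the expectation; the upper one-sided 95% limit is
``mean + 1.6449 * sd`` (normal method) or the empirical 95th percentile,
and the lower limit is ``2 * expected - upper``.  A CAI above the upper
limit indicates positive adaptation, below the lower limit negative
adaptation, and anything inside the band is indistinguishable from a
composition-matched random gene.

RCDI compares within-family codon frequencies directly:
``RCDI = (1/N) * sum_c n_c * f_query(c) / f_ref(c)`` over the gene's
sense codons, where ``f`` is the codon's relative frequency within its
amino-acid family.  RCDI is 1 exactly when the gene reproduces the
reference frequencies and grows with deoptimization (Cauchy-Schwarz gives
RCDI >= 1).  eRCDI builds the analogous composition-matched null; an RCDI
inside the band means the gene's usage is explained by its amino-acid and
base composition alone.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple, Union

import numpy as np
from scipy import stats

from .codon_metrics import codon_counts, synonym_families
from .genetic_code import get_code, translate, _check_alphabet
from .io_formats import CodonUsageTable

__all__ = [
    "RelativeAdaptiveness",
    "AdaptationResult",
    "relative_adaptiveness",
    "cai",
    "generate_mock",
    "ecai",
    "rcdi",
    "ercdi",
]

PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class RelativeAdaptiveness:
    """Per-codon weights in (0, 1]; the family-best codon has weight 1."""

    w: Mapping[str, float]
    reference_id: str
    excluded: frozenset
    code_basis: int = 1


@dataclass(frozen=True)
class AdaptationResult:
    """A CAI or RCDI value against its Monte-Carlo null."""

    metric: str  # "CAI" or "RCDI"
    statistic: float
    expected: float
    upper: float
    lower: float
    verdict: str
    n_random: int
    seed: Optional[int]
    method: str = "normal"


def _smoothed_family_counts(
    ref: CodonUsageTable, fam: Tuple[str, ...]
) -> Dict[str, float]:
    return {c: ref.codon_counts.get(c, 0.0) or PSEUDOCOUNT for c in fam}


def relative_adaptiveness(
    ref: CodonUsageTable, code_basis: int = 1
) -> RelativeAdaptiveness:
    """Build CAI weights from a reference usage table."""
    if ref.total <= 0:
        raise ValueError("reference table has no counts")
    fams = synonym_families(code_basis)
    code = get_code(code_basis)
    w: Dict[str, float] = {}
    excluded = set(code.stop_codons)
    for aa, fam in fams.items():
        if len(fam) == 1:
            excluded.add(fam[0])
            continue
        counts = _smoothed_family_counts(ref, fam)
        top = max(counts.values())
        for c in fam:
            w[c] = counts[c] / top
    return RelativeAdaptiveness(
        w=w,
        reference_id=ref.species or "",
        excluded=frozenset(excluded),
        code_basis=code_basis,
    )


def cai(seq: str, ra: RelativeAdaptiveness) -> float:
    """Geometric-mean CAI of an in-frame gene against reference weights."""
    counts = codon_counts(seq).counts
    log_sum = 0.0
    n = 0
    for codon, k in counts.items():
        if codon in ra.excluded or codon not in ra.w:
            continue
        log_sum += k * math.log(ra.w[codon])
        n += k
    if n == 0:
        raise ValueError("sequence contains only excluded codons")
    return math.exp(log_sum / n)


def _base_freqs(seq: str) -> Dict[str, float]:
    counts = Counter(seq)
    total = sum(counts[b] for b in "ACGT")
    return {b: counts[b] / total for b in "ACGT"}


def _family_probs(
    base_freqs: Mapping[str, float], code_basis: int
) -> Dict[str, Tuple[Tuple[str, ...], np.ndarray]]:
    """Per amino acid: (family codons, base-bias sampling probabilities)."""
    fams = synonym_families(code_basis)
    out = {}
    for aa, fam in fams.items():
        wts = np.array(
            [base_freqs[c[0]] * base_freqs[c[1]] * base_freqs[c[2]] for c in fam],
            dtype=float,
        )
        total = wts.sum()
        if total <= 0:
            wts = np.full(len(fam), 1.0 / len(fam))
        else:
            wts = wts / total
        out[aa] = (fam, wts)
    return out


def generate_mock(
    aa_profile: Union[str, Mapping[str, int]],
    base_freqs: Mapping[str, float],
    code_basis: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """One composition-matched mock gene as an in-frame nucleotide string.

    The amino-acid multiset is preserved exactly; each residue's codon is
    drawn from its synonym family with probability proportional to the
    product of ``base_freqs`` over the codon's three positions.
    """
    if rng is None:
        rng = np.random.default_rng()
    if abs(sum(base_freqs[b] for b in "ACGT") - 1.0) > 1e-6:
        raise ValueError("base frequencies must sum to 1")
    profile = Counter(aa_profile)
    fam_probs = _family_probs(base_freqs, code_basis)
    parts = []
    for aa in sorted(profile):
        m = profile[aa]
        if aa not in fam_probs:
            raise ValueError(f"amino acid {aa!r} has no codon under table {code_basis}")
        fam, probs = fam_probs[aa]
        draws = rng.choice(len(fam), size=m, p=probs)
        parts.extend(fam[i] for i in draws)
    return "".join(parts)


def _mock_ensemble_stats(
    seq: str,
    statistic_fn,
    n_random: int,
    code_basis: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Statistic of ``n_random`` composition-matched mocks of ``seq``."""
    aa = translate(seq, get_code(code_basis), 1).replace("*", "")
    freqs = _base_freqs(_check_alphabet(seq))
    vals = np.empty(n_random)
    for i in range(n_random):
        vals[i] = statistic_fn(generate_mock(aa, freqs, code_basis, rng))
    return vals


def _limits(
    vals: np.ndarray, alpha: float, method: str
) -> Tuple[float, float, float]:
    expected = float(vals.mean())
    if method == "normal":
        z = stats.norm.ppf(1.0 - alpha)
        upper = expected + z * float(vals.std(ddof=1))
    elif method == "percentile":
        upper = float(np.quantile(vals, 1.0 - alpha))
    else:
        raise ValueError(f"unknown limit method {method!r}")
    lower = 2.0 * expected - upper
    return expected, upper, lower


def ecai(
    seq: str,
    ref: CodonUsageTable,
    n_random: int = 500,
    alpha: float = 0.05,
    method: str = "normal",
    seed: Optional[int] = None,
    code_basis: int = 1,
) -> AdaptationResult:
    """CAI of ``seq`` with its Monte-Carlo expected value and verdict."""
    if n_random < 2:
        raise ValueError("n_random must be at least 2")
    rng = np.random.default_rng(seed)
    ra = relative_adaptiveness(ref, code_basis)
    statistic = cai(seq, ra)
    vals = _mock_ensemble_stats(seq, lambda s: cai(s, ra), n_random, code_basis, rng)
    expected, upper, lower = _limits(vals, alpha, method)
    if statistic > upper:
        verdict = "positive_adaptation"
    elif statistic < lower:
        verdict = "negative_adaptation"
    else:
        verdict = "indistinguishable"
    return AdaptationResult(
        metric="CAI",
        statistic=statistic,
        expected=expected,
        upper=upper,
        lower=lower,
        verdict=verdict,
        n_random=n_random,
        seed=seed,
        method=method,
    )


def rcdi(seq: str, ref: CodonUsageTable, code_basis: int = 1) -> float:
    """Relative codon deoptimization index of ``seq`` against ``ref``."""
    counts = codon_counts(seq).counts
    fams = synonym_families(code_basis)
    total = 0.0
    n = 0
    for aa, fam in fams.items():
        fam_n = {c: counts.get(c, 0) for c in fam}
        fam_total = sum(fam_n.values())
        if fam_total == 0:
            continue
        ref_n = _smoothed_family_counts(ref, fam)
        ref_total = sum(ref_n.values())
        for c, k in fam_n.items():
            if k == 0:
                continue
            f_query = k / fam_total
            f_ref = ref_n[c] / ref_total
            total += k * f_query / f_ref
            n += k
    if n == 0:
        raise ValueError("sequence contains no countable sense codons")
    return total / n


def ercdi(
    seq: str,
    ref: CodonUsageTable,
    n_random: int = 500,
    alpha: float = 0.05,
    method: str = "normal",
    seed: Optional[int] = None,
    code_basis: int = 1,
) -> AdaptationResult:
    """RCDI of ``seq`` with its composition-matched null and verdict."""
    if n_random < 2:
        raise ValueError("n_random must be at least 2")
    rng = np.random.default_rng(seed)
    statistic = rcdi(seq, ref, code_basis)
    vals = _mock_ensemble_stats(
        seq, lambda s: rcdi(s, ref, code_basis), n_random, code_basis, rng
    )
    expected, upper, lower = _limits(vals, alpha, method)
    if statistic > upper:
        verdict = "deoptimized"
    elif statistic < lower:
        verdict = "over_adapted"
    else:
        verdict = "composition_driven"
    return AdaptationResult(
        metric="RCDI",
        statistic=statistic,
        expected=expected,
        upper=upper,
        lower=lower,
        verdict=verdict,
        n_random=n_random,
        seed=seed,
        method=method,
    )
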