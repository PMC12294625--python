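"""Independent brute-force oracles used to validate the implementation.

These are deliberately written against the definitions, not against the
package's code paths: the ORF enumerator works off explicit codon lists,
the Kozak oracle off regular expressions, the Wilcoxon oracle off full
2^n sign-flip enumeration, and the numeric oracles off direct formula
transcriptions.
"""

from __future__ import annotations

import math
import re
from itertools import product
from typing import Dict, Iterable, List, Tuple

import numpy as np
from scipy.stats import rankdata

STANDARD_STOPS = frozenset({"TAA", "TAG", "TGA"})


def enumerate_orfs(
    seq: str,
    frames: Iterable[int],
    min_codons: int,
    stops: frozenset = STANDARD_STOPS,
) -> List[Tuple[int, int, int, int]]:
    """All (frame, start_nt, end_nt, length_codons) ATG..stop ORFs.

    Keeps only the 5'-most ATG per stop-bounded segment and requires a
    terminating stop, mirroring the screening criteria.
    """
    out = []
    for f in sorted(frames):
        positions = list(range(f - 1, len(seq) - 2, 3))
        codons = {i: seq[i : i + 3] for i in positions}
        atgs = [i for i in positions if codons[i] == "ATG"]
        stop_pos = [i for i in positions if codons[i] in stops]
        for a in atgs:
            later_stops = [s for s in stop_pos if s > a]
            if not later_stops:
                continue
            prev_stops = [s for s in stop_pos if s < a]
            seg_start = (max(prev_stops) + 3) if prev_stops else f - 1
            if any(seg_start <= b < a for b in atgs):
                continue  # not the 5'-most ATG of its segment
            s = min(later_stops)
            length = (s - a) // 3
            if length >= min_codons:
                out.append((f, a + 1, s + 3, length))
    return sorted(out)


_KOZAK_PATTERNS = (
    ("optimal", re.compile(r"GCC[AG]CCATGG\Z")),
    ("strong", re.compile(r"...[AG]..ATGG\Z")),
    ("adequate", re.compile(r"...[AG]..ATG[ACT]\Z|...[CT]..ATGG\Z")),
    ("weak", re.compile(r"...[CT]..ATG[ACT]\Z")),
)


def kozak_oracle(upstream: str, plus4: str) -> str:
    """Regex transcription of the four published context patterns."""
    s = upstream + "ATG" + plus4
    for name, pattern in _KOZAK_PATTERNS:
        if pattern.match(s):
            return name
    return "undetermined"


def wilcoxon_exact_oracle(d, alternative: str = "greater") -> Tuple[float, float]:
    """One-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    ws = np.array(
        [sum(r for r, s in zip(ranks, signs) if s)
         for signs in product((0, 1), repeat=n)]
    )
    if alternative == "greater":
        p = float(np.mean(ws >= w_obs))
    elif alternative == "less":
        p = float(np.mean(ws <= w_obs))
    else:
        raise ValueError(alternative)
    return w_obs, p


def cai_log_oracle(codons: List[str], w: Dict[str, float], excluded) -> float:
    """Log-domain geometric mean over non-excluded codons."""
    logs = [math.log(w[c]) for c in codons if c not in excluded and c in w]
    return math.exp(sum(logs) / len(logs))


def rscu_oracle(counts: Dict[str, float], families: Dict[str, tuple]) -> Dict[str, float]:
    """Direct RSCU definition: count over mean family count."""
    out = {}
    for fam in families.values():
        total = sum(counts.get(c, 0) for c in fam)
        for c in fam:
            if total > 0:
                out[c] = counts.get(c, 0) / (total / len(fam))
            else:
                out[c] = 1.0
    return out


def spearman_oracle(x, y) -> float:
    """Rank (average ties) then Pearson."""
    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def identity_similarity_oracle(a: str, b: str, groups) -> Tuple[float, float]:
    """Column scan with an explicit residue-group lookup."""
    lookup = {}
    for gi, grp in enumerate(groups):
        for aa in grp:
            lookup[aa] = gi
    cols = ident = sim = 0
    for ca, cb in zip(a, b):
        if ca in "-." and cb in "-.":
            continue
        cols += 1
        if ca in "-." or cb in "-.":
            continue
        if ca == cb:
            ident += 1
            sim += 1
        elif lookup.get(ca, -1) == lookup.get(cb, -2):
            sim += 1
    return 100.0 * ident / cols, 100.0 * sim / cols
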