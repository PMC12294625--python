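"""Kozak initiation-context extraction and strength classification.

Translation initiation efficiency at an AUG is modulated mainly by the
base three positions upstream (-3, ideally a purine) and the base
immediately after the codon (+4, ideally G).  Contexts are binned into
four tiers:

========  =====================================
optimal   GCCRCCAUGG  (full -6..-1 motif plus +4 G)
strong    NNNRNNAUGG
adequate  NNNRNNAUG(A/C/U)  or  NNN(C/U)NNAUGG
weak      NNN(C/U)NNAUG(A/C/U)
========  =====================================

``R`` is a purine (A/G), ``N`` any base; patterns operate on the DNA
alphabet (U = T).  The tiers are nested, so precedence is
optimal > strong > adequate > weak.  Contexts missing the -3 or +4 base
(ORF starting too close to a sequence edge) are ``undetermined`` and are
excluded from positional tallies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Dict, Iterable, Optional

from .genetic_code import normalize_seq

__all__ = [
    "KozakContext",
    "STRENGTHS",
    "extract_context",
    "classify",
    "annotate",
    "tally_contexts",
]

OPTIMAL = "optimal"
STRONG = "strong"
ADEQUATE = "adequate"
WEAK = "weak"
UNDETERMINED = "undetermined"
STRENGTHS = (OPTIMAL, STRONG, ADEQUATE, WEAK, UNDETERMINED)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class KozakContext:
    """The -6..-1 / +4 context around a putative start codon."""

    upstream: str  # up to 6 bases immediately 5' of the ATG
    plus4: Optional[str]  # base at +4, None when the ATG abuts the 3' end
    strength: Optional[str] = None
    host_id: str = ""

    @property
    def minus3(self) -> Optional[str]:
        if len(self.upstream) >= 3:
            return self.upstream[-3]
        return None


def extract_context(host_seq: str, orf_start_nt: int, host_id: str = "") -> KozakContext:
    """Slice the context around an ATG at 1-based position ``orf_start_nt``.

    The upstream window is shortened when the ORF starts within six bases
    of the host 5' end; strength is left unset.
    """
    seq = normalize_seq(host_seq)
    i = orf_start_nt - 1
    if seq[i : i + 3] != "ATG":
        raise ValueError(
            f"no ATG at position {orf_start_nt} (found {seq[i:i + 3]!r})"
        )
    upstream = seq[max(0, i - 6) : i]
    plus4 = seq[i + 3] if i + 3 < len(seq) else None
    return KozakContext(upstream=upstream, plus4=plus4, host_id=host_id)


def classify(ctx: KozakContext) -> str:
    """Assign one of the four strength tiers (or ``undetermined``)."""
    minus3 = ctx.minus3
    plus4 = ctx.plus4
    if minus3 is None or plus4 is None:
        return UNDETERMINED
    up = ctx.upstream
    if (
        len(up) == 6
        and up[0:3] == "GCC"
        and up[3] in _PURINES
        and up[4:6] == "CC"
        and plus4 == "G"
    ):
        return OPTIMAL
    if minus3 in _PURINES:
        return STRONG if plus4 == "G" else ADEQUATE
    return ADEQUATE if plus4 == "G" else WEAK


def annotate(ctx: KozakContext) -> KozakContext:
    """Return a copy of ``ctx`` with its strength field filled in."""
    return replace(ctx, strength=classify(ctx))


def tally_contexts(ctxs: Iterable[KozakContext]) -> Dict[str, Dict[str, int]]:
    """Base composition at -3 and +4 plus per-tier counts.

    Positional tallies cover determined contexts only; the strength tally
    covers every input (undetermined included), so its counts sum to the
    input size.
    """
    minus3: Counter = Counter()
    plus4: Counter = Counter()
    strength: Counter = Counter()
    for ctx in ctxs:
        cls = ctx.strength if ctx.strength is not None else classify(ctx)
        strength[cls] += 1
        if cls != UNDETERMINED:
            minus3[ctx.minus3] += 1
            plus4[ctx.plus4] += 1
    return {
        "minus3": dict(minus3),
        "plus4": dict(plus4),
        "strength": dict(strength),
    }
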