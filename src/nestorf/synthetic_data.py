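"""Synthetic cytb-like hosts, embedded nested ORFs, and codon-usage tables.

Every pipeline stage in this package is testable without downloads
because the generator emits data with a ground-truth manifest: hosts that
are clean frame-1 coding sequences under the vertebrate mitochondrial
code (begin ATG, no internal mitochondrial-code stop, terminal stop),
optionally carrying

* an early frame-1 TGA (default at host codon 30, nucleotides 88-90) —
  tryptophan to the mitochondrial ribosome, a premature stop to a
  cytosolic one;
* an embedded +2/+3-frame standard-code ORF of a requested length and
  Kozak strength class, placed so the scanner must recover its exact
  ATG..stop span;
* for ORF-positive hosts, no downstream frame-1 standard-code ATG-ORF
  longer than 50 codons (the architecture observed in real hosts).

Construction is codon-wise from a mitochondrial codon law, followed by
overwriting the ORF window and Kozak bases, synonymous repair of any
mitochondrial-code stops the overwrite introduced into frame 1, and
bounded resampling whenever a chance qualifying ORF, an upstream in-frame
ATG, or an unrepairable conflict arises.  Generation is rejected rather
than patched whenever a constraint cannot be satisfied exactly, so the
manifest is authoritative: a post-generation self-check runs the real
scanner, Kozak classifier and PTC scan against every record.

Codon-usage tables are multinomial draws from a weight law, with CDS
count and average-length metadata under the caller's control so the
robustness filter can be exercised both ways.  :func:`make_reference_laws`
builds correlated nuclear/mitochondrial weight pairs (shared log-bias
plus gene-set and species offsets), emulating the fact that a species'
two gene sets have distinct but not independent codon usage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .genetic_code import MITO_CODE, STANDARD_CODE, GeneticCode, translate
from .io_formats import (
    ALL_CODONS,
    CdsRecord,
    CodonUsageTable,
    write_codon_table,
    write_fasta,
)
from .kozak import classify, extract_context
from .orf_screen import ptc_scan, scan_nested_orfs

__all__ = [
    "SyntheticSpec",
    "ManifestRow",
    "StudySet",
    "generate_host",
    "generate_usage_table",
    "generate_study_set",
    "make_reference_laws",
    "sample_coding_sequence",
]

_T2_STOPS = frozenset(MITO_CODE.stop_codons)  # TAA, TAG, AGA, AGG
_ORF_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"


class _Retry(Exception):
    """Internal: this construction attempt cannot be completed."""


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic cohort.

    ``kozak_class`` is a single target class or a ``{class: count}`` mix
    over the positive records; ``tga_codon_index`` likewise is a 1-based
    host codon index or a ``{index: count}`` mix (index 30 puts the TGA at
    nucleotides 88-90).  ``codon_law`` drives host codons (mitochondrial
    sense codons), ``orf_codon_law`` drives embedded ORF codons (standard
    sense codons); ``"uniform"`` means equal weights.
    """

    n_positive: int
    n_negative: int
    host_len_nt: int = 1140
    orf_len_codons: Tuple[int, int] = (150, 239)
    orf_frame: int = 3
    kozak_class: Union[str, Mapping[str, int]] = "adequate"
    plant_early_tga: bool = True
    tga_codon_index: Union[int, Mapping[int, int]] = 30
    codon_law: Union[str, CodonUsageTable, Mapping[str, float]] = "uniform"
    orf_codon_law: Union[str, CodonUsageTable, Mapping[str, float]] = "uniform"
    n_duplicates: int = 0
    min_codons: int = 150
    downstream_limit_codons: int = 50
    group: str = "GroupA"
    id_prefix: str = "SYN"

    def __post_init__(self):
        if self.host_len_nt % 3:
            raise ValueError("host_len_nt must be divisible by 3")
        if self.n_positive < 0 or self.n_negative < 0 or self.n_duplicates < 0:
            raise ValueError("record counts must be non-negative")
        if self.orf_frame not in (2, 3):
            raise ValueError("orf_frame must be 2 or 3")
        lo, hi = self.orf_len_codons
        if lo > hi or lo < 1:
            raise ValueError(f"invalid orf_len_codons range {self.orf_len_codons}")


@dataclass
class ManifestRow:
    """Ground truth for one generated record."""

    id: str
    species: str
    group: str
    has_orf: bool
    orf_start_nt: Optional[int] = None
    orf_end_nt: Optional[int] = None
    orf_frame: Optional[int] = None
    orf_len_codons: Optional[int] = None
    kozak_class: Optional[str] = None
    first_stop_span: Optional[Tuple[int, int]] = None
    duplicate_of: Optional[str] = None
    robust_nuclear: bool = False


@dataclass
class StudySet:
    """Paths and truth for a generated fixture tree."""

    out_dir: Path
    fasta: Dict[str, Path]
    meta: Path
    nuclear_dir: Path
    mito_dir: Path
    manifest: List[ManifestRow]
    manifest_tsv: Path
    manifest_json: Path


# ---------------------------------------------------------------------------
# Codon laws
# ---------------------------------------------------------------------------


def _law_weights(law, codons: Sequence[str]) -> np.ndarray:
    if isinstance(law, str):
        if law != "uniform":
            raise ValueError(f"unknown codon law {law!r}")
        w = np.ones(len(codons))
    elif isinstance(law, CodonUsageTable):
        w = np.array([law.codon_counts.get(c, 0.0) for c in codons])
    elif isinstance(law, Mapping):
        w = np.array([float(law.get(c, 0.0)) for c in codons])
    else:
        raise TypeError(f"cannot interpret codon law of type {type(law).__name__}")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("codon law weights must be non-negative with positive total")
    return w / w.sum()


def _sense_codons(code: GeneticCode) -> Tuple[str, ...]:
    return tuple(sorted(c for c, aa in code.codon_to_aa.items() if aa != "*"))


class _CodonSampler:
    def __init__(self, law, code: GeneticCode):
        self.codons = _sense_codons(code)
        self.probs = _law_weights(law, self.codons)

    def draw(self, rng: np.random.Generator, n: int) -> List[str]:
        idx = rng.choice(len(self.codons), size=n, p=self.probs)
        return [self.codons[i] for i in idx]


def sample_coding_sequence(
    law,
    n_codons: int,
    rng: np.random.Generator,
    code_basis: int = 1,
    stop_codon: Optional[str] = None,
) -> str:
    """A gene of ``n_codons`` sense codons drawn i.i.d. from ``law``,
    optionally terminated by ``stop_codon``."""
    code = STANDARD_CODE if code_basis == 1 else MITO_CODE
    body = "".join(_CodonSampler(law, code).draw(rng, n_codons))
    return body + (stop_codon or "")


# ---------------------------------------------------------------------------
# Host construction
# ---------------------------------------------------------------------------


def _sample_kozak(
    target: str, rng: np.random.Generator, plus4: Optional[str] = None
) -> Tuple[str, str]:
    """Upstream -6..-1 bases and the +4 base realising a strength class.

    When ``plus4`` is given (the +4 base is already committed in the
    sequence), only the upstream bases are resampled, consistently with
    the class pattern.
    """
    def bases(n):
        return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))

    def pick(s):
        return s[rng.integers(0, len(s))]

    for _ in range(100):
        if target == "optimal":
            if plus4 not in (None, "G"):
                raise _Retry
            up = "GCC" + pick("AG") + "CC"
            p4 = "G"
        elif target == "strong":
            if plus4 not in (None, "G"):
                raise _Retry
            up = bases(3) + pick("AG") + bases(2)
            p4 = "G"
            if up[:3] == "GCC" and up[4:] == "CC":
                continue
        elif target == "adequate":
            if plus4 == "G" or (plus4 is None and rng.random() < 0.5):
                up = bases(3) + pick("CT") + bases(2)
                p4 = "G"
            else:
                up = bases(3) + pick("AG") + bases(2)
                p4 = plus4 if plus4 is not None else pick("ACT")
        elif target == "weak":
            if plus4 == "G":
                raise _Retry
            up = bases(3) + pick("CT") + bases(2)
            p4 = plus4 if plus4 is not None else pick("ACT")
        else:
            raise ValueError(f"cannot plant Kozak class {target!r}")
        # an upstream in-frame ATG would shift the scanner's reported start
        if up[:3] == "ATG" or up[3:6] == "ATG":
            continue
        return up, p4
    raise _Retry


def _synonyms(codon: str, first_base: Optional[str] = None) -> List[str]:
    aa = STANDARD_CODE.codon_to_aa[codon]
    return [
        c
        for c, a in STANDARD_CODE.codon_to_aa.items()
        if a == aa and (first_base is None or c[0] == first_base)
    ]


class _HostBuilder:
    """One construction attempt; raises _Retry on any dead end."""

    def __init__(self, spec: SyntheticSpec, rng, host_sampler, orf_sampler):
        self.spec = spec
        self.rng = rng
        self.host_sampler = host_sampler
        self.orf_sampler = orf_sampler
        self.n_codons = spec.host_len_nt // 3
        self.seq: List[str] = []
        self.protected = np.zeros(spec.host_len_nt, dtype=bool)
        self.orf_span: Optional[Tuple[int, int]] = None  # 0-based [start, end]
        self.orf_len = 0
        self.plus4 = ""

    # -- scaffolding --------------------------------------------------------

    def build_backbone(self, tga_codon: Optional[int]) -> None:
        body = self.host_sampler.draw(self.rng, self.n_codons - 2)
        codons = ["ATG"] + body + ["TAA"]
        if tga_codon is not None:
            if not 1 < tga_codon < self.n_codons:
                raise ValueError(f"tga_codon_index {tga_codon} outside host")
            codons[tga_codon - 1] = "TGA"
            # the planted TGA must be the *first* standard-code stop of the
            # host frame: no TGA may precede it
            no_tga = [
                (c, p) for c, p in zip(self.host_sampler.codons,
                                       self.host_sampler.probs)
                if c != "TGA"
            ]
            alt_codons = [c for c, _ in no_tga]
            alt_probs = np.array([p for _, p in no_tga])
            alt_probs = alt_probs / alt_probs.sum()
            for i in range(1, tga_codon - 1):
                if codons[i] == "TGA":
                    codons[i] = alt_codons[
                        self.rng.choice(len(alt_codons), p=alt_probs)
                    ]
        self.seq = list("".join(codons))
        self.protected[:3] = True
        self.protected[-3:] = True
        if tga_codon is not None:
            self.protected[3 * (tga_codon - 1) : 3 * tga_codon] = True

    def embed_orf(self, length: int, frame: int, kozak_target: str) -> None:
        n = self.spec.host_len_nt
        span = 3 * (length + 1)
        # keep the initiator context, any planted TGA, and the terminal stop
        lo_protected = int(np.flatnonzero(self.protected[: n // 2]).max()) \
            if self.protected[: n // 2].any() else 2
        i_min = lo_protected + 1 + 6  # room for the -6..-1 context
        i_max = n - 3 - span  # leave the terminal stop codon intact
        starts = [i for i in range(i_min, i_max + 1) if i % 3 == frame - 1]
        if not starts:
            raise ValueError(
                f"no feasible ORF start for length {length} in a "
                f"{n}-nt host with the requested plants"
            )
        i0 = starts[self.rng.integers(0, len(starts))]
        up, p4 = _sample_kozak(kozak_target, self.rng)
        second = self.orf_sampler_codon_with_first_base(p4)
        body = self.orf_sampler.draw(self.rng, length - 2)
        stop = _ORF_STOPS[self.rng.integers(0, 3)]
        orf_nt = "ATG" + second + "".join(body) + stop
        self.seq[i0 - 6 : i0] = list(up)
        self.seq[i0 : i0 + span] = list(orf_nt)
        self.protected[i0 - 6 : i0 + span] = True
        self.orf_span = (i0, i0 + span - 1)
        self.orf_len = length
        self.plus4 = p4

    def orf_sampler_codon_with_first_base(self, base: str) -> str:
        candidates = [
            (c, p)
            for c, p in zip(self.orf_sampler.codons, self.orf_sampler.probs)
            if c[0] == base
        ]
        codons = [c for c, _ in candidates]
        probs = np.array([p for _, p in candidates])
        if probs.sum() <= 0:
            probs = np.full(len(codons), 1.0 / len(codons))
        else:
            probs = probs / probs.sum()
        return codons[self.rng.choice(len(codons), p=probs)]

    # -- frame-1 repair ------------------------------------------------------

    def _frame1_codon(self, j: int) -> str:
        return "".join(self.seq[3 * j : 3 * j + 3])

    def repair_frame1(self) -> None:
        """Remove mitochondrial-code stops the overwrite put into frame 1."""
        if self.orf_span is None:
            return
        lo = max(0, (self.orf_span[0] - 8) // 3)
        hi = min(self.n_codons - 2, (self.orf_span[1] + 2) // 3)
        for _ in range(60):
            bad = [
                j for j in range(lo, hi + 1) if self._frame1_codon(j) in _T2_STOPS
            ]
            if not bad:
                return
            self._fix_frame1(bad[0])
        raise _Retry

    def _overlapping_orf_codons(self, j: int) -> List[int]:
        i0 = self.orf_span[0]
        lo_k = max(0, -(-(3 * j - 2 - i0) // 3))  # ceil division
        hi_k = min(self.orf_len, (3 * j + 2 - i0) // 3)
        return [k for k in range(lo_k, hi_k + 1) if i0 + 3 * k >= i0]

    def _fix_frame1(self, j: int) -> None:
        i0, i1 = self.orf_span
        lo_nt, hi_nt = 3 * j, 3 * j + 2
        rng = self.rng
        # free host codon: redraw from the host law (always mito-sense)
        if not self.protected[lo_nt : hi_nt + 1].any():
            self.seq[lo_nt : hi_nt + 1] = list(self.host_sampler.draw(rng, 1)[0])
            return
        actions: List[Tuple[str, int]] = []
        if hi_nt >= i0 and lo_nt <= i1:
            for k in self._overlapping_orf_codons(j):
                if k == 0:
                    continue  # the ORF's own ATG is immutable
                actions.append(("orf", k))
        if lo_nt <= i0 - 1 and hi_nt >= i0 - 6:
            actions.append(("kozak", -1))
        order = rng.permutation(len(actions))
        for idx in order:
            kind, k = actions[idx]
            if kind == "orf":
                pos = i0 + 3 * k
                current = "".join(self.seq[pos : pos + 3])
                if k == self.orf_len:  # the ORF stop codon
                    options = [s for s in _ORF_STOPS if s != current]
                else:
                    first = self.plus4 if k == 1 else None
                    options = [s for s in _synonyms(current, first) if s != current]
                rng.shuffle(options)
                for cand in options:
                    self.seq[pos : pos + 3] = list(cand)
                    if self._frame1_codon(j) not in _T2_STOPS:
                        return
                self.seq[pos : pos + 3] = list(current)
            else:  # resample the Kozak upstream bases
                current_up = self.seq[i0 - 6 : i0]
                for _ in range(25):
                    up, _p4 = _sample_kozak(self._kozak_target, rng, self.plus4)
                    self.seq[i0 - 6 : i0] = list(up)
                    if self._frame1_codon(j) not in _T2_STOPS:
                        return
                self.seq[i0 - 6 : i0] = current_up
        raise _Retry

    # -- downstream ORF limiting ---------------------------------------------

    def limit_downstream_orfs(self) -> None:
        """Cap frame-1 standard-code ATG-ORFs downstream of the first PTC."""
        limit = self.spec.downstream_limit_codons
        stops = STANDARD_CODE.stop_codons
        for _ in range(30):
            seq = "".join(self.seq)
            first = None
            for j in range(self.n_codons):
                if seq[3 * j : 3 * j + 3] in stops:
                    first = j
                    break
            scan_from = (first + 1) if first is not None else 0
            run = self._find_long_run(seq, scan_from, stops, limit)
            if run is None:
                return
            atg_j, end_j = run
            window = [
                j
                for j in range(atg_j + 1, min(atg_j + limit + 1, end_j))
                if not self.protected[3 * j : 3 * j + 3].any()
            ]
            if not window:
                raise _Retry
            j = window[self.rng.integers(0, len(window))]
            self.seq[3 * j : 3 * j + 3] = list("TGA")  # Trp to the mito ribosome
        raise _Retry

    def _find_long_run(self, seq, scan_from, stops, limit):
        open_j = None
        for j in range(scan_from, self.n_codons):
            codon = seq[3 * j : 3 * j + 3]
            if codon in stops:
                if open_j is not None and j - open_j > limit:
                    return open_j, j
                open_j = None
            elif codon == "ATG" and open_j is None:
                open_j = j
        if open_j is not None and self.n_codons - open_j > limit:
            return open_j, self.n_codons
        return None


def generate_host(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    *,
    record_id: str = "SYN0001",
    species: str = "",
    has_orf: bool = True,
    kozak_target: Optional[str] = None,
    tga_codon: Optional[int] = None,
    orf_length: Optional[int] = None,
    max_attempts: int = 1000,
) -> Tuple[CdsRecord, ManifestRow]:
    """Generate one host CDS and its ground-truth manifest row.

    The returned record is verified with the real scanner, classifier and
    PTC scan before being accepted; an unsatisfiable specification raises
    after ``max_attempts`` bounded resamples.
    """
    host_sampler = _CodonSampler(spec.codon_law, MITO_CODE)
    orf_sampler = _CodonSampler(spec.orf_codon_law, STANDARD_CODE)
    if tga_codon is None and spec.plant_early_tga:
        idx = spec.tga_codon_index
        tga_codon = idx if isinstance(idx, int) else next(iter(idx))
    if kozak_target is None:
        kc = spec.kozak_class
        kozak_target = kc if isinstance(kc, str) else next(iter(kc))

    lo, hi = spec.orf_len_codons
    for _ in range(max_attempts):
        try:
            builder = _HostBuilder(spec, rng, host_sampler, orf_sampler)
            builder._kozak_target = kozak_target
            builder.build_backbone(tga_codon)
            length = None
            if has_orf:
                length = (
                    orf_length
                    if orf_length is not None
                    else int(rng.integers(lo, hi + 1))
                )
                builder.embed_orf(length, spec.orf_frame, kozak_target)
                builder.repair_frame1()
                builder.limit_downstream_orfs()
            seq = "".join(builder.seq)
            row = _validate_host(
                spec, seq, record_id, species, has_orf, length, builder, kozak_target,
                tga_codon,
            )
            if row is None:
                continue
            rec = CdsRecord(id=record_id, species=species, group=spec.group, seq=seq)
            return rec, row
        except _Retry:
            continue
    raise RuntimeError(
        f"could not satisfy the synthetic spec for {record_id} "
        f"after {max_attempts} attempts"
    )


def _validate_host(
    spec, seq, record_id, species, has_orf, length, builder, kozak_target, tga_codon
) -> Optional[ManifestRow]:
    """Run the real pipeline stages as a self-check oracle; None = reject."""
    protein = translate(seq, MITO_CODE, 1)
    if "*" in protein[:-1] or protein[-1] != "*" or protein[0] != "M":
        return None
    rec = CdsRecord(id=record_id, species=species, group=spec.group, seq=seq)
    orfs = scan_nested_orfs(rec, STANDARD_CODE, (2, 3), spec.min_codons)
    # the parallel mitochondrial-code scan is a negative control: the
    # emulated architecture carries no qualifying table-2 nested ORF
    if scan_nested_orfs(rec, MITO_CODE, (2, 3), spec.min_codons):
        return None
    ptc = ptc_scan(rec, spec.downstream_limit_codons)
    if has_orf:
        i0, i1 = builder.orf_span
        if len(orfs) != 1:
            return None
        orf = orfs[0]
        if (
            orf.frame != spec.orf_frame
            or orf.start_nt != i0 + 1
            or orf.end_nt != i1 + 1
            or orf.length_codons != length
        ):
            return None
        ctx = extract_context(seq, orf.start_nt)
        if classify(ctx) != kozak_target:
            return None
        if ptc.downstream_long_orf:
            return None
    else:
        if orfs:
            return None
    if tga_codon is not None:
        want = (3 * tga_codon - 2, 3 * tga_codon)
        if ptc.first_stop_span != want or ptc.first_stop_codon != "TGA":
            return None
    return ManifestRow(
        id=record_id,
        species=species,
        group=spec.group,
        has_orf=has_orf,
        orf_start_nt=(builder.orf_span[0] + 1) if has_orf else None,
        orf_end_nt=(builder.orf_span[1] + 1) if has_orf else None,
        orf_frame=spec.orf_frame if has_orf else None,
        orf_len_codons=length if has_orf else None,
        kozak_class=kozak_target if has_orf else None,
        first_stop_span=ptc.first_stop_span,
    )


# ---------------------------------------------------------------------------
# Usage tables and reference laws
# ---------------------------------------------------------------------------


def generate_usage_table(
    bias,
    n_cds: int,
    avg_len: float,
    gene_set: str,
    rng: np.random.Generator,
    species: str = "",
) -> CodonUsageTable:
    """Multinomial codon counts of size ``n_cds * avg_len`` from a weight law."""
    probs = _law_weights(bias, ALL_CODONS)
    total = int(round(n_cds * avg_len))
    counts = rng.multinomial(total, probs)
    return CodonUsageTable(
        codon_counts=dict(zip(ALL_CODONS, (float(c) for c in counts))),
        gene_set=gene_set,
        n_cds=n_cds,
        avg_cds_len_codons=avg_len,
        species=species,
    )


def make_reference_laws(
    n_species: int,
    rng: np.random.Generator,
    sigma_shared: float = 1.0,
    sigma_set: float = 0.8,
    sigma_species: float = 0.3,
) -> List[Tuple[Dict[str, float], Dict[str, float]]]:
    """Per-species (nuclear, mitochondrial) codon-weight laws.

    Log-weights decompose into a study-wide component shared by both gene
    sets, a gene-set offset distinguishing nuclear from mitochondrial
    usage, and a small per-species offset — so the two sets are biased
    differently but remain positively correlated, as in real genomes.
    """
    g = rng.normal(0.0, sigma_shared, 64)
    d_nuc = rng.normal(0.0, sigma_set, 64)
    d_mito = rng.normal(0.0, sigma_set, 64)
    laws = []
    for _ in range(n_species):
        b_n = rng.normal(0.0, sigma_species, 64)
        b_m = rng.normal(0.0, sigma_species, 64)
        w_nuc = np.exp(g + d_nuc + b_n)
        w_mito = np.exp(g + d_mito + b_m)
        laws.append(
            (dict(zip(ALL_CODONS, w_nuc)), dict(zip(ALL_CODONS, w_mito)))
        )
    return laws


# ---------------------------------------------------------------------------
# Study sets
# ---------------------------------------------------------------------------


def _expand_mix(mix, n: int, rng) -> List:
    """Expand a value or {value: count} mapping into a shuffled length-n list."""
    if not isinstance(mix, Mapping):
        return [mix] * n
    items: List = []
    for value, count in mix.items():
        items.extend([value] * count)
    if len(items) != n:
        raise ValueError(f"mix counts sum to {len(items)}, expected {n}")
    rng.shuffle(items)
    return items


def generate_study_set(
    spec_a: SyntheticSpec,
    spec_b: SyntheticSpec,
    out_dir,
    rng: np.random.Generator,
    *,
    n_robust_nuclear: Tuple[Optional[int], Optional[int]] = (None, None),
    robust_depth: Tuple[int, float] = (40, 400.0),
    shallow_depth: Tuple[int, float] = (20, 400.0),
    mito_depth: Tuple[int, float] = (13, 300.0),
) -> StudySet:
    """Generate a complete two-group fixture tree.

    Emits one FASTA per group, a sidecar metadata TSV, per-species nuclear
    and mitochondrial codon tables for the ORF-positive species (robust
    nuclear tables for the first ``n_robust_nuclear`` of them, shallow
    ones for the rest), and the truth manifest as TSV and JSON.  Hosts are
    drawn from their species' mitochondrial law.
    """
    out_dir = Path(out_dir)
    nuclear_dir = out_dir / "tables" / "nuclear"
    mito_dir = out_dir / "tables" / "mitochondrial"
    nuclear_dir.mkdir(parents=True, exist_ok=True)
    mito_dir.mkdir(parents=True, exist_ok=True)

    manifest: List[ManifestRow] = []
    fasta_paths: Dict[str, Path] = {}
    meta_rows: List[Tuple[str, str, str]] = []

    for spec, n_robust in zip((spec_a, spec_b), n_robust_nuclear):
        records: List[CdsRecord] = []
        n_total = spec.n_positive + spec.n_negative
        flags = np.zeros(n_total, dtype=bool)
        flags[: spec.n_positive] = True
        rng.shuffle(flags)
        kozak_mix = _expand_mix(spec.kozak_class, spec.n_positive, rng)
        tga_mix = _expand_mix(
            spec.tga_codon_index if spec.plant_early_tga else None,
            spec.n_positive,
            rng,
        )
        laws = make_reference_laws(n_total, rng)
        positives: List[Tuple[CdsRecord, ManifestRow, int]] = []
        pos_i = 0
        for i in range(n_total):
            rec_id = f"{spec.id_prefix}{i + 1:04d}"
            species = f"{spec.group} species {i + 1:04d}"
            law_nuc, law_mito = laws[i]
            local = replace(spec, codon_law=law_mito)
            if flags[i]:
                rec, row = generate_host(
                    local,
                    rng,
                    record_id=rec_id,
                    species=species,
                    has_orf=True,
                    kozak_target=kozak_mix[pos_i],
                    tga_codon=tga_mix[pos_i] if spec.plant_early_tga else None,
                )
                positives.append((rec, row, i))
                pos_i += 1
            else:
                rec, row = generate_host(
                    local, rng, record_id=rec_id, species=species, has_orf=False,
                    tga_codon=(
                        (spec.tga_codon_index if isinstance(spec.tga_codon_index, int)
                         else next(iter(spec.tga_codon_index)))
                        if spec.plant_early_tga else None
                    ),
                )
            records.append(rec)
            manifest.append(row)

        # exact copies of existing positives, as redundant accessions
        if spec.n_duplicates:
            if not positives:
                raise ValueError("cannot plant duplicates without positives")
            picks = rng.integers(0, len(positives), size=spec.n_duplicates)
            for d, pick in enumerate(picks):
                src_rec, src_row, _ = positives[pick]
                dup_id = f"{spec.id_prefix}D{d + 1:03d}"
                dup_species = f"{spec.group} species dup {d + 1:03d}"
                dup_rec = CdsRecord(
                    id=dup_id, species=dup_species, group=spec.group, seq=src_rec.seq
                )
                dup_row = replace(
                    src_row, id=dup_id, species=dup_species, duplicate_of=src_rec.id
                )
                records.append(dup_rec)
                manifest.append(dup_row)

        # reference tables for the ORF-positive species
        n_rob = len(positives) if n_robust is None else n_robust
        for rank, (rec, row, i) in enumerate(positives):
            law_nuc, law_mito = laws[i]
            robust = rank < n_rob
            n_cds, avg = robust_depth if robust else shallow_depth
            nuc_table = generate_usage_table(
                law_nuc, n_cds, avg, "nuclear", rng, species=rec.species
            )
            mito_table = generate_usage_table(
                law_mito, *mito_depth, "mitochondrial", rng, species=rec.species
            )
            stem = rec.species.replace(" ", "_")
            write_codon_table(nuc_table, nuclear_dir / f"{stem}.tsv")
            write_codon_table(mito_table, mito_dir / f"{stem}.tsv")
            row.robust_nuclear = robust

        fasta_path = out_dir / f"{spec.group.lower()}.fa"
        write_fasta(records, fasta_path)
        fasta_paths[spec.group] = fasta_path
        meta_rows.extend((r.id, r.species, r.group) for r in records)

    meta_path = out_dir / "meta.tsv"
    meta_path.write_text(
        "id\tspecies\tgroup\n"
        + "".join(f"{i}\t{s}\t{g}\n" for i, s, g in meta_rows)
    )
    manifest_tsv = out_dir / "manifest.tsv"
    manifest_json = out_dir / "manifest.json"
    _write_manifest(manifest, manifest_tsv, manifest_json)
    return StudySet(
        out_dir=out_dir,
        fasta=fasta_paths,
        meta=meta_path,
        nuclear_dir=nuclear_dir,
        mito_dir=mito_dir,
        manifest=manifest,
        manifest_tsv=manifest_tsv,
        manifest_json=manifest_json,
    )


def _write_manifest(rows: List[ManifestRow], tsv_path: Path, json_path: Path) -> None:
    cols = [
        "id", "species", "group", "has_orf", "orf_start_nt", "orf_end_nt",
        "orf_frame", "orf_len_codons", "kozak_class", "first_stop_span",
        "duplicate_of", "robust_nuclear",
    ]
    lines = ["\t".join(cols)]
    for row in rows:
        d = asdict(row)
        d["first_stop_span"] = (
            f"{d['first_stop_span'][0]}-{d['first_stop_span'][1]}"
            if d["first_stop_span"]
            else ""
        )
        lines.append("\t".join("" if d[c] is None else str(d[c]) for c in cols))
    tsv_path.write_text("\n".join(lines) + "\n")
    json_path.write_text(
        json.dumps([asdict(r) for r in rows], indent=1, sort_keys=True) + "\n"
    )
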