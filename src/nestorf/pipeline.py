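"""End-to-end orchestration: scan, dedupe, Kozak, PTC, adaptation,
similarity, and the summary report.

``run_all`` composes the library stages over one or more taxon groups and
writes per-stage TSVs plus a single ``summary.json``.  The downstream
analyses follow the study design: nested-ORF candidates are consolidated
at the nucleotide level before Kozak/PTC analysis, and the codon-usage
statistics are restricted to species whose nuclear reference table passes
the robustness filter (at least 30 CDSs averaging more than 100 codons).
A parallel mitochondrial-code scan is always executed and reported in its
own section as a negative control.

All randomness (Monte-Carlo nulls) derives from ``config.seed``; the same
configuration and seed reproduce the summary byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .adaptation import AdaptationResult, ecai, ercdi
from .genetic_code import get_code
from .io_formats import (
    CodonUsageTable,
    MissingTableMetadata,
    read_codon_table,
    read_fasta,
    read_metadata,
    table_is_robust,
)
from .kozak import annotate, extract_context, tally_contexts
from .orf_screen import NestedOrf, dedupe_orfs, longest_per_frame, ptc_scan, scan_nested_orfs
from .similarity_stats import build_similarity_table, run_similarity_tests

__all__ = ["PipelineConfig", "run_all", "summarize_prevalence", "round_half_up"]

log = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), matching report formatting."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    """Inputs and parameters for a full run."""

    fasta: Dict[str, str]  # group label -> FASTA path
    out_dir: str
    meta: Optional[str] = None
    nuclear_dir: Optional[str] = None
    mito_dir: Optional[str] = None
    scan_codes: Tuple[int, ...] = (1, 2)
    min_codons: int = 150
    downstream_min: int = 50
    n_random: int = 500
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("min_codons", "downstream_min", "n_random"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "scan_codes" in data:
            data["scan_codes"] = tuple(data["scan_codes"])
        return cls(**data)


def summarize_prevalence(
    group_counts: Mapping[str, Tuple[int, int]]
) -> Dict[str, Dict[str, float]]:
    """Positives, totals and percentage (2 decimals, half-up) per group."""
    out: Dict[str, Dict[str, float]] = {}
    for group, (positive, total) in group_counts.items():
        if total == 0:
            raise ValueError(f"group {group!r} has no records")
        out[group] = {
            "n_positive": positive,
            "n_total": total,
            "pct_positive": round_half_up(100.0 * positive / total, 2),
        }
    return out


def _load_tables(directory: Optional[str]) -> Dict[str, CodonUsageTable]:
    tables: Dict[str, CodonUsageTable] = {}
    if directory is None:
        return tables
    for path in sorted(Path(directory).glob("*.tsv")):
        t = read_codon_table(path, "canonical_tsv")
        tables[t.species] = t
    return tables


def _orfs_frame(orfs: Sequence[NestedOrf]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "host_id": o.host_id,
                "frame": o.frame,
                "start_nt": o.start_nt,
                "end_nt": o.end_nt,
                "length_codons": o.length_codons,
                "nt_seq": o.nt_seq,
                "aa_seq": o.aa_seq,
            }
            for o in orfs
        ],
        columns=[
            "host_id", "frame", "start_nt", "end_nt", "length_codons",
            "nt_seq", "aa_seq",
        ],
    )


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs remain in out_dir."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the summary report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = read_metadata(config.meta) if config.meta else None
    nuclear_tables = _load_tables(config.nuclear_dir)
    mito_tables = _load_tables(config.mito_dir)
    seed_rng = np.random.default_rng(config.seed)

    summary: dict = {
        "seed": config.seed,
        "params": {
            "min_codons": config.min_codons,
            "downstream_min": config.downstream_min,
            "n_random": config.n_random,
            "alpha": config.alpha,
            "scan_codes": list(config.scan_codes),
        },
        "groups": {},
    }

    for group, fasta_path in sorted(config.fasta.items()):
        gdir = out_dir / group.lower()
        gdir.mkdir(exist_ok=True)
        stage = "read"
        try:
            records = read_fasta(fasta_path, metadata=meta)
        except Exception as exc:  # noqa: BLE001 - stage-named abort
            raise StageError(stage, exc) from exc
        by_id = {r.id: r for r in records}

        # --- scan (standard code, plus the mitochondrial-code control) ----
        stage = "scan"
        try:
            per_host: List[NestedOrf] = []
            all_hits: List[NestedOrf] = []
            for rec in records:
                hits = scan_nested_orfs(
                    rec, get_code(1), (2, 3), config.min_codons
                )
                winners = longest_per_frame(hits)
                all_hits.extend(winners)
                if winners:
                    per_host.append(
                        max(winners, key=lambda o: (o.length_codons, -o.frame))
                    )
            table2_hits: List[NestedOrf] = []
            if 2 in config.scan_codes:
                for rec in records:
                    table2_hits.extend(
                        longest_per_frame(
                            scan_nested_orfs(rec, get_code(2), (2, 3),
                                             config.min_codons)
                        )
                    )
            _orfs_frame(all_hits).to_csv(gdir / "orfs.tsv", sep="\t", index=False)
            _orfs_frame(table2_hits).to_csv(
                gdir / "orfs_table2.tsv", sep="\t", index=False
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # --- dedupe --------------------------------------------------------
        stage = "dedupe"
        try:
            unique, groups_map = dedupe_orfs(per_host)
            _orfs_frame(unique).to_csv(gdir / "unique_orfs.tsv", sep="\t",
                                       index=False)
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # --- Kozak ---------------------------------------------------------
        stage = "kozak"
        try:
            contexts = [
                annotate(extract_context(by_id[o.host_id].seq, o.start_nt,
                                         o.host_id))
                for o in unique
            ]
            pd.DataFrame(
                [
                    {
                        "host_id": c.host_id,
                        "upstream": c.upstream,
                        "plus4": c.plus4,
                        "minus3": c.minus3,
                        "strength": c.strength,
                    }
                    for c in contexts
                ],
                columns=["host_id", "upstream", "plus4", "minus3", "strength"],
            ).to_csv(gdir / "kozak.tsv", sep="\t", index=False)
            kozak_tally = tally_contexts(contexts)
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # --- PTC -----------------------------------------------------------
        stage = "ptc"
        try:
            reports = [
                ptc_scan(by_id[o.host_id], config.downstream_min) for o in unique
            ]
            pd.DataFrame(
                [
                    {
                        "host_id": r.host_id,
                        "first_stop_start": r.first_stop_span[0]
                        if r.first_stop_span else "",
                        "first_stop_end": r.first_stop_span[1]
                        if r.first_stop_span else "",
                        "first_stop_codon": r.first_stop_codon or "",
                        "downstream_long_orf": r.downstream_long_orf,
                        "longest_downstream_orf_codons":
                            r.longest_downstream_orf_codons,
                    }
                    for r in reports
                ],
            ).to_csv(gdir / "ptc.tsv", sep="\t", index=False)
            span_counts: Dict[str, int] = {}
            for r in reports:
                key = (
                    f"{r.first_stop_span[0]}-{r.first_stop_span[1]}"
                    if r.first_stop_span
                    else "none"
                )
                span_counts[key] = span_counts.get(key, 0) + 1
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # --- robust-table subset -------------------------------------------
        stage = "tables"
        robust_nuclear: Dict[str, CodonUsageTable] = {}
        for species, t in nuclear_tables.items():
            try:
                ok = table_is_robust(t)
            except MissingTableMetadata:
                log.warning("nuclear table for %s lacks metadata; treated as "
                            "not robust", species)
                ok = False
            if ok:
                robust_nuclear[species] = t

        # --- adaptation -----------------------------------------------------
        stage = "adaptation"
        try:
            adapt_rows = []
            cai_verdicts: Dict[str, int] = {}
            rcdi_verdicts: Dict[str, int] = {}
            for orf in unique:
                species = by_id[orf.host_id].species
                ref = robust_nuclear.get(species)
                if ref is None:
                    continue
                gene_seed = int(seed_rng.integers(2**31))
                for fn, tally in ((ecai, cai_verdicts), (ercdi, rcdi_verdicts)):
                    res: AdaptationResult = fn(
                        orf.nt_seq,
                        ref,
                        n_random=config.n_random,
                        alpha=config.alpha,
                        seed=gene_seed,
                    )
                    tally[res.verdict] = tally.get(res.verdict, 0) + 1
                    adapt_rows.append(
                        {
                            "host_id": orf.host_id,
                            "species": species,
                            "metric": res.metric,
                            "statistic": res.statistic,
                            "expected": res.expected,
                            "upper": res.upper,
                            "lower": res.lower,
                            "verdict": res.verdict,
                            "n_random": res.n_random,
                            "seed": res.seed,
                        }
                    )
            pd.DataFrame(
                adapt_rows,
                columns=[
                    "host_id", "species", "metric", "statistic", "expected",
                    "upper", "lower", "verdict", "n_random", "seed",
                ],
            ).to_csv(gdir / "adaptation.tsv", sep="\t", index=False)
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # --- similarity + tests ---------------------------------------------
        stage = "similarity"
        try:
            sim_records, _skipped = build_similarity_table(
                unique, records, nuclear_tables, mito_tables
            )
            pd.DataFrame([asdict(r) for r in sim_records]).to_csv(
                gdir / "similarity.tsv", sep="\t", index=False
            )
            test_rows = []
            if sim_records:
                for res in run_similarity_tests(sim_records):
                    test_rows.append(asdict(res))
            pd.DataFrame(
                test_rows,
                columns=["comparison", "n", "statistic", "p_value",
                         "alternative", "method"],
            ).to_csv(gdir / "tests.tsv", sep="\t", index=False)
        except Exception as exc:
            raise StageError(stage, exc) from exc

        frame_counts: Dict[str, int] = {}
        for o in all_hits:
            frame_counts[str(o.frame)] = frame_counts.get(str(o.frame), 0) + 1
        prevalence = summarize_prevalence(
            {group: (len(per_host), len(records))}
        )[group]
        summary["groups"][group] = {
            **prevalence,
            "frame_counts": frame_counts,
            "n_unique": len(unique),
            "duplicate_groups": {
                rep: members
                for rep, members in groups_map.items()
                if len(members) > 1
            },
            "table2_orf_count": len(table2_hits),
            "kozak": kozak_tally,
            "ptc_span_counts": span_counts,
            "downstream_long_orf_count": sum(
                r.downstream_long_orf for r in reports
            ),
            "n_adaptation_species": len(
                {r["species"] for r in adapt_rows}
            ),
            "cai_verdicts": cai_verdicts,
            "rcdi_verdicts": rcdi_verdicts,
            "similarity_n": len(sim_records),
            "similarity_tests": test_rows,
        }

    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    return summary
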