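"""Run the whole analysis on a generated two-cohort study set.

Generates a desk-scale fixture (two taxon groups with planted nested
ORFs, redundant accessions and per-species reference tables), runs every
stage, and prints the headline numbers from the summary report.
"""

import json
import tempfile
from pathlib import Path

import numpy as np

from nestorf import PipelineConfig, SyntheticSpec, generate_study_set, run_all

rng = np.random.default_rng(53)
spec_a = SyntheticSpec(n_positive=6, n_negative=50, n_duplicates=1,
                       kozak_class={"adequate": 3, "weak": 3},
                       group="Primates", id_prefix="P")
spec_b = SyntheticSpec(n_positive=10, n_negative=40,
                       kozak_class={"adequate": 8, "weak": 2},
                       group="Rodentia", id_prefix="R")

with tempfile.TemporaryDirectory() as tmp:
    study = generate_study_set(spec_a, spec_b, Path(tmp) / "study", rng,
                               n_robust_nuclear=(4, 6))
    config = PipelineConfig(
        fasta={g: str(p) for g, p in study.fasta.items()},
        meta=str(study.meta),
        nuclear_dir=str(study.nuclear_dir),
        mito_dir=str(study.mito_dir),
        out_dir=str(Path(tmp) / "out"),
        n_random=200,
        seed=1,
    )
    summary = run_all(config)

for group, g in summary["groups"].items():
    print(f"\n{group}: {g['n_positive']}/{g['n_total']} ORF-positive "
          f"({g['pct_positive']}%), {g['n_unique']} unique after "
          "consolidation")
    print(f"  frames: {g['frame_counts']}   "
          f"mito-code control scan: {g['table2_orf_count']} ORFs")
    print(f"  Kozak classes: {g['kozak']['strength']}")
    print(f"  premature-stop spans: {g['ptc_span_counts']}")
    print(f"  CAI verdicts: {g['cai_verdicts']}   "
          f"RCDI verdicts: {g['rcdi_verdicts']}")
    for t in g["similarity_tests"]:
        print(f"  {t['comparison']}: p = {t['p_value']:.4g}")

print("\nEvery number above is recomputed from the generated sequences; "
      "the manifest guarantees the planted ground truth.")
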