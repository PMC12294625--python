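"""RSCU cosine similarity of host and nested genes vs. two reference
sets, with the paired one-tailed Wilcoxon tests.

Twelve species are simulated the way the cohort is modelled: each host
gene follows its species' mitochondrial codon law, each nested gene a
neutral law, and both are compared against the species' nuclear and
mitochondrial usage tables.
"""

import numpy as np

from nestorf import (
    CdsRecord,
    NestedOrf,
    build_similarity_table,
    generate_usage_table,
    run_similarity_tests,
    sample_coding_sequence,
)
from nestorf.synthetic_data import make_reference_laws

rng = np.random.default_rng(41)
hosts, orfs, nuclear, mito = [], [], {}, {}
for i, (law_nuc, law_mito) in enumerate(make_reference_laws(12, rng)):
    species = f"Species {i:02d}"
    host_law = {c: w for c, w in law_mito.items()
                if c not in ("TAA", "TAG", "AGA", "AGG")}
    host_seq = sample_coding_sequence(host_law, 380, rng, code_basis=2)
    orf_seq = sample_coding_sequence("uniform", 190, rng) + "TAA"
    hosts.append(CdsRecord(id=f"H{i:02d}", species=species, seq=host_seq))
    orfs.append(NestedOrf(host_id=f"H{i:02d}", frame=3, start_nt=3,
                          end_nt=2 + len(orf_seq), length_codons=190,
                          nt_seq=orf_seq, aa_seq="X" * 190))
    nuclear[species] = generate_usage_table(law_nuc, 40, 400.0, "nuclear",
                                            rng, species=species)
    mito[species] = generate_usage_table(law_mito, 13, 300.0,
                                         "mitochondrial", rng, species=species)

records, _ = build_similarity_table(orfs, hosts, nuclear, mito)
mean = lambda attr: np.mean([getattr(r, attr) for r in records])
print(f"mean similarity, host vs mito refs:    {mean('sim_cytb_mito'):.4f}")
print(f"mean similarity, host vs nuclear refs: {mean('sim_cytb_nuclear'):.4f}")
print(f"mean similarity, nested vs nuclear:    {mean('sim_ncytb_nuclear'):.4f}")
print(f"mean similarity, nested vs mito:       {mean('sim_ncytb_mito'):.4f}")

print("\none-tailed Wilcoxon signed-rank tests (n = 12 species):")
for res in run_similarity_tests(records):
    print(f"  {res.comparison}: p = {res.p_value:.4g} ({res.method})")
print("\nHost genes track the mitochondrial usage they evolved under; the "
      "nested genes, constrained by their host's sequence, track neither "
      "reference set well.")
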