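"""Classify translation-initiation strength of nested-ORF start codons.

The -3 purine and +4 G are the key determinants; the full GCCRCCAUGG
motif defines the optimal tier.
"""

import numpy as np

from nestorf import (
    SyntheticSpec,
    classify,
    extract_context,
    generate_host,
    scan_nested_orfs,
    tally_contexts,
)
from nestorf.kozak import annotate

rng = np.random.default_rng(23)
spec = SyntheticSpec(n_positive=1, n_negative=0)

contexts = []
for i, cls in enumerate(["adequate"] * 3 + ["weak"] * 2):
    record, _ = generate_host(spec, rng, record_id=f"K{i}", kozak_target=cls)
    orf = scan_nested_orfs(record)[0]
    ctx = annotate(extract_context(record.seq, orf.start_nt, record.id))
    contexts.append(ctx)
    print(f"{ctx.host_id}: {ctx.upstream} ATG {ctx.plus4}  "
          f"(-3 = {ctx.minus3}, +4 = {ctx.plus4})  ->  {ctx.strength}")

tally = tally_contexts(contexts)
print("\nclass tally:", tally["strength"])
print("-3 base composition:", tally["minus3"])
print("+4 base composition:", tally["plus4"])
print("\nWeak or adequate contexts (pyrimidine at -3 and/or non-G at +4) "
      "initiate inefficiently — a gene with only such contexts is unlikely "
      "to be strongly expressed.")
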