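"""Ask what a cytosolic ribosome would do with the host's own frame.

The host gene is read with UGA = Trp inside mitochondria, but UGA is a
stop codon for cytosolic ribosomes.  The PTC scan finds the first
standard-code stop in the host frame and checks whether any downstream
AUG could rescue a product longer than 50 codons.
"""

import numpy as np

from nestorf import SyntheticSpec, generate_host, ptc_scan

rng = np.random.default_rng(11)
spec = SyntheticSpec(n_positive=1, n_negative=0)
record, _ = generate_host(spec, rng, record_id="DEMO002")

report = ptc_scan(record, min_downstream_codons=50)
print(f"host: {report.host_id}")
print(f"first standard-code stop in frame +1: span {report.first_stop_span}, "
      f"codon {report.first_stop_codon}")
print(f"longest AUG-initiated ORF downstream of the stop: "
      f"{report.longest_downstream_orf_codons} codons")
print(f"downstream ORF exceeds 50 codons: {report.downstream_long_orf}")
print("\nAn early TGA (Trp in the organelle) truncates cytosolic translation "
      "of the host frame at ~30 codons, leaving the downstream +3-frame "
      "region free of competing initiation — the architecture that makes a "
      "nested cytosolic ORF conceivable at all.")
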