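# Methods

## Scope and model

`nestorf` analyses nested alternative ORFs inside a mitochondrial
protein-coding host CDS. The analysis treats one host sequence at a time
(the annotated CDS only — no genome context, no reverse complement) and
asks four questions: does a qualifying nested ORF exist, would the host
frame itself terminate early under the standard code, how strong is the
nested ORF's initiation context, and is its codon usage adapted to any
reference gene set.

Coordinates are 1-based and inclusive. Frame +1 is the annotated host
frame; frame *k* places codons starting at nucleotide *k*. The internal
alphabet is DNA; `U` is normalised to `T` on input, because the
literature mixes RNA and DNA notation for the same motifs.

## Screening rules

A nested ORF is an ATG-initiated, stop-terminated stretch in frame +2 or
+3, read under the standard code, of at least `min_codons` codons.
Decisions that the published criteria leave open, resolved here once:

* **Length is stop-exclusive.** `length_codons` equals the encoded
  protein length including the initiator Met, so the 150-codon threshold
  is a protein-length threshold. This keeps reported ORF lengths equal to
  reported protein lengths.
* **5′-most ATG per stop-bounded segment.** Within each segment between
  consecutive in-frame stops, only the longest (5′-most-initiated) ORF is
  a candidate; internal ATGs are not reported separately.
* **A terminal stop is required** by default: the input is a lone CDS, so
  a run-off ORF cannot be verified. `include_incomplete=True` retains
  them, flagged.
* **Only ATG initiates**, even when scanning under the mitochondrial code
  (the parallel control scan): the Kozak analysis downstream presumes
  AUG, and allowing AUA starts would make the two scans incommensurable.
* Ties in per-frame selection go to the smallest start coordinate.

Duplicate consolidation operates on exact nucleotide identity of the ORF
(nucleotide identity implies protein identity); the representative of
each identity group is the lexicographically smallest host accession.

The premature-stop scan reports the first frame-1 standard-code stop and
then the longest ATG-initiated frame-1 ORF strictly downstream of it
(stop-terminated or running to the sequence end, length again
stop-exclusive and Met-inclusive); "long" means strictly more than
`min_downstream_codons` (default 50).

## Kozak classification

Contexts are the bases at −6..−1 and +4 around the ATG. Four nested
tiers: optimal `GCCRCCATGG`; strong `NNNRNNATGG`; adequate
`NNNRNNATG(A/C/T)` or `NNN(C/T)NNATGG`; weak `NNN(C/T)NNATG(A/C/T)`.
Precedence is optimal > strong > adequate > weak, so only −3 and +4
decide the lower three tiers and the full −6..−1 motif is required only
for optimal (an optimal-like motif with a pyrimidine at −3 is therefore
adequate). Contexts with fewer than three upstream bases or no +4 base
are `undetermined` and excluded from positional tallies (never silently
classified).

## Codon-usage statistics

RSCU, CAI/eCAI and RCDI/eRCDI are implemented from their definitions
(see README for formulas). Numerical choices:

* **Synonym basis.** All RSCU vectors — genes and both reference tables —
  use standard-code families over a common 59-codon included set (61
  sense codons minus ATG and TGG), so that vectors are commensurable in
  cosine comparisons. A table-2 basis (`code_basis=2`) is available for
  sensitivity analysis; its families differ (ATA→Met, TGA→Trp, AGA/AGG
  removed).
* **Pseudocounts.** Zero-count reference codons receive 0.5 before weight
  or frequency normalisation, keeping CAI weights positive and RCDI
  denominators finite. Families entirely unobserved in a gene get the
  neutral RSCU 1 rather than NaN (short genes routinely miss amino
  acids).
* **Exclusions.** CAI excludes stop codons and the single-codon families
  ATG/TGG, whose weights are 1 by construction and would only inflate the
  index. RCDI runs over all sense codons present in the query
  (single-codon families contribute neutral terms).
* **Mock genes.** The eCAI/eRCDI null preserves the query's amino-acid
  multiset exactly and draws each residue's codon within its family with
  probability proportional to the product of the query's *global*
  mononucleotide frequencies over the codon's three positions. Global
  (not positional) frequencies are the simplest faithful reading of
  "corrects amino-acid and base bias"; the sequence-level generator is
  exposed as `generate_mock` for inspection.
* **Limits.** `n_random` defaults to 500. The upper one-sided limit is
  the normal approximation `mean + z_{1-α}·sd` (z = 1.6449 at α = 0.05);
  an empirical-percentile method is available since the exact
  distribution fit used by the original web services is not published.
  The lower limit is `2·expected − upper` by construction, so the
  identity holds exactly in every result. With sd = 0 (degenerate
  reference) the band collapses to a point and any equal statistic is
  "indistinguishable". Verdicts are per-gene fixed-band comparisons; no
  multiple-testing correction is applied across genes, matching the
  analysis this package reproduces.
* **Determinism.** Every Monte-Carlo routine takes a seed; identical
  inputs and seed reproduce results bit-identically. The pipeline derives
  one sub-seed per gene from its master seed.

## Statistical tests

The paired Wilcoxon signed-rank test drops zero differences, enumerates
the exact null when the effective n ≤ 25 with no tied absolute
differences, and otherwise uses a tie- and continuity-corrected normal
approximation (delegated to `scipy.stats.wilcoxon`; the test suite checks
the exact branch against a full 2ⁿ sign-flip enumeration). Test
directions are fixed to the study hypotheses (e.g. host-vs-mitochondrial
similarity greater than host-vs-nuclear). Spearman's ρ uses average ranks
and the t-approximation p-value. Pairwise identity/similarity of
pre-aligned proteins is a column scan — alignment construction is out of
scope — with similar-residue groups {GAVLI, FYW, CM, ST, KRH, DENQ, P}.

## Reference-table robustness

A nuclear reference table qualifies for adaptation/similarity analyses
when it derives from **at least 30** CDSs whose average length **strictly
exceeds 100** codons (a literal reading of "minimum of 30" and "exceeded
100"). Tables lacking the metadata raise rather than passing silently;
the pipeline logs and excludes them. Mitochondrial tables are not
filtered — the organellar gene set is small and fixed — and only gate on
presence.

## Synthetic data: what it emulates and what it does not

The generator produces hosts that are clean mitochondrial-code CDSs
(1,140 nt by default, the length of mammalian *cytb*; start ATG, no
internal table-2 stop, terminal stop) built codon-wise from a
mitochondrial codon law, optionally with:

* a frame-1 TGA planted at a chosen codon (default codon 30,
  nt 88–90) that is guaranteed to be the *first* standard-code stop of
  the host frame;
* an embedded +2/+3-frame standard-code ORF of requested length
  (default 150–239 codons) and Kozak class, written over the host and
  followed by synonymous repair of any mitochondrial-code stops the
  overwrite introduced into frame 1 (the Kozak −3/+4 bases are planted by
  construction: +4 is realised as the first base of the ORF's second
  codon, never edited afterwards);
* for ORF-positive hosts, no downstream frame-1 standard-code ATG-ORF
  longer than 50 codons (enforced by inserting TGA — tryptophan to the
  mitochondrial ribosome — into free host codons) and no qualifying ORF
  under the parallel mitochondrial-code scan, so the control scan stays
  empty as in the emulated architecture.

Construction is validated record-by-record by running the real scanner,
classifier and PTC scan; any mismatch triggers bounded resampling (1,000
attempts) and an explicit failure beyond that. The manifest is therefore
authoritative ground truth.

Reference laws decompose per-species log-weights into a study-wide
component (sd 1.0), a gene-set offset (sd 0.8) distinguishing nuclear
from mitochondrial usage, and a per-species offset (sd 0.3): the two gene
sets are biased differently but remain positively correlated, as in real
genomes. These values were chosen once as a realistic regime in which a
host gene drawn from its species' mitochondrial law is closer to the
mitochondrial than the nuclear reference while a neutral nested gene
trails both. Table counts are multinomial draws of size
`n_cds · avg_len`.

What the generator does **not** emulate: phylogenetic correlation between
species (records are i.i.d. given the study-level law), indels and
alignment artefacts, selection within the nested ORF, GenBank annotation
errors, and the dinucleotide/codon-pair structure of real sequences.
Passing round-trip tests therefore demonstrates the pipeline's
correctness on data satisfying its stated assumptions, not the
biological conclusions themselves; real-data replication additionally
requires the public accession lists and usage tables.

A known property of the Monte-Carlo verdicts on synthetic cohorts: the
neutral nested genes are drawn uniformly among synonyms, while the null
mocks draw codons by base-frequency products, so null-band coverage of
the neutral genes is slightly below nominal (roughly 75–95% inside the
95% band rather than exactly 95%). This mirrors the behaviour of the
method on real genes, which are not drawn from the null either.

## Problem sizes

The shipped tests and the acceptance script run entirely on generated
data at the study's own scale: two cohorts of 289 and 380 records with
28 (+3 redundant) and 77 (+1 redundant) ORF-positive hosts, adaptation
statistics at `n_random = 500` for the 12 + 28 species with robust
nuclear tables, and oracle-equivalence checks over 1,000 random
sequences of 300–2,000 nt. A full acceptance run completes in well under
a minute on a single CPU.
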