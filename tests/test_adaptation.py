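import math
from collections import Counter

import numpy as np
import pytest

from nestorf.adaptation import (
    cai,
    ecai,
    ercdi,
    generate_mock,
    rcdi,
    relative_adaptiveness,
)
from nestorf.codon_metrics import synonym_families
from nestorf.io_formats import ALL_CODONS, CodonUsageTable

from .oracles import cai_log_oracle

UNIFORM_TABLE = CodonUsageTable(
    codon_counts={c: 100.0 for c in ALL_CODONS}, species="uniform"
)


def table_with(counts, **kwargs):
    base = {c: 0.0 for c in ALL_CODONS}
    base.update(counts)
    base.setdefault("GGG", base.get("GGG", 0) or 1.0)  # keep the table non-empty
    return CodonUsageTable(codon_counts=base, **kwargs)


def preferred_codons(ref):
    """The most frequent codon of each multi-codon family."""
    out = {}
    for aa, fam in synonym_families(1).items():
        if len(fam) > 1:
            out[aa] = max(fam, key=lambda c: ref.codon_counts[c])
    return out


class TestWeights:
    def test_family_ratio(self):
        ref = table_with({"TTT": 80.0, "TTC": 20.0})
        ra = relative_adaptiveness(ref)
        assert ra.w["TTT"] == pytest.approx(1.0)
        assert ra.w["TTC"] == pytest.approx(0.25)

    def test_zero_count_pseudocount(self):
        ref = table_with({"TTT": 10.0, "TTC": 0.0})
        ra = relative_adaptiveness(ref)
        assert ra.w["TTC"] == pytest.approx(0.05)  # 0.5 / 10

    def test_uniform_reference_gives_unit_weights(self):
        ra = relative_adaptiveness(UNIFORM_TABLE)
        assert all(w == pytest.approx(1.0) for w in ra.w.values())

    def test_excluded_set(self):
        ra = relative_adaptiveness(UNIFORM_TABLE)
        assert {"ATG", "TGG", "TAA", "TAG", "TGA"} <= set(ra.excluded)
        assert "ATG" not in ra.w


class TestCai:
    def test_all_preferred_gene_scores_one(self, rng):
        ref = table_with({"TTT": 80.0, "TTC": 20.0, "GGA": 90.0, "GGC": 10.0})
        ra = relative_adaptiveness(ref)
        gene = "TTTGGA" * 30
        assert cai(gene, ra) == pytest.approx(1.0)

    def test_alternating_half_weight_gene(self):
        ref = table_with({"TTT": 80.0, "TTC": 40.0})
        ra = relative_adaptiveness(ref)
        gene = "TTTTTC" * 25  # equal counts of w=1 and w=0.5 codons
        assert cai(gene, ra) == pytest.approx(math.sqrt(0.5))

    def test_matches_log_domain_oracle(self, rng):
        ref = table_with(
            {c: float(n) for c, n in zip(ALL_CODONS,
                                         rng.integers(1, 100, size=64))}
        )
        ra = relative_adaptiveness(ref)
        codons = [ALL_CODONS[i] for i in rng.integers(0, 64, size=300)]
        gene = "".join(codons)
        assert cai(gene, ra) == pytest.approx(
            cai_log_oracle(codons, ra.w, ra.excluded), abs=1e-12
        )

    def test_monotone_under_preferred_substitution(self):
        ref = table_with({"TTT": 80.0, "TTC": 40.0, "GGA": 50.0, "GGC": 25.0})
        ra = relative_adaptiveness(ref)
        worse = "TTCGGC" * 10
        better = "TTTGGC" * 10
        assert cai(better, ra) > cai(worse, ra)

    def test_only_excluded_codons_is_an_error(self):
        ra = relative_adaptiveness(UNIFORM_TABLE)
        with pytest.raises(ValueError):
            cai("ATGTGG", ra)


class TestMocks:
    def test_uniform_base_freqs_equal_synonym_probabilities(self, rng):
        freqs = {b: 0.25 for b in "ACGT"}
        draws = Counter()
        for _ in range(400):
            draws[generate_mock("K", freqs, rng=rng)] += 1
        # Lys is AAA/AAG; uniform base bias makes them equiprobable
        assert set(draws) == {"AAA", "AAG"}
        assert abs(draws["AAA"] - 200) < 60

    def test_degenerate_base_freqs(self, rng):
        freqs = {"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0}
        assert generate_mock("K", freqs, rng=rng) == "AAA"

    def test_amino_acid_composition_preserved(self, rng):
        from nestorf.genetic_code import STANDARD_CODE, translate

        profile = "MKKLLLWFFD"
        mock = generate_mock(profile, {b: 0.25 for b in "ACGT"}, rng=rng)
        assert Counter(translate(mock, STANDARD_CODE)) == Counter(profile)

    def test_gc_tracks_base_freqs_monotonically(self, rng):
        profile = "LLLLPPPPAAAARRRRGGGG" * 5
        means = []
        for gc in (0.3, 0.5, 0.7):
            freqs = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2,
                     "T": (1 - gc) / 2}
            gcs = []
            for _ in range(30):
                mock = generate_mock(profile, freqs, rng=rng)
                gcs.append(sum(mock.count(b) for b in "GC") / len(mock))
            means.append(np.mean(gcs))
        assert means[0] < means[1] < means[2]


class TestEcai:
    def test_degenerate_uniform_reference(self):
        gene = "TTTGGA" * 30
        res = ecai(gene, UNIFORM_TABLE, n_random=50, seed=1)
        assert res.statistic == pytest.approx(1.0)
        assert res.expected == pytest.approx(1.0)
        assert res.upper == res.lower == res.expected
        assert res.verdict == "indistinguishable"

    def test_seeded_determinism_is_bit_identical(self, rng):
        ref = table_with(
            {c: float(n) for c, n in zip(ALL_CODONS,
                                         rng.integers(1, 100, size=64))}
        )
        gene = "".join(ALL_CODONS[i] for i in rng.integers(0, 61, size=200))
        a = ecai(gene, ref, n_random=100, seed=42)
        b = ecai(gene, ref, n_random=100, seed=42)
        assert a == b

    def test_lower_limit_identity(self, rng):
        ref = table_with(
            {c: float(n) for c, n in zip(ALL_CODONS,
                                         rng.integers(1, 100, size=64))}
        )
        gene = "".join(ALL_CODONS[i] for i in rng.integers(0, 61, size=200))
        for method in ("normal", "percentile"):
            res = ecai(gene, ref, n_random=100, seed=7, method=method)
            assert res.lower == 2 * res.expected - res.upper
            assert res.lower <= res.expected <= res.upper

    def test_all_preferred_gene_is_positively_adapted(self, rng):
        skewed = {c: 1.0 for c in ALL_CODONS}
        ref = CodonUsageTable(codon_counts=skewed, species="skew")
        counts = {c: float(n) for c, n in zip(
            ALL_CODONS, rng.integers(1, 100, size=64))}
        ref = CodonUsageTable(codon_counts=counts, species="skew")
        pref = preferred_codons(ref)
        gene = "".join(pref[aa] for aa in sorted(pref)) * 10
        res = ecai(gene, ref, n_random=200, seed=5)
        assert res.statistic == pytest.approx(1.0)
        assert res.verdict == "positive_adaptation"

    def test_alpha_one_half_collapses_band(self, rng):
        ref = table_with(
            {c: float(n) for c, n in zip(ALL_CODONS,
                                         rng.integers(1, 100, size=64))}
        )
        gene = "".join(ALL_CODONS[i] for i in rng.integers(0, 61, size=150))
        res = ecai(gene, ref, n_random=100, alpha=0.5, seed=9)
        assert res.upper == pytest.approx(res.expected, abs=1e-12)

    def test_n_random_floor(self):
        with pytest.raises(ValueError):
            ecai("TTTGGA" * 30, UNIFORM_TABLE, n_random=1)


class TestRcdi:
    def test_frequency_matched_query_scores_one(self):
        ref = table_with({"TTT": 80.0, "TTC": 20.0})
        gene = "TTT" * 8 + "TTC" * 2
        assert rcdi(gene, ref) == pytest.approx(1.0)

    def test_closed_form_point_eight_family(self):
        ref = table_with({"TTT": 80.0, "TTC": 20.0})
        gene = "TTT" * 20
        assert rcdi(gene, ref) == pytest.approx(1.25)

    def test_never_below_one_on_random_instances(self, rng):
        refs = []
        for _ in range(20):
            counts = {c: float(n) for c, n in zip(
                ALL_CODONS, rng.integers(0, 100, size=64))}
            counts["TTT"] += 1.0
            refs.append(CodonUsageTable(codon_counts=counts))
        sense = [c for c in ALL_CODONS if c not in ("TAA", "TAG", "TGA")]
        for _ in range(500):
            gene = "".join(sense[i] for i in rng.integers(0, 61, size=30))
            assert rcdi(gene, refs[int(rng.integers(0, 20))]) >= 1 - 1e-12


class TestErcdi:
    def test_seeded_determinism(self, rng):
        ref = table_with(
            {c: float(n) for c, n in zip(ALL_CODONS,
                                         rng.integers(1, 100, size=64))}
        )
        gene = "".join(ALL_CODONS[i] for i in rng.integers(0, 61, size=150))
        assert ercdi(gene, ref, n_random=80, seed=3) == \
            ercdi(gene, ref, n_random=80, seed=3)

    def test_composition_matched_genes_are_mostly_composition_driven(self, rng):
        # genes drawn uniformly among synonyms against a uniform reference:
        # the 95% null band should cover the large majority of them
        sense = [c for c in ALL_CODONS if c not in ("TAA", "TAG", "TGA")]
        verdicts = []
        for _ in range(10):
            gene = "".join(sense[i] for i in rng.integers(0, 61, size=300))
            verdicts.append(ercdi(gene, UNIFORM_TABLE, n_random=200,
                                  seed=11).verdict)
        assert verdicts.count("composition_driven") >= 8

    def test_reference_rare_codons_are_deoptimized(self, rng):
        counts = {c: 1.0 for c in ALL_CODONS}
        pref = {}
        for aa, fam in synonym_families(1).items():
            if len(fam) > 1:
                counts[fam[0]] = 95.0  # one heavily preferred codon per family
        ref = CodonUsageTable(codon_counts=counts)
        # build the gene from each family's *rare* codons only
        gene = "".join(
            fam[1] for aa, fam in sorted(synonym_families(1).items())
            if len(fam) > 1
        ) * 12
        res = ercdi(gene, ref, n_random=200, seed=13)
        assert res.statistic > res.upper
        assert res.verdict == "deoptimized"
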