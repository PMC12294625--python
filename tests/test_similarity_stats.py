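import numpy as np
import pytest
from scipy import stats

from nestorf.codon_metrics import RscuVector, codon_counts, rscu
from nestorf.io_formats import ALL_CODONS, CdsRecord, CodonUsageTable
from nestorf.orf_screen import NestedOrf
from nestorf.similarity_stats import (
    DEFAULT_SIMILAR_GROUPS,
    build_similarity_table,
    cosine_similarity,
    dissimilarity_index,
    pairwise_identity_similarity,
    run_similarity_tests,
    spearman,
    wilcoxon_signed_rank,
)
from nestorf.synthetic_data import (
    generate_usage_table,
    make_reference_laws,
    sample_coding_sequence,
)

from .oracles import (
    identity_similarity_oracle,
    spearman_oracle,
    wilcoxon_exact_oracle,
)


def vec(values):
    included = tuple(sorted(values))
    return RscuVector(values=values, code_basis=1, included=included)


class TestCosine:
    def test_identity(self):
        v = vec({"TTT": 1.5, "TTC": 0.5, "GGA": 2.0})
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_supports(self):
        a = vec({"TTT": 1.0, "TTC": 0.0})
        b = vec({"TTT": 0.0, "TTC": 2.0})
        assert cosine_similarity(a, b) == pytest.approx(0.0)

    def test_scale_invariance_and_symmetry(self, rng):
        names = list(ALL_CODONS[:20])
        x = rng.random(20) + 0.1
        y = rng.random(20) + 0.1
        a = vec(dict(zip(names, x)))
        b = vec(dict(zip(names, y)))
        c = vec(dict(zip(names, 3.7 * y)))
        assert cosine_similarity(a, b) == pytest.approx(cosine_similarity(b, a))
        assert cosine_similarity(a, b) == pytest.approx(cosine_similarity(a, c))

    def test_matches_dot_product_oracle(self, rng):
        names = list(ALL_CODONS[:30])
        for _ in range(20):
            x, y = rng.random(30), rng.random(30)
            a, b = vec(dict(zip(names, x))), vec(dict(zip(names, y)))
            xa = np.array([a.values[c] for c in a.included])
            ya = np.array([b.values[c] for c in b.included])
            expected = xa @ ya / (np.linalg.norm(xa) * np.linalg.norm(ya))
            r = cosine_similarity(a, b)
            assert r == pytest.approx(expected, abs=1e-12)
            assert dissimilarity_index(a, b) == pytest.approx((1 - r) / 2)

    def test_zero_vector_rejected(self):
        a = vec({"TTT": 0.0, "TTC": 0.0})
        with pytest.raises(ValueError):
            cosine_similarity(a, a)

    def test_mismatched_codon_sets_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(vec({"TTT": 1.0}), vec({"TTC": 1.0}))


class TestWilcoxon:
    def test_twelve_positive_differences(self):
        x = np.arange(1.0, 13.0)
        res = wilcoxon_signed_rank(x + np.linspace(0.1, 1.2, 12), x,
                                   alternative="greater")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 4096)
        assert round(res.p_value, 4) == 0.0002

    def test_all_zero_differences_is_an_error(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 5.0], [1.0, 1.0, 4.0])
        assert res.n == 2

    def test_matches_bruteforce_enumeration(self, rng):
        for n in range(3, 13):
            for _ in range(5):
                x = rng.random(n) * 2
                y = rng.random(n) * 2
                for alt in ("greater", "less"):
                    res = wilcoxon_signed_rank(x, y, alternative=alt)
                    w, p = wilcoxon_exact_oracle(x - y, alt)
                    assert res.method == "exact"
                    assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_large_or_tied_samples_use_normal_approximation(self, rng):
        x = rng.random(40)
        y = rng.random(40)
        res = wilcoxon_signed_rank(x, y)
        assert res.method == "normal_approx"
        tied = wilcoxon_signed_rank([2.0, 3.0, 4.0], [1.0, 2.0, 5.0])
        assert tied.method == "normal_approx"


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 4], [10, 20, 25, 90])
        assert rho == pytest.approx(1.0)

    def test_reversed(self):
        rho, _ = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        for _ in range(10):
            x = rng.random(30)
            y = rng.random(30)
            rho, p = spearman(x, y)
            assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)
            assert 0 <= p <= 1

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity_similarity("MKLV", "MKLV") == (100.0, 100.0)

    def test_similar_group_rule(self):
        ident, sim = pairwise_identity_similarity("KR", "RK")
        assert ident == 0.0
        assert sim == 100.0

    def test_gap_columns(self):
        # double-gap column ignored; single-gap column counts in denominator
        ident, sim = pairwise_identity_similarity("M-K-", "M--K")
        assert ident == pytest.approx(100 / 3)
        assert sim == pytest.approx(100 / 3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pairwise_identity_similarity("MK", "MKL")

    def test_matches_column_scan_oracle_and_bounds(self, rng):
        alphabet = "ACDEFGHIKLMNPQRSTVWY-"
        for _ in range(50):
            n = int(rng.integers(5, 60))
            a = "".join(alphabet[i] for i in rng.integers(0, 21, size=n))
            b = "".join(alphabet[i] for i in rng.integers(0, 21, size=n))
            if all(x == "-" and y == "-" for x, y in zip(a, b)):
                continue
            got = pairwise_identity_similarity(a, b)
            expected = identity_similarity_oracle(a, b, DEFAULT_SIMILAR_GROUPS)
            assert got == pytest.approx(expected)
            assert 0 <= got[0] <= got[1] <= 100


class TestSimilarityTable:
    def _cohort(self, rng, n_species=8, cytb_from="mito"):
        laws = make_reference_laws(n_species, rng)
        hosts, orfs = [], []
        nuclear, mito = {}, {}
        for i, (law_nuc, law_mito) in enumerate(laws):
            species = f"Species {i:02d}"
            host_law = law_mito if cytb_from == "mito" else law_nuc
            host_seq = sample_coding_sequence(
                {c: w for c, w in host_law.items()
                 if c not in ("TAA", "TAG", "TGA")}, 380, rng)
            orf_seq = sample_coding_sequence("uniform", 180, rng) + "TAA"
            hosts.append(CdsRecord(id=f"H{i:02d}", species=species, seq=host_seq))
            orfs.append(
                NestedOrf(host_id=f"H{i:02d}", frame=3, start_nt=3,
                          end_nt=2 + len(orf_seq), length_codons=180,
                          nt_seq=orf_seq, aa_seq="X" * 180)
            )
            nuclear[species] = generate_usage_table(
                law_nuc, 40, 400.0, "nuclear", rng, species=species)
            mito[species] = generate_usage_table(
                law_mito, 13, 300.0, "mitochondrial", rng, species=species)
        return orfs, hosts, nuclear, mito

    def test_one_record_per_retained_species(self, rng):
        orfs, hosts, nuclear, mito = self._cohort(rng)
        records, skipped = build_similarity_table(orfs, hosts, nuclear, mito)
        assert len(records) == 8
        assert skipped == []
        for r in records:
            for value in (r.sim_ncytb_nuclear, r.sim_ncytb_mito,
                          r.sim_cytb_nuclear, r.sim_cytb_mito):
                assert 0.0 <= value <= 1.0

    def test_non_robust_nuclear_species_skipped_with_log(self, rng):
        orfs, hosts, nuclear, mito = self._cohort(rng, n_species=4)
        shallow = generate_usage_table(
            "uniform", 20, 400.0, "nuclear", rng, species=hosts[0].species)
        nuclear[hosts[0].species] = shallow
        records, skipped = build_similarity_table(orfs, hosts, nuclear, mito)
        assert len(records) == 3
        assert any("not robust" in s for s in skipped)

    def test_host_codon_law_drives_similarity_ordering(self, rng):
        orfs, hosts, nuclear, mito = self._cohort(rng, n_species=10)
        records, _ = build_similarity_table(orfs, hosts, nuclear, mito)
        mean_mito = np.mean([r.sim_cytb_mito for r in records])
        mean_nuc = np.mean([r.sim_cytb_nuclear for r in records])
        mean_orf_nuc = np.mean([r.sim_ncytb_nuclear for r in records])
        assert mean_mito > mean_nuc
        assert mean_nuc > mean_orf_nuc

    def test_paired_tests_report_all_four_comparisons(self, rng):
        orfs, hosts, nuclear, mito = self._cohort(rng, n_species=10)
        records, _ = build_similarity_table(orfs, hosts, nuclear, mito)
        results = run_similarity_tests(records)
        assert [r.comparison for r in results] == [
            "cytb_mito_vs_cytb_nuclear",
            "cytb_nuclear_vs_ncytb_nuclear",
            "cytb_mito_vs_ncytb_mito",
            "ncytb_nuclear_vs_ncytb_mito",
        ]
        assert all(0 <= r.p_value <= 1 for r in results)
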