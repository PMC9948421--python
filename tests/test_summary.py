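"""Cohort summary: landscape matrix, categories, and statistical kernels
checked against independent oracles."""
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from tmn.summary import (
    build_landscape,
    categorize_genes,
    chi_square_association,
    compare_cohort_frequencies,
    compare_groups,
    pairwise_phi,
    progression_changes,
)
from tmn.types import AnnotatedVariant, AnnotationBundle, Origin, VariantCall


def somatic(gene, sample, pos):
    return AnnotatedVariant(
        call=VariantCall(
            sample_id=sample, patient_id=sample.rsplit("-", 1)[0],
            sample_role="tmn_initial", chrom="1", pos=pos, ref="G", alt="A",
            vaf=0.2, depth=100, callers=frozenset({"gatk"}),
        ),
        annotation=AnnotationBundle(gene=gene),
        in_somatic_panel=True,
        origin=Origin.SOMATIC,
    )


class TestLandscape:
    def test_multi_hit_counts_as_multiple_variants(self):
        variants = [
            somatic("TP53", "p1-A", 1),
            somatic("TP53", "p1-A", 2),  # second distinct TP53 hit
            somatic("DNMT3A", "p1-A", 3),
        ]
        m = build_landscape(variants, ["p1-A"])
        assert m.per_sample_counts()["p1-A"] == 3
        assert m.counts.loc["TP53", "p1-A"] == 2

    def test_duplicate_key_counted_once(self):
        variants = [somatic("TP53", "p1-A", 1), somatic("TP53", "p1-A", 1)]
        m = build_landscape(variants, ["p1-A"])
        assert m.counts.loc["TP53", "p1-A"] == 1

    def test_no_variants_gives_empty_matrix(self):
        m = build_landscape([], ["p1-A", "p2-A"])
        assert m.counts.shape == (0, 2)
        assert (m.per_sample_counts() == 0).all()

    def test_disjoint_genes_block_structure(self):
        variants = [somatic("TP53", "p1-A", 1), somatic("ASXL1", "p2-A", 2)]
        m = build_landscape(variants, ["p1-A", "p2-A"])
        assert m.counts.loc["TP53", "p2-A"] == 0
        assert m.counts.loc["ASXL1", "p1-A"] == 0

    def test_unknown_sample_errors(self):
        with pytest.raises(ValueError, match="unknown sample"):
            build_landscape([somatic("TP53", "p9-A", 1)], ["p1-A"])

    def test_genes_ordered_by_patient_frequency_then_alphabet(self):
        variants = [
            somatic("ZZZ", "p1-A", 1), somatic("ZZZ", "p2-A", 2),
            somatic("AAA", "p3-A", 3), somatic("BBB", "p4-A", 4),
        ]
        m = build_landscape(variants, ["p1-A", "p2-A", "p3-A", "p4-A"])
        assert m.genes == ["ZZZ", "AAA", "BBB"]

    def test_longitudinal_pair_is_one_patient_two_samples(self):
        variants = [somatic("TP53", "p1-A", 1), somatic("TP53", "p1-B", 1)]
        m = build_landscape(variants, ["p1-A", "p1-B"])
        assert m.patient_frequency()["TP53"] == 1.0
        assert m.per_sample_counts().sum() == 2


class TestCategories:
    CMAP = {"TP53": "transcription factor", "SRSF2": "splicing factor",
            "SMC3": "cohesin"}

    def test_tp53_flags_transcription_factor(self):
        flags = categorize_genes({"p1": {"TP53"}}, self.CMAP)
        assert flags.loc["p1", "transcription factor"]
        assert not flags.loc["p1", "cohesin"]

    def test_no_variants_all_false(self):
        flags = categorize_genes({"p1": set()}, self.CMAP)
        assert not flags.loc["p1"].any()

    def test_two_categories_from_two_genes(self):
        flags = categorize_genes({"p1": {"SRSF2", "SMC3"}}, self.CMAP)
        assert flags.loc["p1", "splicing factor"] and flags.loc["p1", "cohesin"]

    def test_unmapped_gene_goes_to_other(self, caplog):
        with caplog.at_level("WARNING"):
            flags = categorize_genes({"p1": {"MYSTERY"}}, self.CMAP)
        assert flags.loc["p1", "other"]
        assert "MYSTERY" in caplog.text


class TestPairwisePhi:
    def test_identical_and_complementary_columns(self):
        f = pd.DataFrame({"a": [1, 1, 0, 0], "b": [1, 1, 0, 0], "c": [0, 0, 1, 1]})
        phi, p = pairwise_phi(f)
        assert phi.loc["a", "b"] == pytest.approx(1.0)
        assert phi.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(phi), 1.0)

    def test_balanced_table_gives_zero(self):
        f = pd.DataFrame({"a": [1, 1, 0, 0], "b": [1, 0, 1, 0]})
        phi, _ = pairwise_phi(f)
        assert phi.loc["a", "b"] == pytest.approx(0.0)

    def test_zero_variance_reported_missing(self):
        f = pd.DataFrame({"a": [1, 1, 1, 1], "b": [1, 0, 1, 0]})
        phi, _ = pairwise_phi(f)
        assert np.isnan(phi.loc["a", "b"])

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        f = pd.DataFrame(rng.integers(0, 2, size=(30, 5)), columns=list("abcde"))
        phi, p = pairwise_phi(f)
        assert np.allclose(phi, phi.T, equal_nan=True)
        assert (phi.abs().to_numpy()[~np.isnan(phi)] <= 1 + 1e-12).all()


class TestChiSquare:
    def test_perfect_association_statistic(self):
        # N(ad-bc)^2 / (row/col products) = 40*400^2/160000 = 40
        stat, p = chi_square_association([[20, 0], [0, 20]], yates=False)
        assert stat == pytest.approx(40.0)

    def test_independent_table_statistic_zero(self):
        stat, _ = chi_square_association([[10, 20], [5, 10]], yates=False)
        assert stat == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_expected_counts_oracle(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.integers(1, 40, size=(2, 2)).astype(float)
        stat, _ = chi_square_association(obs, yates=False)
        total = obs.sum()
        expected = np.outer(obs.sum(1), obs.sum(0)) / total
        oracle = ((obs - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(oracle)

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_association([[0, 0], [5, 10]])

    def test_yates_correction_shrinks_statistic(self):
        plain, _ = chi_square_association([[12, 5], [6, 14]], yates=False)
        corrected, _ = chi_square_association([[12, 5], [6, 14]], yates=True)
        assert corrected < plain


def enumeration_mw_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    pooled = sorted(a) + sorted(b)
    na = len(a)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}

    def u_of(idx):
        rank_sum = sum(ranks[pooled[i]] for i in idx)
        return rank_sum - na * (na + 1) / 2

    u_obs = u_of(range(na))
    n_total = len(pooled)
    u_max = na * (len(b))
    lo, hi = min(u_obs, u_max - u_obs), max(u_obs, u_max - u_obs)
    count = total = 0
    for idx in combinations(range(n_total), na):
        u = u_of(idx)
        total += 1
        count += u <= lo or u >= hi
    return count / total


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = compare_groups([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_singletons_p_one(self):
        _, p = compare_groups([5.0], [5.0])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pooled = rng.permutation(np.arange(10, dtype=float))
        a, b = pooled[:4], pooled[4:]
        _, p = compare_groups(a, b)
        assert p == pytest.approx(enumeration_mw_p(list(a), list(b)))

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])


class TestCohortComparison:
    def test_top_gene_ranked_first(self):
        own = {"TP53": 31.6, "RUNX1": 15.5}
        others = {"ext": {"TP53": 21.8, "RUNX1": 19.3}}
        df = compare_cohort_frequencies(own, others, ["TP53", "RUNX1"])
        assert df.loc["TP53", "rank_own"] == 1
        assert df.loc["TP53", "rank_ext"] == 1

    def test_identical_tables_zero_differences(self):
        own = {"TP53": 30.0, "ASXL1": 10.0}
        df = compare_cohort_frequencies(own, {"ext": dict(own)}, list(own))
        assert (df["diff_ext"] == 0).all()

    def test_hand_computed_differences_and_missing_gene(self):
        own = {"TP53": 30.0}
        others = {"ext": {"TP53": 25.0, "CBL": 7.0}}
        df = compare_cohort_frequencies(own, others, ["TP53", "CBL"])
        assert df.loc["TP53", "diff_ext"] == pytest.approx(-5.0)
        assert df.loc["CBL", "freq_own"] == 0.0
        assert df.loc["CBL", "diff_ext"] == pytest.approx(7.0)


def test_progression_changes_gained_and_lost():
    initial = [somatic("TP53", "p1-A", 1), somatic("DIS3", "p1-A", 2)]
    later = [somatic("TP53", "p1-B", 1), somatic("SMC3", "p1-B", 3)]
    delta = progression_changes(initial, later)
    assert delta["gained"] == [("1", 3, "G", "A")]
    assert delta["lost"] == [("1", 2, "G", "A")]
    assert delta["persistent"] == [("1", 1, "G", "A")]
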