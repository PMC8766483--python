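"""Host-range concordance (D_h) and the group-comparison statistics."""

import numpy as np
import pandas as pd
import pytest

from phagenet import (
    HostRangeProfile,
    InteractionMatrix,
    compare_levels,
    concordance_rm_correlation,
    group_concordance,
    life_history_ks,
    morphotype_kill_stats,
    rm_group_test,
    rm_value,
    scaled_divergence,
)


def profile(pid, bits):
    return HostRangeProfile(pid, np.array(bits))


def annotations(rows):
    return pd.DataFrame(
        rows, columns=["phage_id", "species_group", "genus_group", "morphotype", "life_history"]
    )


class TestScaledDivergence:
    def test_identical_profiles_zero(self):
        profs = [profile(f"p{i}", [1, 0, 1, 0]) for i in range(4)]
        assert scaled_divergence(profs) == pytest.approx(0.0)

    def test_disjoint_profiles_one(self):
        profs = [
            profile("a", [1, 0, 0, 0]),
            profile("b", [0, 1, 0, 0]),
            profile("c", [0, 0, 1, 0]),
        ]
        assert scaled_divergence(profs) == pytest.approx(1.0)

    def test_half_overlap_worked_example(self):
        """x=(1,1,0) and (0,1,1): mixture entropy 1.5 bits, mean entropy 1,
        so D_h = 0.5."""
        d = scaled_divergence([profile("a", [1, 1, 0]), profile("b", [0, 1, 1])])
        assert d == pytest.approx(0.5)

    def test_pairwise_case_equals_jsd_bits(self):
        # for n = 2 the log2(2) normalizer is 1, so D_h is the plain JSD
        from scipy.spatial.distance import jensenshannon

        a, b = profile("a", [1, 1, 0, 0]), profile("b", [0, 1, 1, 1])
        expected = jensenshannon(a.p, b.p, base=2) ** 2
        assert scaled_divergence([a, b]) == pytest.approx(expected)

    def test_zero_kill_profile_named_in_error(self):
        with pytest.raises(ValueError, match="deadbeat"):
            scaled_divergence([profile("a", [1, 0]), profile("deadbeat", [0, 0])])

    def test_host_permutation_invariance(self):
        rng = np.random.default_rng(3)
        base = [rng.integers(0, 2, size=8) for _ in range(3)]
        base = [b if b.sum() else np.eye(8, dtype=int)[0] for b in base]
        perm = rng.permutation(8)
        d1 = scaled_divergence([profile(str(i), b) for i, b in enumerate(base)])
        d2 = scaled_divergence([profile(str(i), b[perm]) for i, b in enumerate(base)])
        assert d1 == pytest.approx(d2)

    def test_unkilled_host_padding_invariance(self):
        profs = [profile("a", [1, 1, 0]), profile("b", [0, 1, 1])]
        padded = [profile("a", [1, 1, 0, 0]), profile("b", [0, 1, 1, 0])]
        assert scaled_divergence(profs) == pytest.approx(scaled_divergence(padded))


class TestGroupConcordance:
    def make_matrix(self):
        # species s1: two identical phages; species s2: one disjoint phage
        cells = np.array(
            [[1, 1, 0], [1, 1, 0], [0, 0, 1], [0, 0, 1]]
        )
        m = InteractionMatrix(("h1", "h2", "h3", "h4"), ("p1", "p2", "p3"), cells)
        ann = annotations(
            [
                ("p1", "s1", "g1", "myovirus", "virulent"),
                ("p2", "s1", "g1", "myovirus", "virulent"),
                ("p3", "s2", "g1", "podovirus", "virulent"),
            ]
        )
        return m, ann

    def test_species_level_perfect_overlap(self):
        m, ann = self.make_matrix()
        res = group_concordance(m, ann, level="species")
        assert len(res) == 1  # s2 has a single member and is skipped
        assert res[0].group_id == "s1"
        assert res[0].concordance == pytest.approx(1.0)

    def test_genus_disjoint_species_single_members(self):
        cells = np.array([[1, 0], [0, 1]])
        m = InteractionMatrix(("h1", "h2"), ("p1", "p2"), cells)
        ann = annotations(
            [
                ("p1", "s1", "g1", "myovirus", "virulent"),
                ("p2", "s2", "g1", "myovirus", "virulent"),
            ]
        )
        res = group_concordance(m, ann, level="genus")
        assert res[0].concordance == pytest.approx(0.0)

    def test_bloom_inflates_all_members_concordance(self):
        """A species bloom (many identical profiles) raises genus-level
        concordance relative to the single-representative mode."""
        n_bloom = 10
        cells = np.zeros((4, n_bloom + 1), dtype=int)
        cells[:2, :n_bloom] = 1  # bloom species kills h1, h2
        cells[2:, n_bloom] = 1  # divergent singleton kills h3, h4
        m = InteractionMatrix(
            ("h1", "h2", "h3", "h4"),
            tuple(f"p{i}" for i in range(n_bloom + 1)),
            cells,
        )
        rows = [(f"p{i}", "s1", "g1", "myovirus", "virulent") for i in range(n_bloom)]
        rows.append((f"p{n_bloom}", "s2", "g1", "myovirus", "virulent"))
        ann = annotations(rows)
        all_members = group_concordance(m, ann, level="genus", mode="all_members")
        single = group_concordance(m, ann, level="genus", mode="single_representative", seed=1)
        assert all_members[0].concordance > single[0].concordance

    def test_unannotated_phage_rejected(self):
        m, ann = self.make_matrix()
        with pytest.raises(ValueError, match="missing"):
            group_concordance(m, ann.iloc[:2], level="species")

    def test_representative_draw_is_seeded(self):
        m, ann = self.make_matrix()
        a = group_concordance(m, ann, level="genus", mode="single_representative", seed=9)
        b = group_concordance(m, ann, level="genus", mode="single_representative", seed=9)
        assert a == b


class TestCompareLevels:
    def test_identical_samples(self):
        res = compare_levels([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_separated_samples_significant(self):
        res = compare_levels([0, 0, 0.1], [0.9, 1, 1])
        assert res.pvalue < 0.01

    def test_welch_matches_closed_form(self):
        a = np.array([0.1, 0.3, 0.2, 0.4])
        b = np.array([0.7, 0.9, 0.8])
        res = compare_levels(a, b)
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert res.statistic == pytest.approx((a.mean() - b.mean()) / se)


class TestMorphotypeStats:
    def test_summary_and_pairwise_tests(self):
        cells = np.zeros((6, 5), dtype=int)
        cells[:, 0] = 1  # p0 kills 6
        cells[:5, 1] = 1  # p1 kills 5
        cells[0, 2] = 1  # p2 kills 1
        cells[1, 3] = 1  # p3 kills 1
        cells[2, 4] = 1  # p4 kills 1
        m = InteractionMatrix(
            tuple(f"h{i}" for i in range(6)), tuple(f"p{j}" for j in range(5)), cells
        )
        ann = annotations(
            [
                ("p0", "s1", "g1", "non-tailed", "virulent"),
                ("p1", "s1", "g1", "non-tailed", "virulent"),
                ("p2", "s2", "g2", "myovirus", "virulent"),
                ("p3", "s2", "g2", "myovirus", "virulent"),
                ("p4", "s2", "g2", "myovirus", "virulent"),
            ]
        )
        summary, tests = morphotype_kill_stats(m, ann)
        nt = summary.set_index("morphotype").loc["non-tailed"]
        assert nt["mean"] == pytest.approx(5.5)
        assert nt["sd"] == pytest.approx(np.std([6, 5], ddof=1))
        assert len(tests) == 1
        assert tests.iloc[0]["p"] < 0.01

    def test_identical_groups_t_zero(self):
        cells = np.zeros((3, 4), dtype=int)
        cells[0, :] = 1
        m = InteractionMatrix(("h1", "h2", "h3"), ("p1", "p2", "p3", "p4"), cells)
        ann = annotations(
            [
                ("p1", "s", "g", "myovirus", "virulent"),
                ("p2", "s", "g", "myovirus", "virulent"),
                ("p3", "s2", "g", "podovirus", "virulent"),
                ("p4", "s2", "g", "podovirus", "virulent"),
            ]
        )
        _, tests = morphotype_kill_stats(m, ann)
        assert tests.iloc[0]["t"] == 0.0
        assert tests.iloc[0]["p"] == 1.0


class TestLifeHistoryKS:
    def test_identical_samples_d_zero(self):
        res = life_history_ks([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0

    def test_disjoint_supports_d_one(self):
        res = life_history_ks(range(1, 11), range(11, 21))
        assert res.statistic == 1.0


class TestRM:
    def test_composition(self):
        rec = rm_value("g", 0.1, 100, 0.05)
        assert rec.r_over_m == pytest.approx(0.5)
        assert rm_value("g", 0, 7, 3).r_over_m == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="delta"):
            rm_value("g", 1, -2, 1)

    def test_wilcoxon_exact_all_above_one(self):
        # all six differences positive: two-sided exact p = 2 / 2^6
        assert rm_group_test([1.5, 2, 3, 1.2, 4, 1.1]).pvalue == pytest.approx(2 / 64)

    def test_wilcoxon_symmetric_pair(self):
        assert rm_group_test([0.5, 1.5]).pvalue == pytest.approx(1.0)

    def test_wilcoxon_single_value(self):
        assert rm_group_test([2.0]).pvalue == pytest.approx(1.0)

    def test_all_ones_rejected(self):
        with pytest.raises(ValueError, match="no information"):
            rm_group_test([1.0, 1.0])

    def test_p_decreases_with_sample_size(self):
        ps = [rm_group_test([1.5] * n).pvalue for n in (4, 6, 8, 10)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestSpearman:
    def test_monotone_extremes(self):
        assert concordance_rm_correlation([1, 2, 3], [10, 20, 30]).statistic == 1.0
        assert concordance_rm_correlation([1, 2, 3], [3, 2, 1]).statistic == -1.0

    def test_constant_input_flagged_nan(self):
        res = concordance_rm_correlation([1.0, 1.0, 1.0], [1, 2, 3])
        assert np.isnan(res.statistic)
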