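import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lichenscan import ortho


def exact_p_oracle(x, y):
    """Doubled one-sided tail of the full permutation null, written
    independently (rank-sum enumeration over index subsets)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = len(x)
    obs = ranks[:n].sum()
    sums = [sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n)]
    le = sum(1 for s in sums if s <= obs + 1e-9)
    ge = sum(1 for s in sums if s >= obs - 1e-9)
    return min(1.0, 2.0 * min(le, ge) / len(sums))


class TestLoadMatrix:
    def test_toy_matrix(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("species\tOG1\tOG2\nsp1\t0\t2\nsp2\t1\t0\nsp3\t5\t1\n")
        m = ortho.load_matrix(p)
        assert m.shape == (3, 2)
        assert m.loc["sp3", "OG1"] == 5

    def test_orientation_flag_transposes(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("family\tsp1\tsp2\nOG1\t1\t2\nOG2\t3\t4\nOG3\t0\t1\n")
        m = ortho.load_matrix(p, orientation="family_by_species")
        assert m.shape == (2, 3)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("species\tOG1\n")
        with pytest.raises(ValueError, match="no data rows"):
            ortho.load_matrix(p)

    def test_negative_cell_named(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("species\tOG1\nsp1\t-1\n")
        with pytest.raises(ValueError, match="'sp1'.*'OG1'"):
            ortho.load_matrix(p)


class TestFilterFamilies:
    @pytest.fixture
    def matrix(self):
        return pd.DataFrame(
            {
                "one_sp": [3, 0, 0, 0],
                "two_sp": [1, 1, 0, 0],
                "three_sp": [1, 1, 1, 0],
                "all_sp": [2, 2, 2, 2],
            },
            index=[f"sp{i}" for i in range(4)],
        )

    def test_default_removes_one_and_two_species_families(self, matrix):
        kept = ortho.filter_families(matrix)
        assert list(kept.columns) == ["three_sp", "all_sp"]

    def test_min_species_one_is_identity(self, matrix):
        assert ortho.filter_families(matrix, 1).equals(matrix)

    def test_monotone_in_min_species(self, matrix):
        counts = [ortho.filter_families(matrix, k).shape[1] for k in range(1, 6)]
        assert counts == sorted(counts, reverse=True)


class TestWilcoxon:
    def test_separated_groups_enumeration(self):
        u, p = ortho.wilcoxon_two_sided([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_multisets_give_p_one(self):
        _, p = ortho.wilcoxon_two_sided([1, 2, 2, 7], [2, 7, 1, 2])
        assert p == 1.0

    def test_exact_matches_enumeration_oracle_with_ties(self):
        rng = np.random.default_rng(17)
        for n in range(1, 9):
            for m in range(1, 9):
                x = rng.integers(0, 4, n).astype(float)  # heavy ties
                y = rng.integers(0, 4, m).astype(float)
                u, p = ortho.wilcoxon_two_sided(x, y)
                if np.ptp(np.concatenate([x, y])) == 0:
                    assert p == 1.0
                    continue
                assert p == pytest.approx(exact_p_oracle(x, y), abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        # tie-free n=m=20 sits above the enumeration cutoff; compare the
        # asymptotic p against the exact doubled tail from scipy
        rng = np.random.default_rng(23)
        for _ in range(10):
            x = rng.normal(0, 1, 20)
            y = rng.normal(0.3, 1, 20)
            _, p_approx = ortho.wilcoxon_two_sided(x, y)
            p_exact = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert abs(p_approx - p_exact) < 0.005

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ortho.wilcoxon_two_sided([], [1.0])


class TestEnrichmentScan:
    def _planted(self, rng, n_background=500, n_planted=20, mult=4):
        n_focal, n_other = 13, 23
        lam = rng.gamma(2.0, 1.0, n_background + n_planted)
        counts = rng.poisson(np.broadcast_to(lam, (n_focal + n_other, len(lam)))).astype(float)
        counts[:n_focal, n_background:] = rng.poisson(
            mult * lam[n_background:], (n_focal, n_planted)
        )
        species = [f"sp{i}" for i in range(n_focal + n_other)]
        fams = [f"OG{i}" for i in range(n_background + n_planted)]
        m = pd.DataFrame(counts.astype(int), index=species, columns=fams)
        groups = pd.Series(
            ["focal"] * n_focal + ["other"] * n_other, index=species
        )
        planted = fams[n_background:]
        return m, groups, planted

    def test_planted_families_recovered_with_direction(self):
        rng = np.random.default_rng(2)
        m, groups, planted = self._planted(rng)
        res = ortho.enrichment_scan(ortho.filter_families(m), groups, alpha=0.01)
        table = res.table
        found = [f for f in planted if f in table.index and table.loc[f, "significant"]]
        assert len(found) >= 0.9 * len(planted)
        assert all(table.loc[f, "direction"] == "focal_enriched" for f in found)

    def test_constant_matrix_nothing_significant(self):
        m = pd.DataFrame(3, index=[f"s{i}" for i in range(10)], columns=["OG1", "OG2"])
        groups = pd.Series(["focal"] * 5 + ["other"] * 5, index=m.index)
        with pytest.warns(UserWarning, match="constant"):
            res = ortho.enrichment_scan(m, groups)
        assert len(res.table) == 0

    def test_alpha_one_everything_significant(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(
            rng.poisson(2, (10, 8)), index=[f"s{i}" for i in range(10)],
            columns=[f"OG{i}" for i in range(8)],
        )
        groups = pd.Series(["focal"] * 5 + ["other"] * 5, index=m.index)
        res = ortho.enrichment_scan(m, groups, alpha=1.0)
        assert res.table["significant"].all()

    def test_calibration_under_label_permutation(self):
        # with labels shuffled independently of counts, about alpha of the
        # families should come out significant (binomial error, conservative
        # side allowed for the discrete/continuity-corrected test)
        rng = np.random.default_rng(11)
        n_fam = 2000
        m = pd.DataFrame(
            rng.poisson(2.0, (36, n_fam)),
            index=[f"sp{i}" for i in range(36)],
            columns=[f"OG{i}" for i in range(n_fam)],
        )
        labels = np.array(["focal"] * 13 + ["other"] * 23)
        rng.shuffle(labels)
        groups = pd.Series(labels, index=m.index)
        res = ortho.enrichment_scan(ortho.filter_families(m), groups, alpha=0.01)
        frac = len(res.significant) / len(res.table)
        assert frac <= 0.01 + 3 * math.sqrt(0.01 * 0.99 / n_fam)

    def test_empty_group_rejected(self):
        m = pd.DataFrame({"OG1": [1, 2]}, index=["a", "b"])
        groups = pd.Series(["focal", "focal"], index=m.index)
        with pytest.raises(ValueError, match="non-empty"):
            ortho.enrichment_scan(m, groups)


class TestBhAdjust:
    def test_hand_computed_stepup(self):
        out = ortho.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert ortho.bh_adjust([0.5])[0] == pytest.approx(0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ortho.bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_monotone_and_order_preserving(self, ps):
        adj = ortho.bh_adjust(ps)
        assert len(adj) == len(ps)
        assert np.all((adj >= np.asarray(ps) - 1e-12) & (adj <= 1.0 + 1e-12))
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestGroupFeatureCompare:
    def test_planted_gc_shift_detected(self):
        rng = np.random.default_rng(4)
        gc_focal = rng.normal(50, 2, 13)
        gc_other = rng.normal(60, 2, 23)
        feats = pd.DataFrame(
            {"gc_percent": np.concatenate([gc_focal, gc_other]),
             "genome_mb": rng.normal(100, 20, 36)},
            index=[f"sp{i}" for i in range(36)],
        )
        groups = pd.Series(["focal"] * 13 + ["other"] * 23, index=feats.index)
        res = ortho.group_feature_compare(feats, groups)
        assert res.loc["gc_percent", "p"] < 0.01
        assert res.loc["gc_percent", "median_focal"] < res.loc["gc_percent", "median_other"]

    def test_identical_values_p_one(self):
        feats = pd.DataFrame({"f": [1.0] * 8}, index=[f"s{i}" for i in range(8)])
        groups = pd.Series(["focal"] * 4 + ["other"] * 4, index=feats.index)
        assert ortho.group_feature_compare(feats, groups).loc["f", "p"] == 1.0

    def test_single_species_group_rejected(self):
        feats = pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        groups = pd.Series(["focal", "other", "other"], index=feats.index)
        with pytest.raises(ValueError, match=">= 2 species"):
            ortho.group_feature_compare(feats, groups)

    def test_all_missing_feature_skipped(self):
        feats = pd.DataFrame(
            {"ok": [1.0, 2.0, 3.0, 4.0], "gone": [np.nan, np.nan, 1.0, 2.0]},
            index=["a", "b", "c", "d"],
        )
        groups = pd.Series(["focal", "focal", "other", "other"], index=feats.index)
        with pytest.warns(UserWarning, match="gone"):
            res = ortho.group_feature_compare(feats, groups)
        assert list(res.index) == ["ok"]
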