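import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mirenrich import (EmptyResultError, FoldChangeTable, InputError,
                       TargetPredictionMap, build_universe, mann_whitney,
                       partition_for_family, scan_families)
from _oracles import brute_force_p, u_by_pair_counting


def fc_from(mapping):
    return FoldChangeTable(pd.Series(mapping, name="log_fc").rename_axis("gene_id"))


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitneyExact:
    @pytest.mark.parametrize("x,y,alternative,expected_p", [
        ([1, 2, 3], [4, 5, 6], "less", 1 / 20),     # unique all-smallest assignment of C(6,3)=20
        ([5], [1, 2, 3, 4], "greater", 1 / 5),      # 5 placements, observed is extreme
    ])
    def test_worked_small_samples(self, x, y, alternative, expected_p):
        u, p, method = mann_whitney(x, y, alternative=alternative)
        assert method == "exact"
        assert p == pytest.approx(expected_p, abs=1e-15)
        assert p == pytest.approx(brute_force_p(x, y, alternative), abs=1e-12)

    def test_identical_samples_symmetry_point(self):
        u, p, method = mann_whitney([1, 2, 3], [1, 2, 3], alternative="two-sided")
        assert u == pytest.approx(4.5)  # n1*n2/2
        assert p == 1.0
        assert method == "normal-approximation"  # ties force the approximation

    def test_exact_path_refuses_ties(self):
        _, _, method = mann_whitney([1.0, 2.0], [2.0, 3.0])
        assert method == "normal-approximation"

    def test_exact_limit_switches_method(self):
        x = list(range(10))
        y = [v + 0.5 for v in range(10)]
        assert mann_whitney(x, y, exact_limit=16)[2] == "normal-approximation"
        assert mann_whitney(x[:3], y[:3], exact_limit=16)[2] == "exact"

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            mann_whitney([], [1.0])
        with pytest.raises(InputError):
            mann_whitney([1.0], [])

    @settings(max_examples=150, derandomize=True)
    @given(data=st.data())
    def test_exact_path_matches_enumeration_oracle(self, data):
        """On tie-free pooled samples of size <= 10 the exact p equals the
        brute-force enumeration over all group assignments."""
        n1 = data.draw(st.integers(1, 5))
        n2 = data.draw(st.integers(1, 5))
        pool = data.draw(st.lists(
            st.floats(-50, 50, allow_nan=False, allow_infinity=False),
            min_size=n1 + n2, max_size=n1 + n2, unique=True))
        x, y = pool[:n1], pool[n1:]
        for alternative in ("two-sided", "less", "greater"):
            u, p, method = mann_whitney(x, y, alternative=alternative)
            assert method == "exact"
            assert u == pytest.approx(u_by_pair_counting(x, y))
            assert p == pytest.approx(brute_force_p(x, y, alternative), abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(data=st.data())
    def test_exact_one_sided_matches_reference_implementation(self, data):
        n1 = data.draw(st.integers(2, 6))
        n2 = data.draw(st.integers(2, 6))
        pool = data.draw(st.lists(st.floats(-9, 9, allow_nan=False),
                                  min_size=n1 + n2, max_size=n1 + n2, unique=True))
        x, y = pool[:n1], pool[n1:]
        for alternative in ("less", "greater"):
            _, p, _ = mann_whitney(x, y, alternative=alternative)
            ref = sps.mannwhitneyu(x, y, alternative=alternative, method="exact")
            assert p == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_normal_path_matches_reference_implementation(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(0.3, 1.0, size=200)
        # inject ties to exercise the correction
        x[:5] = y[:5]
        for alternative in ("two-sided", "less", "greater"):
            u, p, method = mann_whitney(x, y, alternative=alternative)
            assert method == "normal-approximation"
            ref = sps.mannwhitneyu(x, y, alternative=alternative,
                                   method="asymptotic", use_continuity=True)
            assert u == pytest.approx(float(ref.statistic))
            assert p == pytest.approx(float(ref.pvalue), rel=1e-9)


class TestMannWhitneyProperties:
    @settings(max_examples=80, derandomize=True)
    @given(x=st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=12),
           y=st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=12))
    def test_group_swap_symmetry(self, x, y):
        u_xy, p_xy, _ = mann_whitney(x, y, alternative="two-sided")
        u_yx, p_yx, _ = mann_whitney(y, x, alternative="two-sided")
        assert u_xy + u_yx == pytest.approx(len(x) * len(y))
        assert p_xy == pytest.approx(p_yx, rel=1e-12)
        assert 0.0 < p_xy <= 1.0
        assert 0.0 <= u_xy <= len(x) * len(y) + 1e-9

    @settings(max_examples=60, derandomize=True)
    @given(x=st.lists(st.floats(-20, 20, allow_nan=False), min_size=2, max_size=8),
           y=st.lists(st.floats(-20, 20, allow_nan=False), min_size=2, max_size=8),
           delta=st.floats(0.0, 10.0, allow_nan=False))
    def test_one_sided_p_monotone_under_downward_shift(self, x, y, delta):
        """Subtracting delta > 0 from all target values can only strengthen
        the evidence that targets are down-regulated (on tie-free data, where
        a single p-value method applies before and after the shift)."""
        shifted = [v - delta for v in x]
        assume(len(set(x + y)) == len(x) + len(y))
        assume(len(set(shifted + y)) == len(x) + len(y))
        _, p0, _ = mann_whitney(x, y, alternative="less")
        _, p1, _ = mann_whitney(shifted, y, alternative="less")
        assert p1 <= p0 + 1e-12


# ---------------------------------------------------------------------------
# Universe and partitions
# ---------------------------------------------------------------------------

class TestUniverse:
    def test_intersection_with_measured_genes(self, small_predictions):
        fc = fc_from({"g2": 0.1, "g3": 0.2, "g4": -0.1, "g9": 1.0})
        assert build_universe(small_predictions, fc) == {"g2", "g3", "g4"}

    def test_fc_superset_leaves_universe_unchanged(self, small_predictions):
        fc = fc_from({f"g{i}": 0.01 * i for i in range(1, 10)})
        assert build_universe(small_predictions, fc) == small_predictions.gene_universe

    def test_disjoint_is_hard_error(self, small_predictions):
        fc = fc_from({"zz1": 0.1})
        with pytest.raises(InputError, match="no overlap"):
            build_universe(small_predictions, fc)

    def test_partition_is_a_partition(self, small_predictions):
        universe = frozenset({"g1", "g2", "g3", "g4", "g5"})
        t, nt = partition_for_family("famA", small_predictions, universe)
        assert t == {"g1", "g2", "g3"}
        assert nt == {"g4", "g5"}
        assert t | nt == universe and not (t & nt)

    def test_unknown_family(self, small_predictions):
        with pytest.raises(InputError, match="unknown family"):
            partition_for_family("nope", small_predictions, frozenset({"g1"}))


# ---------------------------------------------------------------------------
# Scan
# ---------------------------------------------------------------------------

class TestScanFamilies:
    def test_composition_matches_direct_test(self):
        """A single-family scan carries exactly the U and p of the direct
        Mann-Whitney call on the same partition."""
        fc = fc_from({f"g{i}": float(i) for i in range(1, 7)})
        pm = TargetPredictionMap(
            family_targets={"fX": frozenset({"g1", "g2", "g3"}),
                            "fBg": frozenset({"g4", "g5", "g6"})},
            family_members={"fX": frozenset({"m1"}), "fBg": frozenset({"m2"})})
        results = scan_families(fc, pm, alternative="less", min_targets=3)
        by_id = {r.family_id: r for r in results}
        u, p, _ = mann_whitney([1, 2, 3], [4, 5, 6], alternative="less")
        assert by_id["fX"].u_statistic == pytest.approx(u)
        assert by_id["fX"].p_value == pytest.approx(p)
        assert by_id["fX"].median_fc_targets == pytest.approx(2.0)
        assert by_id["fX"].median_fc_non_targets == pytest.approx(5.0)
        assert by_id["fX"].n_targets == 3 and by_id["fX"].n_non_targets == 3

    def test_identical_families_identical_rows(self):
        fc = fc_from({f"g{i}": float(i) for i in range(1, 9)})
        targets = frozenset({"g1", "g2", "g3", "g4", "g5"})
        other = frozenset({"g6", "g7", "g8"})
        pm = TargetPredictionMap(
            family_targets={"fA": targets, "fB": targets, "fO": other},
            family_members={k: frozenset({k + "-m"}) for k in ("fA", "fB", "fO")})
        results = {r.family_id: r for r in scan_families(fc, pm, min_targets=3)}
        a, b = results["fA"], results["fB"]
        assert (a.median_fc_targets, a.u_statistic, a.p_value) == \
               (b.median_fc_targets, b.u_statistic, b.p_value)

    def test_min_targets_skips_all_families_hard_error(self, small_predictions):
        fc = fc_from({f"g{i}": float(i) for i in range(1, 7)})
        with pytest.raises(EmptyResultError):
            scan_families(fc, small_predictions, min_targets=5)

    def test_family_covering_whole_universe_skipped(self):
        fc = fc_from({"g1": 0.1, "g2": 0.2})
        pm = TargetPredictionMap(
            family_targets={"fAll": frozenset({"g1", "g2"})},
            family_members={"fAll": frozenset({"m"})})
        with pytest.raises(EmptyResultError):
            scan_families(fc, pm, min_targets=1)

    def test_results_sorted_and_order_invariant(self, planted_dataset, rng):
        ds = planted_dataset
        res1 = scan_families(ds.fc, ds.predictions)
        perm = rng.permutation(len(ds.fc.values))
        shuffled = FoldChangeTable(ds.fc.values.iloc[perm])
        res2 = scan_families(shuffled, ds.predictions)
        assert [r.p_value for r in res1] == sorted(r.p_value for r in res1)
        assert res1 == res2  # medians/U/p invariant to table re-ordering

    def test_planted_family_attains_minimum_p(self):
        """With one strongly repressed family the scan's best p belongs to
        it, and its U matches a direct rank-sum recomputation."""
        from mirenrich import SimulationConfig, generate_dataset
        ds = generate_dataset(SimulationConfig(
            n_genes=400, n_families=8, targets_per_family=25, n_active=1,
            effect_delta=0.8, noise_sigma=0.2, seed=5))
        results = scan_families(ds.fc, ds.predictions)
        (active,) = ds.truth
        assert results[0].family_id == active
        # independent U: rank-sum on the generated values
        universe = build_universe(ds.predictions, ds.fc)
        targets = ds.predictions.family_targets[active] & universe
        pooled = ds.fc.values.loc[sorted(universe)]
        ranks = pd.Series(sps.rankdata(pooled.to_numpy()), index=pooled.index)
        n1 = len(targets)
        u_direct = ranks.loc[sorted(targets)].sum() - n1 * (n1 + 1) / 2
        assert results[0].u_statistic == pytest.approx(u_direct)

    def test_prefilter_down_restricts_universe(self, planted_dataset):
        ds = planted_dataset
        res = scan_families(ds.fc, ds.predictions, prefilter="down", min_targets=1)
        n_down = int((ds.fc.values < 0).sum())
        for r in res:
            assert r.n_targets + r.n_non_targets <= n_down
            assert r.median_fc_targets < 0 and r.median_fc_non_targets < 0

    def test_null_scan_pvalues_uniform(self, rng):
        """Under iid fold changes and random target assignment, scan p-values
        are uniform (KS check over 1000 families)."""
        n_genes, n_fam, k = 500, 1000, 25
        genes = [f"g{i}" for i in range(n_genes)]
        fc = fc_from(dict(zip(genes, rng.normal(0, 1, n_genes))))
        fam_targets = {f"f{j:04d}": frozenset(rng.choice(genes, k, replace=False))
                       for j in range(n_fam)}
        pm = TargetPredictionMap(
            fam_targets, {f: frozenset({f + "-m"}) for f in fam_targets})
        pvals = np.array([r.p_value for r in scan_families(fc, pm)])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01
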