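"""Cohort filtering, summaries, loss arithmetic and rank tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from retinaquant.stats import (
    correlation_r2,
    filter_by_iop,
    gcl_decomposition,
    group_summary,
    holm_adjust,
    kruskal_wallis,
    mann_whitney,
    percent_loss,
    round_half_up,
    survival_fraction,
)
from retinaquant.synthetic import CohortDesign, LesionSpec, generate_iop_series, simulate_cohort


def _cohort(animals):
    return pd.DataFrame(
        [
            {"animal_id": a, "eye": "LE", "timepoint": "2wk", "population": "OHSt",
             "value": 100}
            for a in animals
        ]
    )


class TestIOPFilter:
    def test_inclusion_boundary_is_strict(self):
        cohort = _cohort(["A", "B", "C"])
        peaks = pd.Series({"A": 26.0, "B": 25.0, "C": 25.0001})
        kept, log = filter_by_iop(cohort, peaks)
        assert sorted(kept["animal_id"].unique()) == ["A", "C"]
        assert any(e["animal_id"] == "B" for e in log)

    def test_missing_iop_record_excluded_with_reason(self):
        cohort = _cohort(["A", "B"])
        peaks = pd.Series({"A": 30.0})
        kept, log = filter_by_iop(cohort, peaks)
        assert kept["animal_id"].unique().tolist() == ["A"]
        assert log[0]["reason"].startswith("no IOP record")

    def test_window_limits_peak_search(self):
        cohort = _cohort(["A"])
        iop = generate_iop_series(30.0, peak_time_h=24.0, seed=0)
        iop.insert(0, "animal_id", "A")
        # peak at 24 h is inside a 48 h window, outside a 6 h window
        kept, _ = filter_by_iop(cohort, iop, window_h=48.0)
        assert len(kept) == 1
        late = iop.copy()
        kept2, log2 = filter_by_iop(cohort, late, window_h=6.0)
        assert len(kept2) == 0 or late[late["time_h"] <= 6]["iop_mmHg"].max() > 25

    def test_designed_pass_rate_on_synthetic_batch(self):
        """12 animals with 9 designed peaks above threshold: exactly the
        9 designed animals are retained (generator labels are the oracle)."""
        peaks = (30.0, 28.0, 33.0, 24.0, 29.5, 31.0, 22.0, 27.0, 26.1, 32.0, 20.0, 35.0)
        design = CohortDesign(
            n_animals=12,
            populations=("OHSt",),
            lesion=LesionSpec(),
            iop_peaks_mmHg=peaks,
        )
        # tiny populations for speed: counts are irrelevant to the filter
        design = CohortDesign(**{**design.__dict__, "populations": ("melanopsin",)})
        counts, iop = simulate_cohort(design, seed=3)
        kept, log = filter_by_iop(counts, iop)
        expected = [f"M{i+1:03d}" for i, p in enumerate(peaks) if p > 25.0]
        assert sorted(kept["animal_id"].unique()) == expected
        assert len(log) == 3


class TestGroupSummary:
    def test_hand_computable(self):
        df = pd.DataFrame({"g": ["a"] * 3, "value": [2.0, 4.0, 6.0]})
        out = group_summary(df, "g")
        assert out.loc[0, "mean"] == 4.0
        assert out.loc[0, "sd"] == 2.0
        assert out.loc[0, "n"] == 3

    def test_singleton_sd_zero_with_n_flag(self):
        df = pd.DataFrame({"g": ["a"], "value": [38_479.0]})
        out = group_summary(df, "g")
        assert out.loc[0, "mean"] == 38_479.0
        assert out.loc[0, "sd"] == 0.0
        assert out.loc[0, "n"] == 1

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            group_summary(pd.DataFrame({"g": [], "value": []}), "g")

    def test_matches_two_pass_reference(self):
        rng = np.random.default_rng(0)
        v = rng.normal(1000.0, 50.0, 500)
        df = pd.DataFrame({"g": ["x"] * 500, "value": v})
        out = group_summary(df, "g")
        mean_ref = float(np.sum(v) / v.size)
        sd_ref = float(np.sqrt(np.sum((v - mean_ref) ** 2) / (v.size - 1)))
        assert out.loc[0, "mean"] == pytest.approx(mean_ref, rel=1e-12)
        assert out.loc[0, "sd"] == pytest.approx(sd_ref, rel=1e-12)


class TestLossArithmetic:
    @pytest.mark.parametrize(
        "ctrl,trt,raw,rounded",
        [
            (38_479.0, 19_383.0, 49.627, 50),
            (38_507.0, 14_795.0, 61.578, 62),
            (100.0, 100.0, 0.0, 0),
        ],
    )
    def test_percent_loss(self, ctrl, trt, raw, rounded):
        got_raw, got_round = percent_loss(ctrl, trt)
        assert got_raw == pytest.approx(raw, abs=1e-3)
        assert got_round == rounded

    @pytest.mark.parametrize(
        "ctrl,trt,rounded",
        [(1_059.0, 629.0, 59), (38_507.0, 14_795.0, 38), (37_936.0, 15_583.0, 41)],
    )
    def test_survival_fraction(self, ctrl, trt, rounded):
        _, got = survival_fraction(ctrl, trt)
        assert got == rounded

    def test_loss_and_survival_complement(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            c = rng.uniform(1, 1e5)
            t = rng.uniform(0, c * 1.5)
            assert percent_loss(c, t)[0] + survival_fraction(c, t)[0] == pytest.approx(
                100.0, abs=1e-9
            )

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            percent_loss(0.0, 10.0)
        with pytest.raises(ValueError):
            survival_fraction(0.0, 10.0)

    def test_round_half_up(self):
        assert round_half_up(49.5) == 50
        assert round_half_up(49.4999) == 49

    def test_gcl_decomposition(self):
        assert gcl_decomposition(82_094.0, 36_623.0) == 45_471.0
        assert gcl_decomposition(61_589.0, 14_508.0) == 47_081.0
        assert gcl_decomposition(5.0, 5.0) == 0.0
        with pytest.warns(UserWarning):
            assert gcl_decomposition(3.0, 5.0) == -2.0


def mw_permutation_oracle(a, b, alternative):
    """Full-enumeration oracle over all C(n1+n2, n1) group assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = sps.rankdata(pooled)
    obs = ranks[:n1].sum()
    sums = np.array(
        [ranks[list(c)].sum() for c in itertools.combinations(range(len(pooled)), n1)]
    )
    eps = 1e-9
    p_le = np.mean(sums <= obs + eps)
    p_ge = np.mean(sums >= obs - eps)
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(p_le, p_ge))
    return p_ge if alternative == "greater" else p_le


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0

    def test_fully_separated_small_groups(self):
        res = mann_whitney([1, 2, 3], [10, 20, 30])
        assert res.p_value == pytest.approx(0.1)
        one_sided = mann_whitney([1, 2, 3], [10, 20, 30], alternative="less")
        assert one_sided.p_value == pytest.approx(1 / 20)

    def test_all_tied_warns_p_one(self):
        with pytest.warns(UserWarning):
            res = mann_whitney([5, 5], [5, 5, 5])
        assert res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("alternative", ["two-sided", "less", "greater"])
    def test_exact_p_equals_permutation_oracle(self, seed, alternative):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 8, size=2)
        a = rng.normal(0, 1, n1)
        b = rng.normal(0.8, 1, n2)
        if seed % 2:  # inject ties
            a = np.round(a)
            b = np.round(b)
        res = mann_whitney(a, b, alternative=alternative)
        assert res.method in ("exact", "degenerate")
        assert res.p_value == pytest.approx(mw_permutation_oracle(a, b, alternative),
                                            abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_tie_free_matches_scipy_exact(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.5, 1, 7)
        ours = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        assert ours.statistic == pytest.approx(ref.statistic)

    def test_large_samples_use_asymptotic(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 12)
        res = mann_whitney(a, b)
        assert res.method == "asymptotic"
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)


class TestKruskalWallis:
    def test_identical_groups(self):
        res = kruskal_wallis([[1, 1], [1, 1], [1, 1]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_fully_separated_attains_enumeration_maximum(self):
        """k=3, n=2 each with fully separated ranks reaches the maximum
        H over all assignments of ranks 1..6 into three pairs."""
        res = kruskal_wallis([[1, 2], [13, 14], [105, 106]])
        best = 0.0
        ranks = list(range(1, 7))
        for g1 in itertools.combinations(ranks, 2):
            rest = [r for r in ranks if r not in g1]
            for g2 in itertools.combinations(rest, 2):
                g3 = [r for r in rest if r not in g2]
                h, _ = sps.kruskal(list(g1), list(g2), list(g3))
                best = max(best, h)
        assert res.statistic == pytest.approx(best, rel=1e-12)

    def test_two_groups_guarded(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], [3, 4]])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], [], [3, 4]])


class TestCorrelation:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = correlation_r2(x, 2 * x)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlation_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_shared_lesion_couples_populations(self):
        """Per-animal OHSt and Brn3a counts share the lesion severity, so
        their treated-eye counts correlate strongly (r² > 0.9)."""
        design = CohortDesign(
            n_animals=7,
            populations=("OHSt", "Brn3a"),
            lesion=LesionSpec(wedges=((0.0, 90.0, 1.0),), diffuse_fraction=1 / 3),
            severity_cv=0.5,
        )
        counts, _ = simulate_cohort(design, seed=9)
        le = counts[counts["eye"] == "LE"].pivot_table(
            index="animal_id", columns="population", values="value"
        )
        res = correlation_r2(le["OHSt"].to_numpy(), le["Brn3a"].to_numpy())
        assert res.r_squared > 0.9


def test_holm_adjustment_monotone_and_bounded():
    p = [0.001, 0.04, 0.03, 0.5]
    adj = holm_adjust(p)
    assert np.all(adj >= np.asarray(p))
    assert np.all(adj <= 1.0)
    assert adj[0] == pytest.approx(0.004)
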