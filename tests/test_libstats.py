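import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from satlib.datasets import schistocerca_satdna, sg1_fish_loci
from satlib.io import round_half_up
from satlib.libstats import (
    clade_distance_test,
    spearman_t_statistic,
    spearman_ties,
    substitution_rate,
    summary_stats,
    z_scores,
)
from satlib.phylo import DistanceMatrix


def sg1_abundances():
    df = schistocerca_satdna()
    sub = df[df.family == "SG1"]
    return dict(zip(sub.species, sub.abundance_pct))


class TestSummaryStats:
    def test_reproduces_published_sg1_abundance_row(self):
        st_ = summary_stats(list(sg1_abundances().values()))
        assert round_half_up(st_.mean, 1) == 1.6
        assert round_half_up(st_.sd, 1) == 2.0
        assert round_half_up(st_.cv_pct, 1) == 124.4

    def test_constant_vector_has_zero_sd_and_cv(self):
        st_ = summary_stats([3.0, 3.0, 3.0])
        assert st_.sd == 0.0
        assert st_.cv_pct == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            summary_stats([1.0])

    def test_zero_mean_cv_undefined(self):
        with pytest.raises(ValueError, match="CV"):
            summary_stats([-1.0, 1.0])


class TestZScores:
    def test_outgroup_amplification_exceeds_2p5_sd(self):
        z = z_scores(sg1_abundances())
        assert z["SGRE"] > 2.5

    def test_sign_flip_when_outgroup_excluded(self):
        values = sg1_abundances()
        assert z_scores(values)["SFLA"] < 0
        assert z_scores(values, exclude={"SGRE"})["SFLA"] > 0

    def test_excluded_species_scored_against_included_baseline(self):
        values = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 100.0}
        z = z_scores(values, exclude={"D"})
        incl = np.array([1.0, 2.0, 3.0])
        assert z["D"] == pytest.approx((100 - incl.mean()) / incl.std(ddof=1))

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="deviation"):
            z_scores({"A": 1.0, "B": 1.0, "C": 1.0})

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=20,
                    unique=True))
    def test_included_scores_have_mean_zero_sd_one(self, values):
        named = {f"s{i}": v for i, v in enumerate(values)}
        z = np.array(list(z_scores(named).values()))
        assert abs(z.mean()) < 1e-9
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestSubstitutionRate:
    @pytest.mark.parametrize("d,t,expected", [
        (0.0, 7.9, 0.0),
        (0.158, 7.9, 1.0),
        (0.332, 7.9, pytest.approx(2.1, abs=0.005)),
    ])
    def test_rate_is_distance_over_twice_time(self, d, t, expected):
        assert substitution_rate("SG1", "X", d, t).rate_pct_per_myr == expected

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            substitution_rate("SG1", "X", 0.1, 0.0)


def _pooled_t_oracle(x, y):
    """Textbook pooled-variance two-sample t, written independently."""
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    sx2 = sum((v - mx) ** 2 for v in x) / (nx - 1)
    sy2 = sum((v - my) ** 2 for v in y) / (ny - 1)
    sp2 = ((nx - 1) * sx2 + (ny - 1) * sy2) / (nx + ny - 2)
    return (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))


def _matrix_from_pairs(labels, dist):
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = dist(labels[i], labels[j])
    return DistanceMatrix(tuple(labels), m)


NINE_SPECIES = ["a1", "a2", "b1", "b2", "c1", "c2", "d1", "d2", "d3"]
NINE_CLADES = {s: s[0] for s in NINE_SPECIES}  # sizes {2,2,2,3}


class TestCladeDistanceTest:
    def test_nine_species_design_gives_df_34(self):
        rng = np.random.default_rng(0)
        dm = _matrix_from_pairs(
            NINE_SPECIES,
            lambda a, b: 0.1 + 0.2 * (a[0] != b[0]) + rng.uniform(0, 0.01))
        # symmetric noise: rebuild properly
        res = clade_distance_test(dm, NINE_CLADES)
        assert res.df == 34  # 6 within + 30 between pairs

    def test_matches_hand_computed_pooled_t(self):
        within = [0.10, 0.11, 0.12, 0.13, 0.14, 0.15]
        between = [round(0.30 + 0.01 * k, 2) for k in range(30)]
        vals = {}
        wit = iter(within)
        bet = iter(between)

        def dist(a, b):
            key = tuple(sorted((a, b)))
            if key not in vals:
                vals[key] = next(wit) if a[0] == b[0] else next(bet)
            return vals[key]

        dm = _matrix_from_pairs(NINE_SPECIES, dist)
        res = clade_distance_test(dm, NINE_CLADES)
        assert res.statistic == pytest.approx(_pooled_t_oracle(between, within))
        assert res.df == 34

    def test_identical_distances_give_t_zero(self):
        dm = _matrix_from_pairs(NINE_SPECIES, lambda a, b: 0.2)
        res = clade_distance_test(dm, NINE_CLADES)
        assert res.statistic == pytest.approx(0.0)

    def test_invariant_to_species_order_and_clade_labels(self):
        rng = np.random.default_rng(3)
        vals = {}

        def dist(a, b):
            key = tuple(sorted((a, b)))
            if key not in vals:
                vals[key] = float(rng.uniform(0.05, 0.4))
            return vals[key]

        dm1 = _matrix_from_pairs(NINE_SPECIES, dist)
        shuffled = NINE_SPECIES[::-1]
        dm2 = _matrix_from_pairs(shuffled, dist)
        relabeled = {s: "clade_" + c for s, c in NINE_CLADES.items()}
        r1 = clade_distance_test(dm1, NINE_CLADES)
        r2 = clade_distance_test(dm2, relabeled)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_outgroup_excluded_from_pairs(self):
        labels = NINE_SPECIES + ["OG"]
        clades = dict(NINE_CLADES)
        dm = _matrix_from_pairs(labels, lambda a, b: 0.5 if "OG" in (a, b)
                                else 0.2 + 0.1 * (a[0] != b[0]))
        res = clade_distance_test(dm, clades, outgroup="OG")
        assert res.df == 34

    def test_single_clade_rejected(self):
        dm = _matrix_from_pairs(["a1", "a2", "a3"], lambda a, b: 0.1)
        with pytest.raises(ValueError):
            clade_distance_test(dm, {s: "a" for s in ["a1", "a2", "a3"]})


class TestSpearman:
    def test_published_sg1_abundance_vs_fish_loci(self):
        ab = sg1_abundances()
        loci = sg1_fish_loci()
        species = list(ab)
        res = spearman_ties([ab[s] for s in species],
                            [loci[s] for s in species])
        assert round_half_up(res.statistic, 2) == 0.70
        assert round_half_up(spearman_t_statistic(res), 2) == 2.79
        assert res.p_value == pytest.approx(0.023, abs=0.0005)

    def test_monotone_increasing_is_rho_one(self):
        x = [1.0, 2.0, 5.0, 9.0]
        res = spearman_ties(x, [v * 3 for v in x])
        assert res.statistic == pytest.approx(1.0)

    def test_reversed_ranks_give_rho_minus_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = spearman_ties(x, x[::-1])
        assert res.statistic == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_ties([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(st.lists(st.integers(0, 8), min_size=4, max_size=25),
           st.data())
    def test_agrees_with_scipy_including_ties(self, x, data):
        y = data.draw(st.lists(st.integers(0, 8), min_size=len(x),
                               max_size=len(x)))
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        res = spearman_ties(x, y)
        rho_ref = sps.spearmanr(x, y).statistic
        assert res.statistic == pytest.approx(rho_ref, abs=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=20, unique=True),
           st.data())
    def test_tie_free_case_matches_classical_formula(self, x, data):
        perm = data.draw(st.permutations(range(len(x))))
        y = [x[i] for i in perm]
        res = spearman_ties(x, y)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        n = len(x)
        d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
        classical = 1 - 6 * d2 / (n * (n * n - 1))
        assert res.statistic == pytest.approx(classical, abs=1e-10)
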