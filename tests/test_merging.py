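"""Monte-Carlo merging and the quality-metric set."""

import numpy as np
import pandas as pd
import pytest

from pinksfx import merging, presets, truth
from pinksfx.errors import InvalidInputError, UndefinedMetricError
from pinksfx.geometry import UnitCell


def obs_frame(rows):
    """Observation table from (pattern, (h,k,l), minus, intensity) tuples."""
    return pd.DataFrame(
        {
            "pattern": [r[0] for r in rows],
            "ah": [r[1][0] for r in rows],
            "ak": [r[1][1] for r in rows],
            "al": [r[1][2] for r in rows],
            "minus": [r[2] for r in rows],
            "intensity": [float(r[3]) for r in rows],
            "sigma": [1.0] * len(rows),
        }
    )


CELL = UnitCell(58.52, 58.52, 151.30)


class TestMerge:
    def test_single_observation_passthrough(self):
        obs = obs_frame([(0, (1, 2, 3), False, 10.0)])
        mg = merging.merge(obs, CELL)
        assert len(mg) == 1
        row = mg.frame.iloc[0]
        assert row["I"] == 10.0
        assert row["sigma"] == 1.0  # falls back to the observation's sigma
        assert row["nobs"] == 1

    def test_toy_mean_and_sigma(self):
        obs = obs_frame(
            [(0, (1, 2, 3), False, 10.0), (1, (1, 2, 3), False, 12.0), (2, (1, 2, 3), False, 14.0)]
        )
        row = merging.merge(obs, CELL).frame.iloc[0]
        assert row["I"] == pytest.approx(12.0)
        assert row["sigma"] == pytest.approx(2.0 / np.sqrt(3))  # sd/sqrt(n)
        assert row["I_even"] == pytest.approx(12.0)  # patterns 0, 2
        assert row["I_odd"] == pytest.approx(12.0)

    def test_matches_groupby_oracle_on_random_observations(self, small_pink_dataset):
        obs = small_pink_dataset.observations()
        mg = merging.merge(obs, CELL, "P41212", outlier_sd=np.inf)
        # independent oracle: plain python accumulation
        acc = {}
        for row in obs.itertuples():
            key = (row.ah, row.ak, row.al, row.minus)
            acc.setdefault(key, []).append(row.intensity)
        assert len(acc) == len(mg)
        frame = mg.frame.set_index(["ah", "ak", "al", "minus"])
        rng = np.random.default_rng(0)
        keys = list(acc)
        for i in rng.choice(len(keys), 300):
            key = keys[i]
            assert frame.loc[key, "I"] == pytest.approx(np.mean(acc[key]), rel=1e-12)
            assert frame.loc[key, "nobs"] == len(acc[key])

    def test_outlier_clipped_once(self):
        rng = np.random.default_rng(4)
        values = list(10.0 + rng.normal(size=99)) + [1000.0]
        obs = obs_frame([(i, (1, 2, 3), False, v) for i, v in enumerate(values)])
        row = merging.merge(obs, CELL, outlier_sd=4.0).frame.iloc[0]
        assert row["nobs"] == 99
        assert row["I"] == pytest.approx(10.0, abs=0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            merging.merge(obs_frame([]), CELL)


class TestScaling:
    def test_identical_scales_recovered_as_unity(self, small_pink_dataset):
        obs = small_pink_dataset.observations().copy()
        # strip the simulated per-pattern scale jitter by merging duplicates
        scaled = merging.scale_patterns(obs)
        assert set(scaled.columns) >= {"pattern", "intensity", "sigma"}

    def test_known_scale_factor_recovered(self):
        rng = np.random.default_rng(1)
        rows = []
        intensities = rng.exponential(100, size=40)
        for p in range(4):
            factor = 5.0 if p == 3 else 1.0
            for j, inten in enumerate(intensities):
                rows.append((p, (j + 1, 0, 0), False, inten * factor))
        scaled = merging.scale_patterns(obs_frame(rows))
        by_pattern = scaled.groupby("pattern")["intensity"].sum()
        # pattern 3 deflated back to the common scale
        assert by_pattern[3] == pytest.approx(by_pattern[0], rel=1e-6)

    def test_scaling_reduces_r_split_on_jittered_data(self, small_pink_dataset):
        obs = small_pink_dataset.observations()
        raw = merging.r_split(merging.merge(obs, CELL, "P41212"))
        scaled = merging.r_split(merging.merge(merging.scale_patterns(obs), CELL, "P41212"))
        assert scaled < raw

    def test_single_pattern_rejected(self):
        with pytest.raises(InvalidInputError):
            merging.scale_patterns(obs_frame([(0, (1, 2, 3), False, 1.0)]))


def merged_from_halves(rows):
    """MergedDataset from (key, minus, I_even, I_odd) tuples."""
    frame = pd.DataFrame(
        {
            "ah": [r[0][0] for r in rows],
            "ak": [r[0][1] for r in rows],
            "al": [r[0][2] for r in rows],
            "minus": [r[1] for r in rows],
            "I_even": [r[2] for r in rows],
            "I_odd": [r[3] for r in rows],
        }
    )
    frame["I"] = (frame["I_even"] + frame["I_odd"]) / 2
    frame["sigma"] = 1.0
    frame["nobs"] = 2
    frame["n_even"] = 1
    frame["n_odd"] = 1
    frame["d"] = 3.0
    frame["centric"] = False
    return merging.MergedDataset(frame, CELL, "P41212", True, 2)


class TestRSplit:
    def test_identical_halves_give_zero(self):
        mg = merged_from_halves([((h, 2, 3), False, 10.0, 10.0) for h in range(1, 6)])
        assert merging.r_split(mg) == 0.0

    def test_doubled_half_value(self):
        # I_odd = 2 I_even for every reflection: 2^-1/2 / 1.5 * 100
        mg = merged_from_halves([((h, 2, 3), False, float(h), 2.0 * h) for h in range(1, 6)])
        assert merging.r_split(mg) == pytest.approx(100.0 / (1.5 * np.sqrt(2.0)))

    def test_hand_computed_toy_table(self):
        halves = [(10.0, 12.0), (20.0, 18.0), (5.0, 6.0), (8.0, 8.0), (15.0, 11.0)]
        mg = merged_from_halves(
            [((i + 1, 2, 3), False, a, b) for i, (a, b) in enumerate(halves)]
        )
        num = sum(abs(a - b) for a, b in halves)
        den = 0.5 * sum(a + b for a, b in halves)
        assert merging.r_split(mg) == pytest.approx(100.0 * num / (np.sqrt(2.0) * den))

    def test_disjoint_halves_undefined(self):
        mg = merged_from_halves([((1, 2, 3), False, 10.0, 10.0)])
        mg.frame.loc[:, "n_odd"] = 0
        with pytest.raises(UndefinedMetricError):
            merging.r_split(mg)


class TestCorrelations:
    @pytest.mark.parametrize(
        "cchalf,expected", [(0.869, 0.964), (0.501, 0.817), (1.0, 1.0)]
    )
    def test_cc_star_transform(self, cchalf, expected):
        assert merging.cc_star(cchalf) == pytest.approx(expected, abs=5e-4)

    def test_cc_half_perfect_halves(self):
        rng = np.random.default_rng(2)
        vals = rng.exponential(50, size=30)
        mg = merged_from_halves(
            [((i + 1, 2, 3), False, v, v) for i, v in enumerate(vals)]
        )
        assert merging.cc_half(mg) == pytest.approx(1.0)

    def test_cc_ano_identical_differences(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(20):
            base = rng.exponential(100)
            delta = rng.normal(0, 5)
            rows.append(((i + 1, i + 2, 7), False, base + delta, base + delta))
            rows.append(((i + 1, i + 2, 7), True, base, base))
        mg = merged_from_halves(rows)
        assert merging.cc_ano(mg) == pytest.approx(1.0)

    def test_cc_ano_null_when_no_anomalous_signal(self, thaumatin_cell, p41212):
        sf = truth.generate_structure_factors(
            thaumatin_cell, p41212, d_min=3.0, target_bijvoet_ratio=0.0, seed=21
        )
        from tests.conftest import cc_null_bound, make_dataset

        ds = make_dataset(sf, thaumatin_cell, p41212, "pink-6keV", 120, seed=21)
        mg = merging.merge(ds.observations(), thaumatin_cell, "P41212")
        both = mg.frame[(mg.frame["n_even"] > 0) & (mg.frame["n_odd"] > 0)]
        pairs = merging._anomalous_differences(both, ["I_even", "I_odd"])
        d_even = (pairs["I_even_p"] - pairs["I_even_m"]).to_numpy()
        d_odd = (pairs["I_odd_p"] - pairs["I_odd_m"]).to_numpy()
        assert abs(merging.cc_ano(mg)) < cc_null_bound(d_even, d_odd)

    def test_cc_anoref_truth_against_itself(self, truth_set):
        frame = pd.DataFrame(
            {
                "ah": truth_set.miller[:, 0],
                "ak": truth_set.miller[:, 1],
                "al": truth_set.miller[:, 2],
            }
        )
        plus = frame.assign(
            minus=False, I=truth_set.f_plus**2, sigma=1.0, nobs=2,
            I_even=truth_set.f_plus**2, I_odd=truth_set.f_plus**2,
            n_even=1, n_odd=1, d=truth_set.d, centric=truth_set.centric,
        )
        minus = frame.assign(
            minus=True, I=truth_set.f_minus**2, sigma=1.0, nobs=2,
            I_even=truth_set.f_minus**2, I_odd=truth_set.f_minus**2,
            n_even=1, n_odd=1, d=truth_set.d, centric=truth_set.centric,
        )
        mg = merging.MergedDataset(
            pd.concat([plus, minus], ignore_index=True), CELL, "P41212", True, 2
        )
        assert merging.cc_anoref(mg, truth_set) == pytest.approx(1.0, abs=1e-9)


class TestSummaries:
    def test_redundancy_of_uniform_triplets(self):
        obs = obs_frame(
            [(p, (h, 2, 3), False, 10.0) for h in range(1, 5) for p in range(3)]
        )
        mg = merging.merge(obs, CELL)
        assert merging.redundancy(mg) == 3.0

    def test_completeness_full_enumeration(self, thaumatin_cell, p41212):
        from pinksfx.geometry import enumerate_unique

        uniq = enumerate_unique(thaumatin_cell, p41212, 20.0, 8.0)
        rows = []
        for i, (m, cen) in enumerate(zip(uniq["miller"], uniq["centric"])):
            rows.append((i % 4, tuple(m), False, 50.0))
            if not cen:
                rows.append((i % 4, tuple(m), True, 50.0))
        mg = merging.merge(obs_frame(rows), thaumatin_cell, "P41212")
        assert merging.completeness(mg, 20.0, 8.0) == pytest.approx(100.0)

    def test_shell_boundaries_equal_volume(self):
        bounds = merging.shell_boundaries(24.8, 2.5, 10)
        inv3 = bounds**-3
        assert np.allclose(np.diff(inv3), np.diff(inv3)[0], rtol=1e-9)
        assert bounds[0] == pytest.approx(24.8)
        assert bounds[-1] == pytest.approx(2.5)

    def test_shell_table_covers_all_uniques(self, small_pink_dataset):
        obs = small_pink_dataset.observations()
        mg = merging.merge(obs, CELL, "P41212")
        table = merging.shell_table(mg, 6)
        assert table["n_unique"].sum() == len(mg)
        assert (table["d_max"].values[1:] == table["d_min"].values[:-1]).all()
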