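import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cgiset as cg
from cgiset.errors import ValidationError
from cgiset.matching import read_pairing, write_pairing


def _meta(rows):
    return cg.SampleMetadata(pd.DataFrame(rows))


class TestMatchPairs:
    def test_strict_caliper(self):
        meta = _meta([
            {"sample_id": "c1", "group": "case", "age": 50},
            {"sample_id": "c2", "group": "case", "age": 60},
            {"sample_id": "n1", "group": "control", "age": 51},
            {"sample_id": "n2", "group": "control", "age": 64},
        ])
        pairing = cg.match_pairs(meta, caliper=3)
        assert pairing.pairs == (("c1", "n1"),)
        assert pairing.unmatched_cases == ("c2",)  # gap 4 >= 3

    def test_gap_equal_to_caliper_is_excluded(self):
        # the age difference must be strictly LESS than the caliper
        meta = _meta([
            {"sample_id": "c1", "group": "case", "age": 53},
            {"sample_id": "n1", "group": "control", "age": 50},
        ])
        pairing = cg.match_pairs(meta, caliper=3)
        assert pairing.n_pairs == 0 and pairing.unmatched_cases == ("c1",)

    def test_one_control_many_cases(self):
        rows = [{"sample_id": f"c{a}", "group": "case", "age": a}
                for a in (40, 41, 42, 43)]
        rows.append({"sample_id": "n1", "group": "control", "age": 41})
        pairing = cg.match_pairs(_meta(rows), caliper=5, max_cases_per_control=4)
        assert pairing.n_pairs == 4
        assert all(b == "n1" for _, b in pairing.pairs)

    def test_exact_covariate_blocks_cross_group(self):
        meta = _meta([
            {"sample_id": "c1", "group": "case", "age": 50, "ethnicity": "A"},
            {"sample_id": "n1", "group": "control", "age": 50, "ethnicity": "B"},
            {"sample_id": "n2", "group": "control", "age": 54, "ethnicity": "A"},
        ])
        pairing = cg.match_pairs(meta, caliper=5, exact_on=("ethnicity",))
        assert pairing.pairs == (("c1", "n2"),)

    def test_invalid_caliper(self):
        meta = _meta([
            {"sample_id": "c1", "group": "case", "age": 50},
            {"sample_id": "n1", "group": "control", "age": 50},
        ])
        with pytest.raises(ValidationError):
            cg.match_pairs(meta, caliper=0)

    def test_no_match_warns_not_raises(self):
        meta = _meta([
            {"sample_id": "c1", "group": "case", "age": 20},
            {"sample_id": "n1", "group": "control", "age": 80},
        ])
        with pytest.warns(UserWarning):
            pairing = cg.match_pairs(meta, caliper=3)
        assert pairing.n_pairs == 0

    def test_constraints_hold_on_random_cohorts(self):
        # every emitted pair must satisfy the caliper and exact covariates
        for seed in range(5):
            meta, *_ = cg.simulate_matched_cohort(
                n_cases=25, n_controls=20, m_probes=4, seed=seed
            )
            pairing = cg.match_pairs(meta, caliper=3, exact_on=("ethnicity",),
                                     max_cases_per_control=2)
            tab = meta.table.set_index("sample_id")
            for a, b in pairing.pairs:
                assert abs(tab.at[a, "age"] - tab.at[b, "age"]) < 3
                assert tab.at[a, "ethnicity"] == tab.at[b, "ethnicity"]

    def test_pairing_round_trip(self, tmp_path):
        pairing = cg.Pairing((("c1", "n1"), ("c2", "n1")), caliper=5.0,
                             exact_on=("ethnicity",), max_cases_per_control=2,
                             unmatched_cases=("c3",))
        write_pairing(pairing, tmp_path / "pairs.tsv")
        back = read_pairing(tmp_path / "pairs.tsv")
        assert back == pairing


class TestComputeTheta:
    def _beta(self, probe_ids, sample_ids, vals):
        return cg.BetaMatrix(probe_ids, sample_ids, np.asarray(vals, float))

    def test_simple_difference(self):
        cases = self._beta(("p1",), ("c1",), [[0.8]])
        ctrls = self._beta(("p1",), ("n1",), [[0.3]])
        pairing = cg.Pairing((("c1", "n1"),), caliper=3)
        theta = cg.compute_theta(cases, ctrls, pairing)
        assert theta.theta[0, 0] == pytest.approx(0.5)

    def test_identical_matrices_give_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.random((5, 3))
        cases = self._beta(tuple("pqrst"), ("c1", "c2", "c3"), vals)
        ctrls = self._beta(tuple("pqrst"), ("n1", "n2", "n3"), vals)
        pairing = cg.Pairing((("c1", "n1"), ("c2", "n2"), ("c3", "n3")), caliper=3)
        assert np.all(cg.compute_theta(cases, ctrls, pairing).theta == 0.0)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        m, n = 30, 20
        probe_ids = tuple(f"p{i}" for i in range(m))
        cvals, nvals = rng.random((m, n)), rng.random((m, n))
        cases = self._beta(probe_ids, tuple(f"c{i}" for i in range(n)), cvals)
        ctrls = self._beta(probe_ids, tuple(f"n{i}" for i in range(n)), nvals)
        pairing = cg.Pairing(tuple((f"c{i}", f"n{i}") for i in range(n)), caliper=3)
        theta = cg.compute_theta(cases, ctrls, pairing)
        for i in range(n):
            for j in range(m):
                assert theta.theta[i, j] == cvals[j, i] - nvals[j, i]

    def test_linearity_in_inputs(self):
        rng = np.random.default_rng(2)
        vals_c, vals_n = rng.random((4, 2)), rng.random((4, 2))
        ids = tuple("wxyz")
        pairing = cg.Pairing((("c1", "n1"), ("c2", "n2")), caliper=3)
        a = 0.5
        t1 = cg.compute_theta(
            self._beta(ids, ("c1", "c2"), a * vals_c),
            self._beta(ids, ("n1", "n2"), a * vals_n), pairing)
        t2 = cg.compute_theta(
            self._beta(ids, ("c1", "c2"), vals_c),
            self._beta(ids, ("n1", "n2"), vals_n), pairing)
        np.testing.assert_allclose(t1.theta, a * t2.theta, atol=1e-15)

    def test_missing_probes_dropped(self):
        vals = np.array([[0.5, 0.4], [np.nan, 0.2]])
        cases = self._beta(("p1", "p2"), ("c1", "c2"), vals)
        ctrls = self._beta(("p1", "p2"), ("n1", "n2"), np.full((2, 2), 0.1))
        pairing = cg.Pairing((("c1", "n1"), ("c2", "n2")), caliper=3)
        theta = cg.compute_theta(cases, ctrls, pairing)
        assert theta.probe_ids == ("p1",)


class TestCgiDispersion:
    def _ann(self, cgi):
        cgi = np.asarray(cgi, bool)
        return cg.ProbeAnnotation(
            tuple(f"p{i}" for i in range(len(cgi))),
            tuple(f"G{i}" for i in range(len(cgi))), cgi)

    def test_all_zero_theta(self):
        theta = cg.PairedDifferenceMatrix(
            ("a", "b"), ("p0", "p1", "p2", "p3"), np.zeros((2, 4)))
        s = cg.cgi_dispersion_summary(theta, self._ann([1, 1, 0, 0]))
        assert s.mean_cgi == 0 and s.var_cgi == 0
        assert s.mean_non_cgi == 0 and s.var_non_cgi == 0

    def test_cgi_probes_disperse_more(self):
        rng = np.random.default_rng(9)
        n, m = 50, 100
        cgi = np.arange(m) < 76
        vals = np.where(cgi, rng.normal(0, 0.2, (n, m)), rng.normal(0, 0.05, (n, m)))
        theta = cg.PairedDifferenceMatrix(
            tuple(f"pr{i}" for i in range(n)), tuple(f"p{j}" for j in range(m)),
            np.clip(vals, -1, 1))
        s = cg.cgi_dispersion_summary(theta, self._ann(cgi))
        assert s.var_cgi > s.var_non_cgi
        assert s.comparable and np.isfinite(s.welch_t)

    def test_single_stratum_flagged_not_raised(self):
        theta = cg.PairedDifferenceMatrix(
            ("a", "b"), ("p0", "p1"), np.full((2, 2), 0.1))
        s = cg.cgi_dispersion_summary(theta, self._ann([1, 1]))
        assert not s.comparable and np.isnan(s.welch_t)


class TestPairedTBaseline:
    def test_bonferroni_threshold_with_array_panel_size(self):
        rng = np.random.default_rng(4)
        theta = cg.PairedDifferenceMatrix(
            ("a", "b", "c"), tuple(f"p{j}" for j in range(1675)),
            rng.uniform(-0.1, 0.1, (3, 1675)))
        tab = cg.paired_t_baseline(theta, alpha=0.05)
        assert tab["threshold"].iloc[0] == pytest.approx(0.05 / 1675)
        assert tab["threshold"].iloc[0] < 3e-5  # the printed per-test bound

    def test_zero_variance_column_degenerate(self):
        theta = cg.PairedDifferenceMatrix(
            ("a", "b", "c"), ("p0", "p1"),
            np.column_stack([np.zeros(3), [0.1, 0.2, 0.15]]))
        tab = cg.paired_t_baseline(theta)
        assert bool(tab["degenerate"].iloc[0]) and tab["p_value"].iloc[0] == 1.0
        assert not tab["significant"].iloc[0]

    def test_shifted_column_matches_closed_form_t(self):
        rng = np.random.default_rng(5)
        n, m = 30, 10
        vals = rng.normal(0, 0.01, (n, m))
        vals[:, 0] += 0.3
        theta = cg.PairedDifferenceMatrix(
            tuple(f"pr{i}" for i in range(n)), tuple(f"p{j}" for j in range(m)),
            np.clip(vals, -1, 1))
        tab = cg.paired_t_baseline(theta, alpha=0.05)
        col = theta.theta[:, 0]
        t_hand = col.mean() / (col.std(ddof=1) / np.sqrt(n))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=n - 1)
        assert tab["t_stat"].iloc[0] == pytest.approx(t_hand)
        assert tab["p_value"].iloc[0] == pytest.approx(p_hand, rel=1e-10)
        assert bool(tab["significant"].iloc[0])

    def test_bonferroni_subset_of_uncorrected(self):
        rng = np.random.default_rng(6)
        theta = cg.PairedDifferenceMatrix(
            tuple(f"pr{i}" for i in range(20)), tuple(f"p{j}" for j in range(50)),
            np.clip(rng.normal(0.02, 0.05, (20, 50)), -1, 1))
        bonf = cg.paired_t_baseline(theta, correction="bonferroni")
        unc = cg.paired_t_baseline(theta, correction="none")
        assert set(bonf[bonf["significant"]]["probe_id"]) <= \
            set(unc[unc["significant"]]["probe_id"])
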