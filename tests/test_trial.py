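"""Virtual trial machinery: LHS, screening, RECIST, response statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tcesim.invitro import HillParams
from tcesim.patient import PatientParams
from tcesim.trial import (ParameterRange, ParameterRanges, build_patient,
                          classify_recist, default_parameter_ranges, lhs_sample,
                          response_rate_ci, run_trial, screen_cohort,
                          subgroup_response)


class TestLHS:
    def test_one_sample_per_quartile(self):
        ranges = ParameterRanges([("x", 0.0, 1.0, "linear")])
        df = lhs_sample(ranges, 4, seed=3)
        counts, _ = np.histogram(df["x"], bins=[0, 0.25, 0.5, 0.75, 1.0])
        assert np.all(counts == 1)

    def test_stratification_on_log_scale(self):
        ranges = ParameterRanges([("x", 1.0, 10000.0, "log")])
        n = 8
        df = lhs_sample(ranges, n, seed=5)
        edges = np.logspace(0, 4, n + 1)
        counts, _ = np.histogram(df["x"], bins=edges)
        assert np.all(counts == 1)

    def test_reproducible(self):
        r = default_parameter_ranges()
        a = lhs_sample(r, 50, seed=11)
        b = lhs_sample(r, 50, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_marginal_uniformity_ks(self):
        """KS statistic vs uniform below the 5% critical value at n=1000."""
        r = default_parameter_ranges()
        df = lhs_sample(r, 1000, seed=2)
        crit = 1.358 / math.sqrt(1000)
        for pr in r:
            x = df[pr.name].to_numpy()
            if pr.scale == "log":
                u = (np.log(x) - np.log(pr.lower)) / (np.log(pr.upper) - np.log(pr.lower))
            else:
                u = (x - pr.lower) / (pr.upper - pr.lower)
            stat = sps.kstest(u, "uniform").statistic
            assert stat < crit

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            ParameterRange("x", 2.0, 1.0)
        with pytest.raises(ValueError):
            ParameterRange("x", -1.0, 1.0, "log")
        with pytest.raises(ValueError):
            lhs_sample(default_parameter_ranges(), 0, seed=0)


class TestBuildPatient:
    def test_patient_fields_take_priority(self):
        row = {"patient_id": 0, "cea_sites": 1234.0, "lambda_crossarm": 77.0,
               "koff_cd3tce": 2e-4, "tmb": 55.0}
        p = build_patient(row)
        assert p.cea_sites == 1234.0           # PatientParams field
        assert p.binding.lambda_crossarm == 77.0  # binding-only field
        assert p.binding.koff_cd3tce == 2e-4
        assert p.tmb == 55.0
        # the synapse view propagates the patient's CEA expression
        assert p.synapse_binding("teff").cea_sites == 1234.0

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            build_patient({"no_such_parameter": 1.0})


class TestClassifyRecist:
    def test_flat_series_is_sd(self):
        assert classify_recist(3.0, [3.0] * 10) == "SD"

    def test_minus_35_is_pr(self):
        assert classify_recist(3.0, [3.0, 2.5, 1.95]) == "PR"

    def test_plus_25_from_nadir_is_pd(self):
        assert classify_recist(3.0, [3.0, 3.1, 3.75]) == "PD"

    def test_cr_below_floor(self):
        assert classify_recist(3.0, [3.0, 1.0, 0.1]) == "CR"

    def test_small_absolute_increase_is_not_pd(self):
        # +25% from nadir but under the 5 mm absolute guard
        assert classify_recist(1.0, [1.0, 0.8, 1.0]) == "SD"

    def test_dip_then_regrow_keeps_best_response(self):
        assert classify_recist(3.0, [3.0, 1.8, 2.8]) == "PR"

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            classify_recist(3.0, [])


class TestResponseRateCI:
    def test_published_cohort_rate(self):
        rate, lo, hi = response_rate_ci(130, 1750)
        assert round(100 * rate, 1) == 7.4

    def test_zero_responders_clipped(self):
        rate, lo, hi = response_rate_ci(0, 50)
        assert rate == 0.0 and lo == 0.0 and hi > 0.0

    def test_hand_computed_bounds(self):
        # x=50, n=100, z=1.959964: ntilde=n+z^2, ptilde=(x+z^2/2)/ntilde
        z = sps.norm.ppf(0.975)
        ntilde = 100 + z * z
        ptilde = (50 + z * z / 2) / ntilde
        half = z * math.sqrt(ptilde * (1 - ptilde) / ntilde)
        rate, lo, hi = response_rate_ci(50, 100)
        assert lo == pytest.approx(ptilde - half, abs=1e-10)
        assert hi == pytest.approx(ptilde + half, abs=1e-10)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            response_rate_ci(5, 4)
        with pytest.raises(ValueError):
            response_rate_ci(0, 0)


class TestSubgroupResponse:
    @staticmethod
    def _fake_cohort(n=1750, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"x": rng.uniform(size=n)})
        df["recist"] = np.where(df["x"] > 0.9, "PR", "PD")
        return df

    def test_17_bins_sizes_differ_at_most_one(self):
        df = self._fake_cohort()
        table = subgroup_response(df, "x", split=17)
        sizes = table["n"].to_numpy()
        assert sizes.sum() == len(df)
        assert sizes.max() - sizes.min() <= 1

    def test_zero_responder_subgroup(self):
        df = self._fake_cohort()
        table = subgroup_response(df, "x", split="median")
        below = table.iloc[0]
        assert below["responders"] == 0 and below["orr"] == 0.0

    def test_constant_parameter_rejected(self):
        df = self._fake_cohort()
        df["x"] = 1.0
        with pytest.raises(ValueError):
            subgroup_response(df, "x")


class TestScreening:
    def test_zero_growth_excluded(self):
        samples = pd.DataFrame([{"patient_id": 0, "growth_rate": 0.0}])
        plausible, excluded, _ = screen_cohort(samples)
        assert len(plausible) == 0 and len(excluded) == 1
        assert "did not reach" in excluded.iloc[0]["reason"]

    def test_viable_patient_not_excluded(self):
        samples = pd.DataFrame([{"patient_id": 0, "growth_rate": 0.015,
                                 "tmb": 50.0}])
        plausible, excluded, grown = screen_cohort(samples)
        assert len(plausible) == 1 and len(excluded) == 0
        assert 0 in grown


@pytest.fixture(scope="module")
def tiny():
    return run_trial(n=8, seed=4, t_end=120.0)


class TestSmallTrial:

    def test_categories_partition_cohort(self, tiny):
        assert sum(tiny.category_counts().values()) == tiny.n_plausible
        assert tiny.n_plausible + tiny.n_excluded == 8

    def test_subgroup_orr_consistent_with_whole(self, tiny):
        if tiny.n_plausible >= 2 and tiny.patients["tmb"].nunique() > 1:
            table = subgroup_response(tiny, "tmb")
            weighted = (table["orr"] * table["n"]).sum() / table["n"].sum()
            assert weighted == pytest.approx(tiny.orr()[0], abs=1e-12)

    def test_no_killing_no_spurious_responders(self):
        """With all killing disabled, every plausible patient is PD or SD."""
        ranges = ParameterRanges([
            ("tmb", 10.0, 2000.0, "log"),
            ("growth_rate", 0.008, 0.03, "log"),
            ("cea_sites", 1e3, 1e6, "log"),
        ])
        base = PatientParams(
            k_kill_base=0.0,
            hill_kill=HillParams(d50=248.2, n_hill=3.0, k_max=0.0))
        res = run_trial(n=6, seed=9, ranges=ranges, base=base, t_end=120.0)
        assert set(res.patients["recist"]) <= {"PD", "SD"}
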