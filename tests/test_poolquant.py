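"""Probe QC, strain-frequency estimation, and standard curves."""

import numpy as np
import pandas as pd
import pytest

from mipmeter.poolquant import (QcThresholds, mip_frequency, qc_panel,
                                qc_probe, standard_curve_eval,
                                strain_frequencies)
from mipmeter.readquant import AlleleCountRecord, frame_to_records
from mipmeter.simulate import SimConfig, simulate_equimolar_pilot, simulate_trajectories


def rec(probe="p1", sample="pilot", ref=0, alt=0, oa=0, ob=0):
    return AlleleCountRecord(probe, sample, n_ref=ref, n_alt=alt,
                             n_other_a=oa, n_other_b=ob)


class TestMipFrequency:
    @pytest.mark.parametrize("alt,ref,want", [(0, 1000, 0.0), (500, 500, 0.5),
                                              (970, 99030, 0.0097)])
    def test_alt_over_alt_plus_ref(self, alt, ref, want):
        assert mip_frequency(rec(ref=ref, alt=alt)) == pytest.approx(want)

    def test_other_reads_excluded_from_denominator(self):
        assert mip_frequency(rec(ref=50, alt=50, oa=1000, ob=1000)) == 0.5

    def test_no_ref_alt_reads_warns_and_returns_none(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert mip_frequency(rec(oa=10)) is None


class TestQcProbe:
    thr = QcThresholds(n_strains=103)

    def test_far_off_frequency_fails_band(self):
        r = qc_probe(rec(ref=50_000, alt=50_000), self.thr)
        assert r.fail_reasons == {"band"} and not r.passed

    def test_low_total_fails_total(self):
        # ~1/103 frequency but only 10,000 alt+ref reads
        r = qc_probe(rec(ref=9_903, alt=97), self.thr)
        assert r.fail_reasons == {"total"}

    def test_excess_other_reads_fail_other(self):
        r = qc_probe(rec(ref=99_000, alt=1_000, oa=12_500, ob=12_500), self.thr)
        assert r.fail_reasons == {"other"}

    def test_all_three_criteria_reported_together(self):
        r = qc_probe(rec(ref=100, alt=9_900, oa=25_000, ob=0), self.thr)
        assert r.fail_reasons == {"band", "other", "total"}

    def test_band_boundary_exactly_3_5_fold_passes(self):
        # alt/(alt+ref) = 3500/103000 = exactly 3.5x the expected 1/103
        r = qc_probe(rec(ref=99_500, alt=3_500), self.thr)
        assert r.passed
        # one read beyond the closed band fails
        r = qc_probe(rec(ref=99_499, alt=3_501), self.thr)
        assert r.fail_reasons == {"band"}
        # lower boundary: 1/(103*3.5) of the 103,000 total (not integral, so
        # bracket it): 285 reads is below, 286 is above
        assert qc_probe(rec(ref=102_714, alt=286), self.thr).passed
        assert "band" in qc_probe(rec(ref=102_715, alt=285), self.thr).fail_reasons

    def test_exempt_probe_bypasses_but_stays_flagged(self):
        r = qc_probe(rec(ref=50_000, alt=50_000), self.thr, exempt=True)
        assert not r.passed and r.exempt and r.usable

    def test_scaled_thresholds(self):
        thr = QcThresholds(n_strains=10).scaled(0.01)
        assert thr.total_min == 200 and thr.total_max == 20_000
        assert thr.other_max == 200
        assert thr.fold_band == 3.5  # band is relative, never rescaled


class TestStrainFrequencies:
    probe_strain = {"p1": "A", "p2": "A", "p3": "B"}

    def test_unweighted_mean_of_passing_probes(self):
        counts = [rec("p1", "s", ref=990, alt=10), rec("p2", "s", ref=988, alt=12),
                  rec("p3", "s", ref=500, alt=500)]
        freq, drop = strain_frequencies(counts, None, self.probe_strain)
        f = freq.set_index("strain_id")
        assert f.loc["A", "frequency"] == pytest.approx((0.01 + 12 / 1000) / 2)
        assert f.loc["A", "n_probes_used"] == 2
        assert f.loc["B", "frequency"] == 0.5 and f.loc["B", "n_probes_used"] == 1
        assert drop.empty

    def test_failed_probes_excluded_and_dropout_reported(self):
        thr = QcThresholds(n_strains=2, total_min=100, total_max=10_000, other_max=50)
        counts = [rec("p1", "s", ref=500, alt=500), rec("p2", "s", ref=5, alt=5),
                  rec("p3", "s", ref=3, alt=3)]
        qc = qc_panel(counts, thr, probe_strain=self.probe_strain)
        freq, drop = strain_frequencies(counts, qc, self.probe_strain)
        assert list(freq["strain_id"]) == ["A"]
        assert freq["n_probes_used"].iloc[0] == 1
        assert list(drop.itertuples(index=False)) == [("s", "B")]

    def test_permutation_invariance(self):
        counts = [rec("p1", "s", ref=990, alt=10), rec("p2", "s", ref=980, alt=20),
                  rec("p3", "s", ref=900, alt=100)]
        f1, _ = strain_frequencies(counts, None, self.probe_strain)
        f2, _ = strain_frequencies(counts[::-1], None, self.probe_strain)
        assert f1.sort_values("strain_id").reset_index(drop=True).equals(
            f2.sort_values("strain_id").reset_index(drop=True))

    def test_estimator_unbiased_on_unbiased_pilots(self):
        # 200 pilot replicates without capture bias: mean estimate of each
        # strain within 3 standard errors of the true 1/S
        S, n_rep = 5, 200
        means = []
        for seed in range(n_rep):
            cfg = SimConfig(n_strains=S, strain_half_life=np.full(S, 10.0),
                            probes_per_strain=2, probe_depth_mean=400,
                            probe_bias_sd=0.0, seed=seed)
            truth = simulate_trajectories(cfg)
            pilot, _ = simulate_equimolar_pilot(cfg)
            freq, _ = strain_frequencies(frame_to_records(pilot), None,
                                         truth.probe_strain)
            means.append(freq.set_index("strain_id")["frequency"])
        est = pd.concat(means, axis=1).mean(axis=1)
        se = pd.concat(means, axis=1).std(axis=1, ddof=1) / np.sqrt(n_rep)
        assert (np.abs(est - 1 / S) <= 3 * se).all()


class TestStandardCurve:
    def test_perfect_fit(self):
        obs = pd.DataFrame({"strain_id": list("abc"), "frequency": [0.001, 0.01, 0.1]})
        exp = pd.DataFrame({"strain_id": list("abc"),
                            "known_proportion": [0.001, 0.01, 0.1]})
        fit = standard_curve_eval(obs, exp)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_regression_on_logs(self):
        # closed-form least squares on (log10 expected, log10 observed)
        obs = pd.DataFrame({"strain_id": list("abc"),
                            "frequency": [0.0012, 0.009, 0.11]})
        exp = pd.DataFrame({"strain_id": list("abc"),
                            "known_proportion": [0.001, 0.01, 0.1]})
        x = np.log10(exp["known_proportion"].to_numpy())
        y = np.log10(obs["frequency"].to_numpy())
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        r2 = sxy ** 2 / (sxx * ((y - y.mean()) ** 2).sum())
        fit = standard_curve_eval(obs, exp)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(y.mean() - slope * x.mean())
        assert fit.r_squared == pytest.approx(r2)

    def test_zero_observations_floored_with_warning(self):
        obs = pd.DataFrame({"strain_id": list("abcd"),
                            "frequency": [0.0, 0.002, 0.02, 0.2]})
        exp = pd.DataFrame({"strain_id": list("abcd"),
                            "known_proportion": [1e-4, 1e-3, 1e-2, 1e-1]})
        with pytest.warns(UserWarning, match="flooring"):
            fit = standard_curve_eval(obs, exp)
        assert np.isfinite(fit.r_squared)
        assert fit.residuals["log10_observed"].iloc[0] == pytest.approx(np.log10(0.001))

    def test_too_few_strains_rejected(self):
        obs = pd.DataFrame({"strain_id": ["a", "b"], "frequency": [0.1, 0.2]})
        exp = pd.DataFrame({"strain_id": ["a", "b"], "known_proportion": [0.1, 0.2]})
        with pytest.raises(ValueError, match="at least 3"):
            standard_curve_eval(obs, exp)
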