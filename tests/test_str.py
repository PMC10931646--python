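import pytest

from chimkin.config import AnalysisConfig
from chimkin.simulate import SimulationConfig, simulate_str_profiles
from chimkin.str_analysis import (STRChimerismModel, STRProfile,
                                  correct_stutter, select_informative_str)


def profile(**markers):
    """Build a single-subject profile from genotype tuples, equal areas."""
    peaks, genotypes = {}, {}
    for marker, alleles in markers.items():
        areas = {}
        for a in alleles:
            areas[a] = areas.get(a, 0.0) + 5000.0
        peaks[marker] = areas
        genotypes[marker] = tuple(alleles)
    return STRProfile(peaks, genotypes=genotypes)


class TestSelectInformative:
    def test_partially_shared_heterozygotes(self):
        rec = profile(m1=(12, 14))
        don = profile(m1=(12, 15))
        (info,) = select_informative_str(rec, don)
        assert info.recipient_unique == {14}
        assert info.donor_unique == {15}
        assert info.recipient_unique_copies == 1

    def test_identical_genotypes_not_informative(self):
        rec = profile(m1=(12, 15))
        don = profile(m1=(12, 15))
        assert select_informative_str(rec, don) == []

    def test_homozygous_recipient(self):
        rec = profile(m1=(13, 13))
        don = profile(m1=(12, 14))
        (info,) = select_informative_str(rec, don)
        assert info.recipient_unique == {13}
        assert info.recipient_unique_copies == 2

    def test_disjoint_marker_sets_error(self):
        rec = profile(m1=(12, 14))
        don = profile(m2=(12, 15))
        with pytest.raises(ValueError, match="share no markers"):
            select_informative_str(rec, don)


class TestComputeChimerism:
    def test_single_marker_direct_proportion(self):
        """Fully distinguishable heterozygotes: 50 vs 950 area -> 5%."""
        rec = profile(m1=(13, 14))
        don = profile(m1=(11, 12))
        mixed = STRProfile({"m1": {13: 25.0, 14: 25.0, 11: 475.0, 12: 475.0}})
        res = STRChimerismModel(mixed, rec, don,
                                config=AnalysisConfig(min_informative=1)).fit()
        assert res.value_pct == pytest.approx(5.0)

    def test_mean_over_markers(self):
        rec = profile(m1=(13, 14), m2=(13, 14))
        don = profile(m1=(11, 12), m2=(11, 12))
        mixed = STRProfile({
            "m1": {13: 20.0, 14: 20.0, 11: 480.0, 12: 480.0},   # 4%
            "m2": {13: 30.0, 14: 30.0, 11: 470.0, 12: 470.0},   # 6%
        })
        res = STRChimerismModel(mixed, rec, don,
                                config=AnalysisConfig(min_informative=2)).fit()
        assert res.value_pct == pytest.approx(5.0)

    def test_no_recipient_peaks_censored_at_floor(self):
        rec = profile(m1=(13, 14), m2=(13, 14), m3=(13, 14))
        don = profile(m1=(11, 12), m2=(11, 12), m3=(11, 12))
        mixed = STRProfile({m: {11: 500.0, 12: 500.0} for m in ("m1", "m2", "m3")})
        res = STRChimerismModel(mixed, rec, don).fit()
        assert res.censored
        assert res.value_pct == 0.8

    def test_insufficient_markers_flagged(self):
        rec = profile(m1=(12, 14))
        don = profile(m1=(12, 15))
        mixed = STRProfile({"m1": {14: 50.0, 15: 950.0}})
        res = STRChimerismModel(mixed, rec, don).fit()
        assert res.qc_status == "fail"

    def test_zygosity_scaling_hom_vs_het(self):
        """Homozygous recipient vs fully distinct donor at 5% mixture."""
        rec = profile(m1=(13, 13))
        don = profile(m1=(11, 12))
        # areas proportional to genome share x allele copies / 2
        mixed = STRProfile({"m1": {13: 50.0, 11: 475.0, 12: 475.0}})
        res = STRChimerismModel(mixed, rec, don,
                                config=AnalysisConfig(min_informative=1)).fit()
        assert res.value_pct == pytest.approx(5.0)

    def test_shared_allele_uses_unique_subsets(self):
        """One shared allele: unique peaks alone still recover the truth."""
        f = 0.05
        rec = profile(m1=(12, 14))
        don = profile(m1=(12, 15))
        mixed = STRProfile({"m1": {
            14: 1000 * f / 2, 15: 1000 * (1 - f) / 2,
            12: 1000 * f / 2 + 1000 * (1 - f) / 2,
        }})
        res = STRChimerismModel(mixed, rec, don,
                                config=AnalysisConfig(min_informative=1)).fit()
        assert res.value_pct == pytest.approx(5.0)

    def test_invariant_under_uniform_area_rescale(self):
        rec = profile(m1=(13, 14), m2=(13, 13), m3=(12, 14))
        don = profile(m1=(11, 12), m2=(11, 12), m3=(12, 15))
        base = {
            "m1": {13: 30.0, 14: 30.0, 11: 470.0, 12: 470.0},
            "m2": {13: 60.0, 11: 470.0, 12: 470.0},
            "m3": {14: 30.0, 15: 470.0, 12: 500.0},
        }
        scaled = {m: {a: 7.3 * v for a, v in d.items()} for m, d in base.items()}
        r1 = STRChimerismModel(STRProfile(base), rec, don).fit()
        r2 = STRChimerismModel(STRProfile(scaled), rec, don).fit()
        assert r1.value_pct == pytest.approx(r2.value_pct)
        assert r1.n_informative == r2.n_informative


class TestStutter:
    def test_subtracts_expected_stutter(self):
        p = STRProfile({"m1": {14: 1000.0, 13: 120.0}})
        out = correct_stutter(p, 0.1)
        assert out.peaks["m1"][13] == pytest.approx(20.0)
        assert out.peaks["m1"][14] == pytest.approx(1000.0)

    def test_zero_ratio_is_identity(self):
        p = STRProfile({"m1": {14: 1000.0, 13: 120.0}})
        assert correct_stutter(p, 0.0) is p

    def test_floors_at_zero(self):
        p = STRProfile({"m1": {14: 1000.0, 13: 50.0}})
        out = correct_stutter(p, 0.1)
        assert out.peaks["m1"][13] == 0.0

    def test_ratio_out_of_range(self):
        p = STRProfile({"m1": {14: 1000.0}})
        with pytest.raises(ValueError):
            correct_stutter(p, 0.3)


class TestSimulatedMixtures:
    @pytest.mark.parametrize("true_pct", [2.0, 5.0, 20.0, 50.0])
    def test_exact_recovery_without_stutter(self, true_pct):
        cfg = SimulationConfig(
            seed=11, true_fractions={"recipient": true_pct, "donor": 100 - true_pct}
        )
        ref, mixed = simulate_str_profiles(cfg)
        res = STRChimerismModel(mixed, ref["recipient"], ref["donor"]).fit()
        if res.qc_status == "pass":
            assert res.value_pct == pytest.approx(true_pct, abs=1e-9)

    def test_below_lod_censored(self):
        cfg = SimulationConfig(
            seed=12, true_fractions={"recipient": 0.5, "donor": 99.5}
        )
        ref, mixed = simulate_str_profiles(cfg)
        res = STRChimerismModel(mixed, ref["recipient"], ref["donor"]).fit()
        assert res.censored
        assert res.value_pct == 0.8

    def test_stutter_correction_restores_estimate(self):
        cfg = SimulationConfig(
            seed=13, true_fractions={"recipient": 5.0, "donor": 95.0},
            stutter_ratio=0.08,
        )
        ref, mixed = simulate_str_profiles(cfg)
        raw = STRChimerismModel(mixed, ref["recipient"], ref["donor"]).fit()
        corrected = STRChimerismModel(
            mixed, ref["recipient"], ref["donor"], stutter_ratio=0.08
        ).fit()
        truth = 5.0
        assert abs(corrected.value_pct - truth) <= abs(raw.value_pct - truth) + 1e-9
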