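import numpy as np
import pytest

from chimkin.config import AnalysisConfig
from chimkin.simulate import (SimulationConfig, simulate_genotypes,
                              simulate_mixture_counts)
from chimkin.snp import (InfoClass, SNPChimerismModel, apply_loq,
                         classify_informative)

from conftest import make_noiseless_counts

NOISELESS = AnalysisConfig(error_rate=0.0)


class TestClassifyInformative:
    @pytest.mark.parametrize(
        "genotypes, info_class, subject, allele, scale",
        [
            ({"recipient": 1, "donor": 0}, InfoClass.HET_VS_HOM, "recipient", "alt", 2),
            ({"recipient": 1, "donor": 2}, InfoClass.HET_VS_HOM, "recipient", "ref", 2),
            ({"recipient": 2, "donor": 0}, InfoClass.OPP_HOM, "recipient", "alt", 1),
            ({"recipient": 0, "donor": 2}, InfoClass.OPP_HOM, "recipient", "ref", 1),
            ({"recipient": 0, "donor1": 1, "donor2": 0},
             InfoClass.HET_VS_HOM, "donor1", "alt", 2),
            ({"recipient": 2, "donor1": 0, "donor2": 0},
             InfoClass.OPP_HOM, "recipient", "alt", 1),
            ({"recipient": 0, "donor1": 2, "donor2": 2},
             InfoClass.OPP_HOM, "recipient", "ref", 1),
        ],
    )
    def test_informative_configurations(self, genotypes, info_class, subject,
                                        allele, scale):
        info = classify_informative(genotypes, "rs1")
        assert info is not None
        assert info.info_class is info_class
        assert info.signal_subject == subject
        assert info.signal_allele == allele
        assert info.scale == scale

    @pytest.mark.parametrize(
        "genotypes",
        [
            {"recipient": 1, "donor": 1},           # identical genotypes
            {"recipient": 0, "donor": 0},
            {"recipient": 1, "donor1": 0, "donor2": 1},  # others not identical hom
            {"recipient": 1, "donor1": 0, "donor2": 2},  # opposed homs behind a het
            {"recipient": 2, "donor1": 0, "donor2": 2},  # no unique singleton? -> donor1
            {"recipient": None, "donor": 0},          # missing call
        ],
    )
    def test_not_informative_or_missing(self, genotypes):
        info = classify_informative(genotypes, "rs1")
        if genotypes == {"recipient": 2, "donor1": 0, "donor2": 2}:
            # the lone opposite homozygote is the exposed contributor
            assert info is not None and info.signal_subject == "donor1"
        else:
            assert info is None

    def test_requires_two_genotypes(self):
        with pytest.raises(ValueError):
            classify_informative({"recipient": 1}, "rs1")


class TestApplyLoq:
    @pytest.mark.parametrize(
        "value, expected, censored",
        [(0.20, 0.36, True), (0.41, 0.41, False), (0.36, 0.36, False)],
    )
    def test_floor(self, value, expected, censored):
        assert apply_loq(value) == (expected, censored)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            apply_loq(-0.1)

    def test_idempotent(self):
        once = apply_loq(0.1)
        assert apply_loq(once[0]) == (once[0], False)


def _hand_profiles(n_opp=4, n_het=4):
    """Small profile set: opposite-homozygote and het-vs-hom loci."""
    recipient, donor = {}, {}
    for i in range(n_opp):
        recipient[f"opp{i}"], donor[f"opp{i}"] = 2, 0
    for i in range(n_het):
        recipient[f"het{i}"], donor[f"het{i}"] = 1, 0
    return {"recipient": recipient, "donor": donor}


class TestTargetedNoiselessOracle:
    @pytest.mark.parametrize("frac", [0.005, 0.01, 0.05, 0.10, 0.50])
    def test_exact_recovery_mixed_classes(self, frac):
        genotypes = _hand_profiles()
        counts = make_noiseless_counts(genotypes, frac, depth=4000)
        res = SNPChimerismModel(counts, genotypes=genotypes, config=NOISELESS).fit()
        assert res.fractions_pct["recipient"] == pytest.approx(100 * frac, abs=1e-9)
        assert res.fractions_pct["donor"] == pytest.approx(100 * (1 - frac), abs=1e-9)

    def test_exact_recovery_simulated_genotypes(self, sim_pair):
        counts = make_noiseless_counts(sim_pair, 0.05, depth=4000)
        res = SNPChimerismModel(counts, genotypes=sim_pair, config=NOISELESS).fit()
        assert res.fractions_pct["recipient"] == pytest.approx(5.0, abs=1e-9)

    def test_monotone_in_true_fraction(self):
        genotypes = _hand_profiles()
        estimates = []
        for frac in np.linspace(0, 1, 21):
            counts = make_noiseless_counts(genotypes, round(frac, 2), depth=4000)
            res = SNPChimerismModel(counts, genotypes=genotypes,
                                    config=NOISELESS).fit()
            estimates.append(res.fractions_pct["recipient"])
        assert all(b >= a - 1e-12 for a, b in zip(estimates, estimates[1:]))

    def test_fractions_sum_to_100(self):
        genotypes = _hand_profiles()
        counts = make_noiseless_counts(genotypes, 0.25, depth=4000)
        res = SNPChimerismModel(counts, genotypes=genotypes, config=NOISELESS).fit()
        assert sum(res.fractions_pct.values()) == pytest.approx(100.0, abs=0.01)


class TestTargetedNoisy:
    def test_pure_donor_censored_at_floor(self, sim_pair):
        counts = make_noiseless_counts(sim_pair, 0.0, depth=2000)
        res = SNPChimerismModel(counts, genotypes=sim_pair, config=NOISELESS).fit()
        assert res.censored
        assert res.recipient_pct == 0.36

    @pytest.mark.parametrize("true_pct", [0.5, 1.0, 5.0, 10.0, 50.0])
    def test_recovery_at_study_depth(self, sim_panel, true_pct):
        """At ~1871x over 202 loci the estimate lands within binomial bounds."""
        errs = []
        for seed in range(5):
            cfg = SimulationConfig(
                seed=seed,
                true_fractions={"recipient": true_pct, "donor": 100 - true_pct},
            )
            rng = cfg.rng()
            genotypes = simulate_genotypes(cfg, sim_panel, rng=rng)
            counts = simulate_mixture_counts(cfg, genotypes, rng=rng)
            res = SNPChimerismModel(counts, genotypes=genotypes).fit()
            errs.append(res.fractions_pct["recipient"] - true_pct)
        # binomial sd of a single locus at p=0.5, depth 1871 is ~1.2 pp;
        # medians over ~60-130 informative loci shrink that ~8-fold
        assert abs(np.mean(errs)) < 0.3
        assert max(abs(e) for e in errs) < 0.75

    def test_insufficient_markers_fails_qc(self):
        genotypes = {"recipient": {"rs1": 1, "rs2": 1}, "donor": {"rs1": 1, "rs2": 1}}
        counts = make_noiseless_counts(genotypes, 0.05, depth=2000)
        res = SNPChimerismModel(counts, genotypes=genotypes).fit()
        assert res.qc_status == "fail"
        assert any("insufficient" in r for r in res.qc_reasons)

    def test_low_coverage_warns(self, sim_pair):
        counts = make_noiseless_counts(sim_pair, 0.05, depth=40)
        res = SNPChimerismModel(counts, genotypes=sim_pair, config=NOISELESS).fit()
        assert res.qc_status == "warning"
        assert any("coverage" in r for r in res.qc_reasons)


class TestWrongDonor:
    def test_wrong_donor_grossly_inflates_recipient(self, sim_panel):
        """Targeting the wrong donor of a two-donor transplant misreads
        the other donor's alleles as recipient signal."""
        cfg = SimulationConfig(
            seed=21,
            true_fractions={"recipient": 0.1, "donor1": 0.1, "donor2": 99.8},
        )
        rng = cfg.rng()
        genotypes = simulate_genotypes(
            cfg, sim_panel, subjects=("recipient", "donor1", "donor2"), rng=rng
        )
        counts = simulate_mixture_counts(cfg, genotypes, rng=rng)
        wrong = SNPChimerismModel(
            counts,
            genotypes={"recipient": genotypes["recipient"],
                       "donor": genotypes["donor1"]},
        ).fit()
        right = SNPChimerismModel(
            counts,
            genotypes={"recipient": genotypes["recipient"],
                       "donor": genotypes["donor2"]},
        ).fit()
        # true recipient fraction is 0.1%: the correct donor recovers it
        # (censored below the LOQ), the wrong donor inflates it by orders
        # of magnitude
        assert right.censored
        assert wrong.fractions_pct["recipient"] > 100 * 0.1


class TestBlind:
    def test_recovers_ten_percent_within_one_point(self, sim_panel):
        cfg = SimulationConfig(
            seed=7, true_fractions={"recipient": 10.0, "donor": 90.0}
        )
        rng = cfg.rng()
        genotypes = simulate_genotypes(cfg, sim_panel, rng=rng)
        counts = simulate_mixture_counts(cfg, genotypes, rng=rng)
        res = SNPChimerismModel(counts, panel=sim_panel).fit()
        assert res.mode == "blind"
        assert res.fractions_pct["minor"] == pytest.approx(10.0, abs=1.0)

    def test_pure_donor_censored(self, sim_panel, sim_pair):
        cfg = SimulationConfig(
            seed=7, true_fractions={"recipient": 0.0, "donor": 100.0}
        )
        counts = simulate_mixture_counts(cfg, sim_pair, rng=np.random.default_rng(5))
        res = SNPChimerismModel(counts, panel=sim_panel).fit()
        assert res.censored
        assert res.recipient_pct == 0.36

    def test_symmetric_mixture_flags_ambiguity(self, sim_panel, sim_pair):
        cfg = SimulationConfig(
            seed=9, true_fractions={"recipient": 50.0, "donor": 50.0}
        )
        counts = simulate_mixture_counts(cfg, sim_pair, rng=np.random.default_rng(6))
        res = SNPChimerismModel(counts, panel=sim_panel).fit()
        assert res.fractions_pct["minor"] == pytest.approx(50.0, abs=2.0)
        assert any("ambiguous" in r for r in res.qc_reasons)


class TestSingleGenotypeModes:
    def test_recipient_targeted(self, sim_panel):
        cfg = SimulationConfig(
            seed=7, true_fractions={"recipient": 10.0, "donor": 90.0}
        )
        rng = cfg.rng()
        genotypes = simulate_genotypes(cfg, sim_panel, rng=rng)
        counts = simulate_mixture_counts(cfg, genotypes, rng=rng)
        res = SNPChimerismModel(
            counts, genotypes={"recipient": genotypes["recipient"]},
            panel=sim_panel,
        ).fit()
        assert res.mode == "recipient_targeted"
        assert res.recipient_pct == pytest.approx(10.0, abs=1.0)

    def test_donor_targeted(self, sim_panel):
        cfg = SimulationConfig(
            seed=7, true_fractions={"recipient": 10.0, "donor": 90.0}
        )
        rng = cfg.rng()
        genotypes = simulate_genotypes(cfg, sim_panel, rng=rng)
        counts = simulate_mixture_counts(cfg, genotypes, rng=rng)
        res = SNPChimerismModel(
            counts, genotypes={"donor": genotypes["donor"]}, panel=sim_panel
        ).fit()
        assert res.mode == "donor_targeted"
        assert res.recipient_pct == pytest.approx(10.0, abs=1.0)


class TestThreeContributors:
    def test_double_targeted_with_withheld_donor(self, sim_panel):
        cfg = SimulationConfig(
            seed=33,
            true_fractions={"recipient": 10.0, "donor1": 60.0, "donor2": 30.0},
        )
        rng = cfg.rng()
        genotypes = simulate_genotypes(
            cfg, sim_panel, subjects=("recipient", "donor1", "donor2"), rng=rng
        )
        counts = simulate_mixture_counts(cfg, genotypes, rng=rng)
        known = {k: genotypes[k] for k in ("recipient", "donor1")}
        res = SNPChimerismModel(counts, genotypes=known, n_contributors=3).fit()
        assert res.fractions_pct["recipient"] == pytest.approx(10.0, abs=1.5)
        assert res.fractions_pct["unknown"] == pytest.approx(30.0, abs=3.0)
        assert sum(res.fractions_pct.values()) == pytest.approx(100.0, abs=0.01)

    def test_all_three_known(self, sim_panel):
        cfg = SimulationConfig(
            seed=34,
            true_fractions={"recipient": 5.0, "donor1": 70.0, "donor2": 25.0},
        )
        rng = cfg.rng()
        genotypes = simulate_genotypes(
            cfg, sim_panel, subjects=("recipient", "donor1", "donor2"), rng=rng
        )
        counts = simulate_mixture_counts(cfg, genotypes, rng=rng)
        res = SNPChimerismModel(counts, genotypes=genotypes).fit()
        assert res.fractions_pct["recipient"] == pytest.approx(5.0, abs=1.0)
        assert res.fractions_pct["donor2"] == pytest.approx(25.0, abs=2.5)
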