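import numpy as np
import pytest

from conftest import certain_ppm, random_ppm
from oracles import brute_best_snp_score
from prescan.motif_dictionary import MotifDictionary, MotifRecord
from prescan.promoter_scan import ppm_to_pwm
from prescan.snp_effects import (
    SNPRecord,
    UnsupportedVariantError,
    classify_binding_change,
    filter_candidate_sites,
    group_effect_comparison,
    merge_panels,
    risk_allele_effect,
    score_panel,
    simulation_null,
    summarize_risk_effects,
)
from prescan.synthetic_data import generate_snp_panel, random_snp_sampler


def snp_of(flank, risk, nonrisk, snp_id="rs1", **kwargs):
    return SNPRecord(
        snp_id=snp_id, chrom="chr1", pos=100, risk_allele=risk,
        nonrisk_allele=nonrisk, flank=flank, **kwargs
    )


class TestRiskAlleleEffect:
    def test_identical_scores_zero_effect(self):
        pwm = ppm_to_pwm(certain_ppm("m", "ACGT"))
        # SNP far outside any good match; both alleles score identically badly
        snp = snp_of("CCCCCCCCACCCCCCCC", "A", "G")
        eff_a = risk_allele_effect(pwm, snp)
        swapped = snp_of("CCCCCCCCACCCCCCCC", "G", "A")
        eff_b = risk_allele_effect(pwm, swapped)
        assert eff_a.effect == pytest.approx(-eff_b.effect)

    def test_antisymmetry_under_allele_swap(self, rng):
        ppm = random_ppm(rng, width=6)
        pwm = ppm_to_pwm(ppm)
        flank = "".join(rng.choice(list("ACGT"), size=21))
        flank = flank[:10] + "A" + flank[11:]
        fwd = risk_allele_effect(pwm, snp_of(flank, "A", "C"))
        rev = risk_allele_effect(pwm, snp_of(flank, "C", "A"))
        assert fwd.effect == pytest.approx(-rev.effect)

    def test_disrupting_snp_negative_effect(self):
        pwm = ppm_to_pwm(certain_ppm("m", "GAAA", p=0.9))
        flank = "CCCCCCCGAAACCCCCCCC"[:19]
        # center (index 9) is the second A of the planted GAAA
        snp = snp_of(flank, "T", flank[9])
        eff = risk_allele_effect(pwm, snp)
        assert eff.effect < 0
        assert eff.psi_r == pytest.approx(
            brute_best_snp_score(pwm.weights, flank, 9, "T")
        )
        assert eff.psi_nr == pytest.approx(
            brute_best_snp_score(pwm.weights, flank, 9, flank[9])
        )

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            ppm = random_ppm(rng, width=int(rng.integers(4, 9)))
            pwm = ppm_to_pwm(ppm)
            if pwm.is_degenerate:
                continue
            flank = "".join(rng.choice(list("ACGT"), size=25))
            center = 12
            alleles = rng.choice(list("ACGT"), size=2, replace=False)
            flank = flank[:center] + alleles[0] + flank[center + 1 :]
            snp = snp_of(flank, alleles[0], alleles[1])
            eff = risk_allele_effect(pwm, snp)
            assert eff.psi_r == pytest.approx(
                brute_best_snp_score(pwm.weights, flank, center, alleles[0])
            )
            assert eff.psi_nr == pytest.approx(
                brute_best_snp_score(pwm.weights, flank, center, alleles[1])
            )

    def test_short_flank_rejected(self):
        pwm = ppm_to_pwm(certain_ppm("m", "ACGTACGTAC"))
        with pytest.raises(ValueError, match="flank"):
            risk_allele_effect(pwm, snp_of("CCACC", "A", "G"))

    def test_indel_rejected(self):
        with pytest.raises(UnsupportedVariantError):
            snp_of("CCACC", "AT", "A")


class TestClassify:
    @pytest.mark.parametrize(
        "r, nr, expected",
        [
            (0.90, 0.70, "engendered"),
            (0.70, 0.90, "disrupted"),
            (0.82, 0.78, "none"),
            (0.86, 0.76, "none"),  # psi_nr not below 0.75
            (0.85, 0.70, "none"),  # boundary is strict
        ],
    )
    def test_threshold_rules(self, r, nr, expected):
        assert classify_binding_change(r * 10, nr * 10, 10.0) == expected

    def test_nonpositive_psi_max_rejected(self):
        with pytest.raises(ValueError):
            classify_binding_change(1.0, 0.5, 0.0)


class TestSummary:
    def _effects(self, n_eng, n_dis, n_none):
        from prescan.snp_effects import RiskAlleleEffect

        out = []
        for i in range(n_eng):
            out.append(RiskAlleleEffect(f"e{i}", "m", psi_r=9.0, psi_nr=7.0, psi_max=10.0))
        for i in range(n_dis):
            out.append(RiskAlleleEffect(f"d{i}", "m", psi_r=7.0, psi_nr=9.0, psi_max=10.0))
        for i in range(n_none):
            out.append(RiskAlleleEffect(f"n{i}", "m", psi_r=8.0, psi_nr=8.0, psi_max=10.0))
        return out

    def test_counts_partition(self):
        summary = summarize_risk_effects(self._effects(3, 5, 12))
        assert summary.n_combinations == 20
        assert summary.n_engendered == 3
        assert summary.n_disrupted == 5

    def test_ratio_and_percentage_arithmetic(self):
        summary = summarize_risk_effects(self._effects(73, 130, 24433 - 203))
        assert summary.n_combinations == 24433
        assert round(summary.pct_changed, 2) == 0.83
        assert summary.disrupted_engendered_ratio == pytest.approx(130 / 73)

    def test_zero_engendered_ratio_undefined(self):
        summary = summarize_risk_effects(self._effects(0, 4, 6))
        assert summary.disrupted_engendered_ratio is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_risk_effects([])


class TestGroupComparison:
    def _effects_with_shift(self, rng, shift, n_pre=50, n_other=200, n_snps=20):
        from prescan.snp_effects import RiskAlleleEffect

        effects = []
        for i in range(n_pre + n_other):
            motif = f"m{i:03d}"
            mu = shift if i < n_pre else 0.0
            for j in range(n_snps):
                e = rng.normal(mu, 0.02)
                effects.append(
                    RiskAlleleEffect(f"s{j}", motif, psi_r=5 + 10 * e, psi_nr=5.0, psi_max=10.0)
                )
        pre = {f"m{i:03d}" for i in range(n_pre)}
        other = {f"m{i:03d}" for i in range(n_pre, n_pre + n_other)}
        return effects, pre, other

    def test_shifted_group_detected(self, rng):
        effects, pre, other = self._effects_with_shift(rng, -0.05)
        med_pre, med_other, p = group_effect_comparison(effects, pre, other)
        assert med_pre < med_other
        assert p < 0.01

    def test_null_p_not_small(self, rng):
        # full uniformity check is in test_acceptance
        effects, pre, other = self._effects_with_shift(rng, 0.0)
        _, _, p = group_effect_comparison(effects, pre, other)
        assert p > 0.001

    def test_small_group_rejected(self, rng):
        effects, pre, other = self._effects_with_shift(rng, 0.0, n_pre=1)
        with pytest.raises(ValueError):
            group_effect_comparison(effects, pre, other)


class TestPlantedPanels:
    def test_disrupt_snps_classified(self):
        from prescan.synthetic_data import generate_motifs

        motifs, _ = generate_motifs(
            6, n_families=2, width_range=(8, 10),
            ic_per_column_range=(1.3, 1.8), seed=4,
        )
        snps, truth = generate_snp_panel(
            60, motifs, fractions=(1.0, 0.0, 0.0), seed=5
        )
        dictionary = MotifDictionary(motifs)
        correct = 0
        for snp in snps:
            motif_id, intent = truth.snp_intent[snp.snp_id]
            rec = dictionary.get(motif_id)
            eff = risk_allele_effect(ppm_to_pwm(rec.ppm), snp)
            correct += eff.change == "disrupted"
        assert correct / len(snps) >= 0.95

    def test_neutral_panel_mostly_unchanged(self):
        from prescan.synthetic_data import generate_motifs

        motifs, _ = generate_motifs(
            5, n_families=1, width_range=(8, 10),
            ic_per_column_range=(1.3, 1.8), seed=6,
        )
        snps, _ = generate_snp_panel(40, motifs, fractions=(0.0, 0.0, 1.0), seed=7)
        summary = summarize_risk_effects(score_panel(MotifDictionary(motifs), snps))
        assert summary.pct_changed <= 2.0


class TestSimulationNull:
    def _setup(self, seed=0):
        from prescan.synthetic_data import generate_motifs

        motifs, _ = generate_motifs(
            4, n_families=1, width_range=(6, 8),
            ic_per_column_range=(1.2, 1.6), seed=seed,
        )
        return MotifDictionary(motifs), random_snp_sampler(motifs)

    def test_deterministic_given_seed(self):
        dictionary, sampler = self._setup()
        snps = sampler(np.random.default_rng(1), 10)
        observed = summarize_risk_effects(score_panel(dictionary, snps))
        p1 = simulation_null(sampler, dictionary, observed, n_trials=100, seed=3)
        p2 = simulation_null(sampler, dictionary, observed, n_trials=100, seed=3)
        assert p1 == p2

    def test_extreme_observation_hits_floor(self):
        dictionary, sampler = self._setup()
        from prescan.snp_effects import RiskEffectSummary

        observed = RiskEffectSummary(
            n_combinations=10 * len(dictionary), n_engendered=0,
            n_disrupted=10 * len(dictionary),
        )
        out = simulation_null(sampler, dictionary, observed, n_trials=100, seed=3)
        assert out["p_pct_changed"] == pytest.approx(1 / 101)

    def test_low_trial_warning(self, caplog):
        dictionary, sampler = self._setup()
        snps = sampler(np.random.default_rng(1), 5)
        observed = summarize_risk_effects(score_panel(dictionary, snps))
        with caplog.at_level("WARNING"):
            simulation_null(sampler, dictionary, observed, n_trials=20, seed=3)
        assert any("n_trials" in rec.message for rec in caplog.records)


class TestPanelPlumbing:
    def test_merge_panels_deduplicates(self):
        a = [snp_of("CCACC", "A", "C", snp_id="rs1")]
        b = [snp_of("CCACC", "A", "C", snp_id="rs1"),
             snp_of("CCACC", "A", "C", snp_id="rs2")]
        merged = merge_panels(a, b)
        assert [s.snp_id for s in merged] == ["rs1", "rs2"]

    def test_filter_candidates_or_rule(self):
        from prescan.snp_effects import RiskAlleleEffect

        effects = [
            RiskAlleleEffect("conserved", "m1", psi_r=7.0, psi_nr=9.0, psi_max=10.0),
            RiskAlleleEffect("deglinked", "m2", psi_r=9.0, psi_nr=7.0, psi_max=10.0),
            RiskAlleleEffect("neither", "m3", psi_r=7.0, psi_nr=9.0, psi_max=10.0),
            RiskAlleleEffect("nochange", "m1", psi_r=8.0, psi_nr=8.0, psi_max=10.0),
        ]
        snps = {
            "conserved": snp_of("CCACC", "A", "C", snp_id="conserved", phastcons=0.9),
            "deglinked": snp_of("CCACC", "A", "C", snp_id="deglinked", phastcons=0.1),
            "neither": snp_of("CCACC", "A", "C", snp_id="neither", phastcons=0.1),
            "nochange": snp_of("CCACC", "A", "C", snp_id="nochange", phastcons=0.9),
        }
        table = filter_candidate_sites(effects, snps, deg_encoded_motifs={"m2"})
        assert set(table["snp_id"]) == {"conserved", "deglinked"}

    def test_roundtrip_snp_tsv(self, tmp_path):
        from prescan.snp_effects import load_snp_panel
        from prescan.synthetic_data import generate_motifs, write_snp_panel

        motifs, _ = generate_motifs(3, n_families=1, seed=9)
        snps, _ = generate_snp_panel(8, motifs, seed=9)
        path = tmp_path / "snps.tsv"
        write_snp_panel(snps, path)
        loaded = load_snp_panel(path)
        assert len(loaded) == 8
        assert loaded[0].flank == snps[0].flank
        assert loaded[0].risk_allele == snps[0].risk_allele
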