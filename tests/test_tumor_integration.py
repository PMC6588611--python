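import itertools

import pytest

from germscreen.models import (
    ACMGClass,
    ClassifiedVariant,
    Consequence,
    HitCategory,
    PairPhase,
    Phase,
    SomaticVariant,
    TumorObservation,
)
from germscreen.tumor_integration import (
    analyze_tumor,
    call_loh,
    check_blood_heterozygosity,
    detect_reversion,
    detect_second_hit,
    loh_fraction,
)

from conftest import make_call


def obs(vaf=None, hits=(), pid="P1", gene="BRCA2", hgvs="c.100G>A"):
    return TumorObservation(patient_id=pid, gene=gene, hgvs_c=hgvs,
                            tumor_vaf=vaf, somatic_hits=list(hits))


def germline_fs(net=-2, gene="BRCA2", hgvs="c.7069_7070del"):
    return ClassifiedVariant(
        make_call(gene=gene, hgvs_c=hgvs, consequence=Consequence.FRAMESHIFT,
                  indel_net_length=net),
        ACMGClass.PATHOGENIC)


class TestHeterozygosity:
    @pytest.mark.parametrize("vaf,expected", [
        (0.50, True), (0.65, False), (0.64999, True), (0.0, True), (1.0, False),
    ])
    def test_strict_bound(self, vaf, expected):
        assert check_blood_heterozygosity(vaf) is expected


class TestLoh:
    @pytest.mark.parametrize("vaf,expected", [
        (0.64, False), (0.65, False), (0.66, True), (0.87, True),
    ])
    def test_cutoff(self, vaf, expected):
        assert call_loh(obs(vaf=vaf)) is expected

    def test_missing_tumor_is_none_not_false(self):
        assert call_loh(obs(vaf=None)) is None

    def test_monotone_in_vaf(self):
        grid = [i / 200 for i in range(201)]
        calls = [call_loh(obs(vaf=v)) for v in grid]
        assert calls == sorted(calls)  # False..False True..True


class TestReversion:
    def test_printed_pair_cis_restores_frame(self):
        germ = germline_fs(net=-2)
        som = SomaticVariant(gene="BRCA2", hgvs_c="c.7065del",
                             consequence=Consequence.FRAMESHIFT,
                             indel_net_length=-1,
                             phase_vs_germline=Phase.CIS)
        assert detect_reversion(germ.variant, som) is True

    def test_trans_is_not_reversion(self):
        germ = germline_fs(net=-2)
        som = SomaticVariant(gene="BRCA2", indel_net_length=-1,
                             consequence=Consequence.FRAMESHIFT,
                             phase_vs_germline=Phase.TRANS)
        assert detect_reversion(germ.variant, som) is False

    def test_unknown_phase_conservative(self):
        germ = germline_fs(net=-2)
        som = SomaticVariant(gene="BRCA2", indel_net_length=-1,
                             consequence=Consequence.FRAMESHIFT,
                             phase_vs_germline=Phase.UNKNOWN)
        assert detect_reversion(germ.variant, som) is False

    def test_exhaustive_net_length_pairs(self):
        # oracle: (g + s) % 3 == 0 and CIS
        for g, s in itertools.product(range(-6, 7), repeat=2):
            if g % 3 == 0:
                continue  # not a frameshift-consistent germline length
            germ = germline_fs(net=g)
            for phase in (Phase.CIS, Phase.TRANS):
                som = SomaticVariant(gene="BRCA2", indel_net_length=s,
                                     consequence=Consequence.FRAMESHIFT,
                                     phase_vs_germline=phase)
                expected = (g + s) % 3 == 0 and phase is Phase.CIS
                assert detect_reversion(germ.variant, som) is expected

    def test_symmetric_in_labels_given_cis(self):
        for g, s in itertools.product(range(-6, 7), repeat=2):
            if g % 3 == 0 or s % 3 == 0:
                continue
            a = detect_reversion(
                germline_fs(net=g).variant,
                SomaticVariant(gene="BRCA2", indel_net_length=s,
                               phase_vs_germline=Phase.CIS))
            b = detect_reversion(
                germline_fs(net=s).variant,
                SomaticVariant(gene="BRCA2", indel_net_length=g,
                               phase_vs_germline=Phase.CIS))
            assert a == b


class TestSecondHit:
    def test_reversion_takes_precedence(self):
        germ = germline_fs(net=-2)
        som = SomaticVariant(gene="BRCA2", hgvs_c="c.7065del",
                             consequence=Consequence.FRAMESHIFT,
                             indel_net_length=-1,
                             phase_vs_germline=Phase.CIS)
        r = detect_second_hit(germ, obs(vaf=0.5, hits=[som]))
        assert r.category is HitCategory.REVERSION

    def test_biallelic_somatic_splice_pair(self):
        germ = germline_fs(net=-2)
        s1 = SomaticVariant(gene="BRCA2", hgvs_c="c.517-1G>A",
                            consequence=Consequence.SPLICE_SITE,
                            splice_offset=-1,
                            phase_vs_germline=Phase.UNKNOWN,
                            pair_phase=PairPhase.OPPOSITE_ALLELES)
        s2 = SomaticVariant(gene="BRCA2", hgvs_c="c.631+3A>G",
                            consequence=Consequence.SPLICE_SITE,
                            splice_offset=3,
                            phase_vs_germline=Phase.UNKNOWN,
                            pair_phase=PairPhase.OPPOSITE_ALLELES)
        r = detect_second_hit(germ, obs(vaf=0.5, hits=[s1, s2]))
        assert r.category is HitCategory.SOMATIC_SECOND_HIT
        assert r.biallelic_somatic is True

    def test_loh_when_no_somatic(self):
        r = detect_second_hit(germline_fs(), obs(vaf=0.8))
        assert r.category is HitCategory.LOH
        assert r.loh is True

    def test_none_when_quiet(self):
        r = detect_second_hit(germline_fs(), obs(vaf=0.5))
        assert r.category is HitCategory.NONE

    def test_no_tumor_reason(self):
        r = detect_second_hit(germline_fs(), obs(vaf=None))
        assert r.category is HitCategory.NONE
        assert r.loh is None
        assert r.evidence.get("reason") == "no_tumor"

    def test_cis_nonrestoring_not_a_second_hit(self):
        # cis somatic that does not restore frame: neither reversion nor
        # trans/unknown hit
        som = SomaticVariant(gene="BRCA2", indel_net_length=-3,
                            consequence=Consequence.FRAMESHIFT,
                            phase_vs_germline=Phase.CIS)
        r = detect_second_hit(germline_fs(net=-2), obs(vaf=0.5, hits=[som]))
        assert r.category is HitCategory.NONE

    def test_deterministic(self):
        germ = germline_fs()
        o = obs(vaf=0.7, hits=[SomaticVariant(
            gene="BRCA2", consequence=Consequence.NONSENSE,
            phase_vs_germline=Phase.UNKNOWN)])
        assert detect_second_hit(germ, o) == detect_second_hit(germ, o)


class TestLohFraction:
    def _results(self, loh_flags, gene="BRCA2"):
        return [detect_second_hit(
            germline_fs(gene=gene, hgvs=f"c.{i}del"),
            obs(vaf=0.9 if flag else 0.5, gene=gene, hgvs=f"c.{i}del"))
            for i, flag in enumerate(loh_flags)]

    def test_arithmetic(self):
        results = self._results([True] * 19 + [False] * 81)
        assert loh_fraction(results) == pytest.approx(0.19)

    def test_empty_not_available(self):
        assert loh_fraction([]) is None

    def test_missing_tumor_excluded_from_denominator(self):
        results = self._results([True])
        results.append(detect_second_hit(germline_fs(hgvs="c.9del"),
                                         obs(vaf=None, hgvs="c.9del")))
        assert loh_fraction(results) == pytest.approx(1.0)

    def test_hr_subset(self, panel):
        hr = self._results([True, False], gene="BRCA2")
        fanconi = self._results([True, True], gene="FANCM")
        other = self._results([False, False], gene="TP53")
        assert loh_fraction(hr + fanconi + other, panel=panel,
                            hr_supergroup=True) == pytest.approx(3 / 4)

    def test_planted_fraction_recovered(self, panel):
        from germscreen.synthetic_cohort import SimulationConfig, simulate_cohort

        config = SimulationConfig(n_patients=2000, seed=3, loh_fraction=0.27,
                                  tumor_purity_range=(1.0, 1.0),
                                  second_hit_fraction=0.0,
                                  reversion_fraction=0.0)
        _, calls, tumor, truth = simulate_cohort(config)
        classified = [germline_fs(gene=r.gene, hgvs=r.hgvs_c)
                      for r in truth.pathogenic]
        for cv, r in zip(classified, truth.pathogenic):
            cv.variant.patient_id = r.patient_id
        results = analyze_tumor(classified, tumor)
        est = loh_fraction(results)
        n = len(truth.pathogenic)
        se = (0.27 * 0.73 / n) ** 0.5
        assert abs(est - 0.27) <= 3 * se


class TestPuritySweep:
    def test_loh_sensitivity_monotone_in_purity(self):
        from germscreen.synthetic_cohort import (
            SimulationConfig,
            simulate_cohort,
            simulate_tumor_vafs,
        )

        config = SimulationConfig(n_patients=1500, seed=5, loh_fraction=1.0,
                                  second_hit_fraction=0.0,
                                  reversion_fraction=0.0)
        _, _, _, truth = simulate_cohort(config)
        sensitivities = []
        for purity in (0.2, 0.4, 0.6, 0.8, 1.0):
            tumor = simulate_tumor_vafs(truth, purity, depth=200, seed=42)
            hits = sum(1 for o in tumor if o.tumor_vaf > 0.65)
            sensitivities.append(hits / len(tumor))
        assert sensitivities == sorted(sensitivities)
        assert sensitivities[0] < 0.5  # dilution masks LOH at low purity
        assert sensitivities[-1] > 0.99
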