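"""Scenario calculus: C-value profiles, classification, gamete back-calculation."""

from fractions import Fraction

import pytest

from seedscreen import scenarios as sc


def spec(**kw) -> sc.ScenarioSpec:
    return sc.ScenarioSpec(**kw)


class TestExpectedCValues:
    # profiles the seed-screen literature treats as canonical, frozen exactly
    @pytest.mark.parametrize(
        "kw, embryo, endosperm",
        [
            # sexual diploid double fertilization: 2C embryo, 3C endosperm
            (dict(), 2, 3),
            # diploid apomict, autonomous endosperm
            (dict(egg_reduced=False, embryo_fertilized=False, polar_reduced=False,
                  endosperm_sperms=0), 2, 4),
            # pseudogamy, one reduced sperm
            (dict(egg_reduced=False, embryo_fertilized=False, polar_reduced=False,
                  endosperm_sperms=1), 2, 5),
            # pseudogamy, one unreduced sperm
            (dict(egg_reduced=False, embryo_fertilized=False, polar_reduced=False,
                  endosperm_sperms=1, sperm_reduced=False), 2, 6),
            # pseudogamy, two reduced sperms (same 2/6 profile)
            (dict(egg_reduced=False, embryo_fertilized=False, polar_reduced=False,
                  endosperm_sperms=2), 2, 6),
            # tri-nucleate central cell, one reduced sperm
            (dict(egg_reduced=False, embryo_fertilized=False, polar_reduced=False,
                  polar_nuclei=3, endosperm_sperms=1), 2, 7),
            # tri-nucleate, one unreduced sperm
            (dict(egg_reduced=False, embryo_fertilized=False, polar_reduced=False,
                  polar_nuclei=3, endosperm_sperms=1, sperm_reduced=False), 2, 8),
            # tri-nucleate, two unreduced sperms
            (dict(egg_reduced=False, embryo_fertilized=False, polar_reduced=False,
                  polar_nuclei=3, endosperm_sperms=2, sperm_reduced=False), 2, 10),
            # BIII hybrid: unreduced egg fertilized by an unreduced 2x sperm
            (dict(egg_reduced=False, embryo_fertilized=True, polar_reduced=False,
                  endosperm_sperms=1, sperm_reduced=False), 4, 6),
            # triploid mother, unreduced parthenogenetic egg, reduced 1x sperm
            (dict(maternal_ploidy=3, egg_reduced=False, embryo_fertilized=False,
                  polar_reduced=False, endosperm_sperms=1), 3, 7),
        ],
        ids=["sexual-2/3", "autonomous-2/4", "pseudogamy-2/5", "pseudogamy-2/6",
             "two-sperm-2/6", "trinucleate-2/7", "trinucleate-2/8",
             "trinucleate-2/10", "BIII-4/6", "triploid-3/7"],
    )
    def test_printed_profiles(self, kw, embryo, endosperm):
        prof = sc.expected_c_values(spec(**kw))
        assert prof.embryo_c == Fraction(embryo)
        assert prof.endosperm_c == Fraction(endosperm)
        assert prof.quotient == Fraction(endosperm, embryo)

    def test_sexual_quotient_is_three_halves_for_matched_ploidies(self):
        for m in (2, 4, 6, 8):
            s = spec(maternal_ploidy=m, pollen_ploidy=m)
            assert s.quotient == Fraction(3, 2)

    def test_reduced_gametes_of_odd_ploidy_stay_exact_rationals(self):
        s = spec(maternal_ploidy=3, pollen_ploidy=3)
        assert s.embryo_c == Fraction(3)
        assert s.endosperm_c == Fraction(9, 2)
        assert s.label == "3/4.5"

    def test_invalid_configurations_rejected(self):
        with pytest.raises(sc.ScenarioError):
            spec(polar_nuclei=4)
        with pytest.raises(sc.ScenarioError):
            spec(endosperm_sperms=3)
        with pytest.raises(sc.ScenarioError):
            spec(maternal_ploidy=0)
        with pytest.raises(sc.ScenarioError):
            spec(endosperm_sperms=0)  # fertilized embryo, autonomous endosperm


class TestParseLabel:
    def test_accepts_both_orders(self):
        assert sc.parse_label("2/5") == sc.parse_label("5/2") == (Fraction(2), Fraction(5))

    @pytest.mark.parametrize("bad", ["", "2", "2/0", "a/b", "1/2/3"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(sc.ScenarioError):
            sc.parse_label(bad)


class TestEnumerate:
    def test_default_diploid_profiles(self, diploid_default):
        labels = {s.label for s in diploid_default}
        assert labels == {"2/3", "2/4", "2/5", "2/6", "2/8"}
        quotients = sorted(float(s.quotient) for s in diploid_default)
        assert quotients == [1.5, 2.0, 2.5, 3.0, 4.0]

    def test_two_six_variants_merged_but_preserved(self, diploid_default):
        (s26,) = [s for s in diploid_default
                  if s.label == "2/6" and s.mode == sc.MODE_PSEUDOGAMOUS]
        assert len(s26.equivalents) == 1  # one unreduced sperm <-> two reduced

    def test_extended_set_adds_trinucleate_and_biii(self, diploid_extended):
        labels = {s.label for s in diploid_extended}
        assert {"2/7", "2/8", "2/10", "4/6"} <= labels
        modes = {s.label: s.mode for s in diploid_extended}
        assert modes["4/6"] == sc.MODE_BIII

    def test_deduplication_is_by_profile_and_mode(self, diploid_extended):
        keys = [(s.embryo_c, s.endosperm_c, s.mode) for s in diploid_extended]
        assert len(keys) == len(set(keys))

    def test_haploid_maternal_guarded(self):
        with pytest.raises(sc.ScenarioError):
            sc.enumerate_scenarios(1, (2,))
        assert sc.enumerate_scenarios(1, (2,), allow_haploid_maternal=True)

    def test_empty_pollen_rejected(self):
        with pytest.raises(sc.ScenarioError):
            sc.enumerate_scenarios(2, ())


class TestClassify:
    def test_aberrant_quotient_near_two_sevenths(self, diploid_extended):
        """A 3.32 quotient sits nearest the tri-nucleate 2/7 profile (3.5)."""
        call = sc.classify_quotient(3.32, diploid_extended)
        assert call.label == "2/7"
        assert call.mode == sc.MODE_PSEUDOGAMOUS
        assert call.deviation == pytest.approx(abs(3.32 - 3.5) / 3.5)

    def test_sexual_quotient_exact(self, diploid_default):
        call = sc.classify_quotient(1.5, diploid_default)
        assert call.mode == sc.MODE_SEXUAL and call.deviation == 0.0

    def test_far_quotient_unresolved(self, diploid_default):
        call = sc.classify_quotient(10.0, diploid_default)
        assert call.mode == sc.MODE_UNRESOLVED and not call.matched

    def test_two_six_tie_preserved(self, diploid_extended):
        call = sc.classify_quotient(3.0, diploid_extended)
        pseud = [s for s in call.matched if s.mode == sc.MODE_PSEUDOGAMOUS]
        sperms = {(s.endosperm_sperms, s.sperm_reduced) for s in pseud}
        assert {(1, False), (2, True)} <= sperms  # one unreduced or two reduced

    def test_self_consistency_over_enumeration(self, diploid_extended):
        """Classifying a scenario's own quotient must recover it (or a tie)."""
        for s in diploid_extended:
            call = sc.classify_quotient(float(s.quotient), diploid_extended)
            assert call.deviation == 0.0
            assert any(
                m.embryo_c == s.embryo_c and m.endosperm_c == s.endosperm_c
                for m in call.matched
            )

    def test_invalid_inputs(self, diploid_default):
        with pytest.raises(ValueError):
            sc.classify_quotient(-1.0, diploid_default)
        with pytest.raises(ValueError):
            sc.classify_quotient(1.5, [])


class TestGameteBackcalc:
    def test_pseudogamy_reduced_sperm(self, diploid_default):
        sols = sc.gamete_backcalc(2.0, 5.0, diploid_default)
        best = sols[0]
        assert best.scenario.label == "2/5"
        assert best.implied_sperm_gs == pytest.approx(1.0)  # = embryo/2
        assert best.consistency == "reduced_consistent"

    def test_two_six_alternates(self, diploid_default):
        sols = sc.gamete_backcalc(2.0, 6.0, diploid_default)
        consistent = [s for s in sols if s.consistent and s.deviation < 1e-9]
        kinds = {(s.scenario.endosperm_sperms, s.consistency) for s in consistent}
        assert (1, "unreduced_consistent") in kinds  # one 2.0 pg sperm
        assert (2, "reduced_consistent") in kinds  # two 1.0 pg sperms
        assert all(s.alternate_labels for s in consistent)

    def test_sexual_identity(self, diploid_default):
        sols = sc.gamete_backcalc(2.0, 3.0, diploid_default)
        best = sols[0]
        assert best.scenario.mode == sc.MODE_SEXUAL
        assert best.implied_polar_sum_gs == pytest.approx(2.0)
        assert best.implied_sperm_gs == pytest.approx(1.0)
        assert best.consistency == "reduced_consistent"

    def test_roundtrip_over_all_default_scenarios(self, diploid_extended):
        """expected C-values -> genome sizes -> back-calc recovers the scenario."""
        for s in diploid_extended:
            g1 = 1.7  # pg per monoploid genome
            sols = sc.gamete_backcalc(
                g1 * float(s.embryo_c), g1 * float(s.endosperm_c), [s]
            )
            assert sols[0].consistent
            assert sols[0].deviation < 1e-9

    def test_impossible_geometry_flagged(self, diploid_default):
        sexual = [s for s in diploid_default if s.mode == sc.MODE_SEXUAL]
        sols = sc.gamete_backcalc(2.0, 1.0, sexual)  # endosperm below polar sum
        assert all(not s.consistent for s in sols)


class TestAggregate:
    def _call(self, mode):
        return sc.ModeCall(1.5, (), mode, 0.0, 0.08)

    def test_facultative_apomict(self):
        calls = [self._call(sc.MODE_SEXUAL)] * 20 + [self._call(sc.MODE_PSEUDOGAMOUS)] * 2
        s = sc.aggregate_species("festuca_like", calls)
        assert s.mode == "facultative_apomict"
        assert s.n_apomictic == 2 and s.n_sexual == 20

    def test_all_no_endosperm_excluded(self):
        s = sc.aggregate_species("x", [self._call(sc.MODE_NO_ENDOSPERM)] * 5)
        assert s.mode == sc.MODE_NO_ENDOSPERM

    def test_all_sexual(self):
        s = sc.aggregate_species("x", [self._call(sc.MODE_SEXUAL)] * 5)
        assert s.mode == sc.MODE_SEXUAL

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sc.aggregate_species("x", [])
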