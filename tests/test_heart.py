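"""Heart-model tests: macro formulas, pacemaker hierarchy, Frank–Starling,
circulation delay lines, the epinephrine transport scenario, electrolyte and
K_ATP rules, conduction timing and remodeling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biocomp import heart as ht
from biocomp.rules import check_conditional_branching, check_well_defined, \
    rule_to_relation


class TestMacroFormulas:
    def test_resting_interval_rounds_to_seventy_bpm(self):
        # 860 ms inter-stroke interval at rest
        assert ht.heart_rate_from_times(0.0, 0.860) == pytest.approx(69.77, abs=0.01)
        assert round(ht.heart_rate_from_times(0.0, 0.860)) == 70

    def test_one_second_interval_is_sixty_bpm(self):
        assert ht.heart_rate_from_times(0.0, 1.0) == 60.0

    @given(st.floats(min_value=0.2, max_value=3.0))
    @settings(deadline=None, derandomize=True)
    def test_rate_interval_round_trip(self, interval):
        bpm = ht.heart_rate_from_times(0.0, interval)
        assert 60.0 / bpm == pytest.approx(interval, rel=1e-12)

    def test_bad_stroke_ordering_rejected(self):
        with pytest.raises(ValueError, match="ordering"):
            ht.heart_rate_from_times(1.0, 1.0)

    def test_typical_volumes_give_half_ejection_fraction(self):
        assert ht.ejection_fraction(70.0, 140.0) == 0.5

    def test_full_ejection_is_unity(self):
        assert ht.ejection_fraction(55.0, 55.0) == 1.0

    def test_ejection_fraction_matches_division(self, rng):
        for _ in range(100):
            edv = float(rng.uniform(50, 250))
            sv = float(rng.uniform(1, edv))
            assert ht.ejection_fraction(sv, edv) == sv / edv

    def test_impossible_ejection_rejected(self):
        with pytest.raises(ValueError, match="impossible"):
            ht.ejection_fraction(150.0, 140.0)


class TestPacemakerHierarchy:
    def test_intrinsic_sa_rate_is_100(self):
        rate = ht.effective_heart_rate(ht.default_nodes(), ht.HeartInternalState())
        assert rate == 100.0

    def test_sa_failure_falls_into_av_band(self):
        rate = ht.effective_heart_rate(ht.default_nodes(sa=False),
                                       ht.HeartInternalState())
        assert 40.0 <= rate <= 60.0

    def test_double_failure_falls_into_purkinje_band(self):
        rate = ht.effective_heart_rate(ht.default_nodes(sa=False, av=False),
                                       ht.HeartInternalState())
        assert 20.0 <= rate <= 40.0

    def test_excited_purkinje_escape_is_140(self):
        rate = ht.effective_heart_rate(
            ht.default_nodes(sa=False, av=False, excited=True),
            ht.HeartInternalState())
        assert rate == pytest.approx(140.0)

    def test_takeover_is_strictly_tiered(self):
        state = ht.HeartInternalState()
        sa = ht.effective_heart_rate(ht.default_nodes(), state)
        av = ht.effective_heart_rate(ht.default_nodes(sa=False), state)
        pk = ht.effective_heart_rate(ht.default_nodes(sa=False, av=False), state)
        assert sa > av > pk > 0

    def test_no_functional_node_is_asystole(self):
        with pytest.raises(ht.AsystoleError):
            ht.effective_heart_rate(
                ht.default_nodes(sa=False, av=False, purkinje=False),
                ht.HeartInternalState())

    def test_autonomic_balance_spans_70_to_100(self):
        resting = ht.effective_heart_rate(
            ht.default_nodes(), ht.HeartInternalState(pns_tone=1.0))
        assert resting == pytest.approx(70.0)
        sympathetic = ht.effective_heart_rate(
            ht.default_nodes(), ht.HeartInternalState(sns_tone=1.0))
        assert sympathetic > 100.0


class TestFrankStarling:
    def test_healthy_curve_is_nondecreasing_everywhere(self):
        curve = ht.FrankStarlingCurve()
        edvs = np.linspace(*curve.domain, 200)
        svs = [curve(e) for e in edvs]
        assert all(b >= a for a, b in zip(svs, svs[1:]))

    def test_baseline_anchor_is_70_at_140(self):
        assert ht.FrankStarlingCurve()(140.0) == 70.0

    def test_sympathetic_shift_raises_pointwise(self):
        base = ht.FrankStarlingCurve()
        shifted = ht.FrankStarlingCurve(sympathetic_shift=0.2)
        for edv in np.linspace(20, 220, 30):
            assert shifted(edv) >= base(edv)

    def test_failing_curve_decreases_at_large_filling(self):
        failing = ht.FrankStarlingCurve(failing=True)
        assert failing(220.0) < failing(140.0)

    def test_stroke_volume_monotone_in_edv(self):
        curve, state = ht.FrankStarlingCurve(), ht.HeartInternalState()
        sv1 = ht.stroke_volume(100.0, curve, state)
        sv2 = ht.stroke_volume(140.0, curve, state)
        assert sv2 >= sv1

    def test_empty_ventricle_ejects_nothing(self):
        assert ht.stroke_volume(0.0, ht.FrankStarlingCurve(),
                                ht.HeartInternalState()) == 0.0

    def test_stroke_volume_never_exceeds_edv(self):
        state = ht.HeartInternalState(sns_tone=3.0, norepinephrine=3.0,
                                      epi_receptor_occupancy=1.0)
        curve = ht.FrankStarlingCurve(sympathetic_shift=1.0)
        for edv in (20.0, 70.0, 140.0, 220.0):
            assert ht.stroke_volume(edv, curve, state) <= edv

    def test_out_of_domain_edv_rejected(self):
        with pytest.raises(ht.CurveDomainError):
            ht.FrankStarlingCurve()(500.0)


class TestCirculation:
    def test_mass_conserved_over_thousand_strokes(self):
        circ = ht.Circulation()
        state = ht.HeartInternalState(pns_tone=1.0)
        curve, nodes = ht.FrankStarlingCurve(), ht.default_nodes()
        t = 0.0
        _, t = ht.advance_stroke(circ, state, curve, nodes, t_prev=t,
                                 injection={"epinephrine": 9800.0})
        total0 = circ.total_mass("epinephrine")
        for i in range(1, 1000):
            _, t = ht.advance_stroke(circ, state, curve, nodes,
                                     t_prev=t, index=i)
        assert circ.total_mass("epinephrine") == pytest.approx(total0, abs=1e-9)

    def test_pure_delay_line_arrival_times(self):
        """With every rule disabled the loop is a pure delay line: mass
        injected at stroke 0 shows up in the right heart at stroke 10 and
        the left heart at stroke 30."""
        circ = ht.Circulation()
        state = ht.HeartInternalState(pns_tone=1.0)
        curve, nodes = ht.FrankStarlingCurve(), ht.default_nodes()
        t, seen_r, seen_l = 0.0, [], []
        for i in range(45):
            inj = {"epinephrine": 9800.0} if i == 0 else None
            rec, t = ht.advance_stroke(circ, state, curve, nodes, t_prev=t,
                                       index=i, injection=inj)
            if rec.contents_r.concentration("epinephrine") > 0:
                seen_r.append(i)
            if rec.contents_l.concentration("epinephrine") > 0:
                seen_l.append(i)
        assert seen_r == [10]
        assert seen_l == [30]

    def test_coronary_systemic_split_sums_exactly(self):
        left = ht.ReducedVector(70.0, {"epinephrine": 9800.0, "o2": 15.0})
        coronary, systemic = left.split(ht.CORONARY_FRACTION)
        merged = ht.ReducedVector.combine(coronary, systemic)
        assert merged.volume == left.volume
        for k in left.counts:
            assert merged.counts[k] == left.counts[k]

    def test_empty_buffer_is_uninitialized_circulation(self):
        circ = ht.Circulation(delays={"systemic-venous": 0, "pulmonary": 0,
                                      "coronary": 0, "systemic-arterial": 0})
        with pytest.raises(ht.UninitializedCirculationError):
            ht.advance_stroke(circ, ht.HeartInternalState(),
                              ht.FrankStarlingCurve(), ht.default_nodes())


@pytest.fixture(scope="module")
def result():
    return ht.run_epinephrine_scenario()


class TestEpinephrineScenario:
    def test_left_contents_0_then_140_pg_per_mL(self, result):
        assert result.left_epinephrine[0] == 0.0
        assert result.left_epinephrine[30] == pytest.approx(140.0)

    def test_saturation_reaches_140_bpm_and_100_mL(self, result):
        assert result.macro.HR[50] == pytest.approx(140.0)
        assert result.macro.SV[50] == pytest.approx(100.0)

    def test_baseline_before_binding(self, result):
        assert result.macro.HR[20] == pytest.approx(70.0)
        assert result.macro.SV[20] == pytest.approx(70.0)

    def test_intervals_shrink_and_sv_grows(self, result):
        t = result.macro.T
        assert t[50] - t[49] < t[1] - t[0]
        assert result.macro.SV[50] > result.macro.SV[0]

    def test_interval_strictly_decreasing_on_ramp(self, result):
        intervals = np.diff(result.macro.T)[40:50]
        assert all(b < a for a, b in zip(intervals, intervals[1:]))

    def test_epinephrine_cleared_after_binding(self, result):
        late = [s.contents_l.concentration("epinephrine")
                for s in result.strokes[55:]]
        assert max(late) < 1.0

    def test_zero_injection_control_is_flat(self):
        cfg = ht.EpinephrineConfig(peak_concentration=0.0)
        result = ht.run_epinephrine_scenario(cfg)
        assert result.left_epinephrine.max() == 0.0
        assert np.allclose(result.macro.HR[1:], 70.0)


class TestElectrolytesAndKatp:
    def test_high_potassium_arrests_the_heart(self):
        state = ht.HeartInternalState(potassium="high")
        assert ht.effective_heart_rate(ht.default_nodes(), state) == 0.0

    def test_normal_electrolytes_are_identity(self):
        ov = ht.apply_electrolyte_rules(ht.HeartInternalState())
        assert (ov.rate_factor, ov.contractility_factor) == (1.0, 1.0)
        assert ov.rate_override is None and not ov.arrhythmia

    def test_low_potassium_weakens_and_destabilises(self):
        ov = ht.apply_electrolyte_rules(ht.HeartInternalState(potassium="low"))
        assert ov.contractility_factor < 1.0 and ov.arrhythmia

    def test_high_calcium_raises_rate_and_contractility(self):
        ov = ht.apply_electrolyte_rules(ht.HeartInternalState(calcium="high"))
        assert ov.rate_factor > 1.0 and ov.contractility_factor > 1.0

    def test_very_high_calcium_adds_arrhythmia(self):
        ov = ht.apply_electrolyte_rules(
            ht.HeartInternalState(calcium="very-high"))
        assert ov.arrhythmia

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="electrolyte"):
            ht.apply_electrolyte_rules(ht.HeartInternalState(potassium="weird"))

    def test_katp_opens_under_ischemia_and_speeds_weakens(self):
        base = ht.HeartInternalState(pns_tone=1.0)
        ischemic = ht.apply_katp_rule(ht.HeartInternalState(pns_tone=1.0,
                                                            ischemia=True))
        assert ischemic.katp_open
        curve, nodes = ht.FrankStarlingCurve(), ht.default_nodes()
        assert ht.effective_heart_rate(nodes, ischemic) > \
            ht.effective_heart_rate(nodes, base)          # shorter interval
        assert ht.stroke_volume(140.0, curve, ischemic) < \
            ht.stroke_volume(140.0, curve, base)          # weaker contraction

    def test_katp_noop_without_ischemia(self):
        state = ht.HeartInternalState()
        assert ht.apply_katp_rule(state) == state

    def test_katp_reduces_ischemic_damage(self):
        episode = ht.HeartInternalState(ischemia=True)
        protected = ht.accumulate_ischemic_damage(
            ht.apply_katp_rule(episode), strokes=200)
        unprotected = ht.accumulate_ischemic_damage(episode, strokes=200)
        assert protected.cell_damage < unprotected.cell_damage


class TestConductionAndChemicalControls:
    def test_default_atrioventricular_gap_is_200_ms(self):
        atrial, ventricular, gap = ht.conduction_timing()
        assert gap == 200.0
        assert atrial == 70.0

    def test_zero_delay_equal_offsets_gives_zero_gap(self):
        assert ht.conduction_timing(0.0, 100.0, 100.0)[2] == 0.0

    def test_gap_linear_in_av_delay(self):
        gaps = [ht.conduction_timing(av_delay_ms=d)[2] for d in (50, 100, 150)]
        assert gaps[1] - gaps[0] == gaps[2] - gaps[1] == 50.0

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError, match="timing"):
            ht.conduction_timing(0.0, 300.0, 100.0)

    def test_adenosine_resting_workload_is_inert(self):
        factor, actions = ht.adenosine_coronary_rule(0.5, ht.HeartInternalState())
        assert factor == 1.0 and actions == []

    def test_adenosine_dilates_under_load(self):
        factor, actions = ht.adenosine_coronary_rule(2.0, ht.HeartInternalState())
        assert factor > 1.0
        assert actions[0].kind == "vessel-dilation"

    def test_adenosine_factor_nondecreasing_in_workload(self):
        factors = [ht.adenosine_coronary_rule(w, ht.HeartInternalState())[0]
                   for w in np.linspace(0, 4, 40)]
        assert all(b >= a for a, b in zip(factors, factors[1:]))

    def test_anp_silent_without_stretch(self):
        assert ht.anp_rule(0.0, ht.HeartInternalState()) == []

    def test_anp_signals_kidneys_and_local_tissue(self):
        actions = ht.anp_rule(2.0, ht.HeartInternalState())
        kinds = {a.kind for a in actions}
        assert "natriuresis-signal" in kinds
        assert "paracrine-antihypertrophy" in kinds

    def test_anp_magnitude_nondecreasing_in_stretch(self):
        mags = []
        for s in np.linspace(1.1, 4, 20):
            mags.append(ht.anp_rule(float(s), ht.HeartInternalState())[0].magnitude)
        assert all(b >= a for a, b in zip(mags, mags[1:]))


class TestRemodeling:
    def test_athlete_regimen_gives_fivefold_output_reserve(self):
        state = ht.remodel(ht.HeartInternalState(), ht.Regimen("athlete", 2.0))
        assert ht.cardiac_output_gain(state) >= 5.0

    def test_rate_doubling_alone_doubles_output(self):
        # CO = HR * SV: with SV fixed, doubling HR exactly doubles CO
        gain = ht.cardiac_output_gain(ht.HeartInternalState(), hr_factor=2.0)
        assert gain == 2.0

    def test_aging_blunts_sympathetic_response(self):
        young = ht.HeartInternalState(norepinephrine=1.0)
        aged = ht.remodel(young, ht.Regimen("aging", duration=30.0))
        nodes = ht.default_nodes()
        assert ht.effective_heart_rate(nodes, aged) < \
            ht.effective_heart_rate(nodes, young)

    def test_infarct_scars_persist(self):
        state = ht.remodel(ht.HeartInternalState(),
                           ht.Regimen("infarct", region="apex", severity=0.4))
        assert state.scar_map["apex"] == pytest.approx(0.6)


class TestMacroSeries:
    def _strokes(self, intervals, sv=70.0, edv=140.0):
        t, out = 0.0, []
        rv = ht.ReducedVector(70.0, {})
        for i, dt in enumerate(intervals):
            t += dt
            out.append(ht.StrokeRecord(i, t, t, edv, edv, sv, sv, rv, rv))
        return out

    def test_constant_intervals_have_zero_hrv(self):
        macro = ht.compute_macroseries(self._strokes([0.860] * 20))
        assert macro.HRV == pytest.approx(0.0)

    def test_resting_cardiac_output_is_4_9_L_min(self):
        macro = ht.compute_macroseries(self._strokes([60.0 / 70.0] * 10))
        assert macro.CO[1] == pytest.approx(4.9, rel=1e-9)

    def test_typical_volumes_give_half_ef_series(self):
        macro = ht.compute_macroseries(self._strokes([1.0] * 5))
        assert np.allclose(macro.EF, 0.5)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            ht.compute_macroseries(self._strokes([1.0]))


class TestHeartAsGeneralRule:
    def test_control_rule_is_well_defined_and_branching(self):
        rule = ht.heart_control_rule()
        verdict = check_well_defined(rule_to_relation(rule), rule.states)
        assert verdict.well_defined is True
        branching, count = check_conditional_branching(rule)
        assert branching is True and count >= 2
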