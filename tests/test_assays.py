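"""MTT viability and GI levels, fluorescence ratios, ddCq fold change."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scratchquant import (
    CqTable,
    DoseResponseCurve,
    FluorescencePair,
    PlateSpec,
    ddcq_fold_change,
    fluorescence_ratio,
    gi_level,
    make_plate,
    plate_to_curve,
    viability_percent,
)


class TestViabilityPercent:
    def test_untreated_equivalence_is_100(self):
        assert viability_percent(T=0.8, Tc=0.1, C=0.8, Cc=0.1) == 100.0

    def test_half_signal_is_the_gi50_condition(self):
        # dyadic absorbances keep (T - Tc) = (C - Cc)/2 exact in floats
        assert viability_percent(T=0.5, Tc=0.25, C=0.75, Cc=0.25) == 50.0

    def test_signal_at_background_is_full_inhibition(self):
        assert viability_percent(T=0.1, Tc=0.1, C=0.9, Cc=0.2) == 0.0

    def test_control_at_background_rejected(self):
        with pytest.raises(ValueError, match="control signal"):
            viability_percent(T=0.5, Tc=0.1, C=0.2, Cc=0.2)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        t=st.floats(0, 2), tc=st.floats(0, 0.5),
        c=st.floats(0.6, 2), cc=st.floats(0, 0.5),
        shift=st.floats(-1, 1),
    )
    def test_affine_invariance(self, t, tc, c, cc, shift):
        base = viability_percent(t, tc, c, cc)
        shifted = viability_percent(t + shift, tc + shift, c + shift, cc + shift)
        assert shifted == pytest.approx(base, abs=1e-8)


class TestGiLevel:
    def test_node_hit_returns_the_node(self):
        curve = DoseResponseCurve(((1, 100.0), (10, 50.0), (100, 0.0)))
        est = gi_level(curve, 50)
        assert est.status == "ok"
        assert est.concentration == 10.0

    def test_log_midpoint_interpolation(self):
        curve = DoseResponseCurve(((1, 100.0), (100, 0.0)))
        est = gi_level(curve, 50)
        assert est.concentration == pytest.approx(10.0, rel=1e-12)

    def test_level_ordering_on_decreasing_curve(self):
        curve = DoseResponseCurve(((1, 95.0), (4, 80.0), (16, 60.0), (64, 30.0), (200, 5.0)))
        c10 = gi_level(curve, 10).concentration
        c25 = gi_level(curve, 25).concentration
        c50 = gi_level(curve, 50).concentration
        assert c10 <= c25 <= c50

    def test_above_range_when_curve_never_drops(self):
        curve = DoseResponseCurve(((1, 99.0), (10, 90.0), (100, 75.0)))
        assert gi_level(curve, 50).status == "above_range"

    def test_below_range_when_curve_starts_below_target(self):
        curve = DoseResponseCurve(((1, 40.0), (10, 20.0), (100, 5.0)))
        assert gi_level(curve, 50).status == "below_range"

    def test_non_monotone_ambiguous(self):
        curve = DoseResponseCurve(((1, 45.0), (10, 60.0), (100, 70.0)))
        assert gi_level(curve, 50).status == "non_monotone_ambiguous"

    @pytest.mark.parametrize("gi50", [5.0, 25.0, 100.0])
    def test_recovers_true_gi50_from_noiseless_4pl_plate(self, gi50):
        plate = make_plate(PlateSpec(gi50_true=gi50, noise_sd=0.0, seed=1))
        est = gi_level(plate_to_curve(plate), 50)
        assert est.status == "ok"
        assert est.concentration == pytest.approx(gi50, rel=0.10)

    def test_error_shrinks_as_dilution_step_refines(self):
        # asymmetric curve (hill != 1, GI50 off the dilution nodes), so the
        # interpolation error is nonzero and must shrink with the step
        errs = []
        for step in (6.0, 2.0, 1.1):
            n = max(8, int(math.ceil(math.log(200 / 0.5, step))) + 1)
            dil = tuple(200.0 / step ** k for k in range(n))
            plate = make_plate(
                PlateSpec(gi50_true=30.0, hill=1.4, dilutions=dil, noise_sd=0.0)
            )
            errs.append(abs(gi_level(plate_to_curve(plate), 50).concentration - 30.0))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.01

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            gi_level(DoseResponseCurve(((1, 50.0),)), 50)


class TestFluorescenceRatio:
    def test_ao_pi_green_over_orange(self):
        assert fluorescence_ratio(FluorescencePair(120.0, 120.0, "AO_PI")) == 1.0

    def test_jc1_orange_over_green(self):
        assert fluorescence_ratio(FluorescencePair(50.0, 100.0, "JC1")) == 2.0

    def test_nao_passes_green_through(self):
        assert fluorescence_ratio(FluorescencePair(137.5, 10.0, "NAO")) == 137.5

    def test_zero_denominator_is_undefined(self):
        with pytest.raises(ZeroDivisionError, match="undefined_ratio"):
            fluorescence_ratio(FluorescencePair(10.0, 0.0, "AO_PI"))


class TestDdcqFoldChange:
    def _table(self, target_treated, target_control, ref_treated=20.0, ref_control=20.0):
        return CqTable(
            records=(
                ("HSP90A", "treated", (target_treated,)),
                ("HSP90A", "control", (target_control,)),
                ("HPRT1", "treated", (ref_treated,)),
                ("HPRT1", "control", (ref_control,)),
            )
        )

    def test_equal_delta_cq_gives_fold_1(self):
        assert ddcq_fold_change(self._table(24.0, 24.0), "HSP90A") == 1.0

    def test_one_cycle_gain_doubles(self):
        # treated dCq one cycle lower than control: ddCq = -1, fold 2
        assert ddcq_fold_change(self._table(23.0, 24.0), "HSP90A") == 2.0

    def test_forced_arithmetic_half(self):
        assert ddcq_fold_change(self._table(25.0, 24.0), "HSP90A") == 0.5

    def test_replicates_averaged_arithmetically(self):
        table = CqTable(
            records=(
                ("G", "treated", (22.0, 24.0)),  # mean 23
                ("G", "control", (24.0,)),
                ("HPRT1", "treated", (20.0,)),
                ("HPRT1", "control", (20.0,)),
            )
        )
        assert ddcq_fold_change(table, "G") == 2.0

    def test_control_against_itself_is_1(self):
        table = CqTable(
            records=(
                ("G", "treated", (26.5,)),
                ("G", "control", (26.5,)),
                ("HPRT1", "treated", (19.2,)),
                ("HPRT1", "control", (19.2,)),
            )
        )
        assert ddcq_fold_change(table, "G") == 1.0

    def test_missing_cell_named_in_error(self):
        table = CqTable(
            records=(
                ("G", "treated", (26.5,)),
                ("HPRT1", "treated", (19.2,)),
                ("HPRT1", "control", (19.2,)),
            )
        )
        with pytest.raises(ValueError, match="'G'.*'control'"):
            ddcq_fold_change(table, "G")

    def test_cq_range_validated(self):
        with pytest.raises(ValueError, match="outside"):
            CqTable(records=(("G", "treated", (55.0,)),))


class TestCurveValidation:
    def test_concentrations_must_increase(self):
        with pytest.raises(ValueError):
            DoseResponseCurve(((10, 50.0), (1, 80.0)))

    def test_concentrations_must_be_positive(self):
        with pytest.raises(ValueError):
            DoseResponseCurve(((0, 100.0), (10, 50.0)))
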