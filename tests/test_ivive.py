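"""In vitro -> in vivo extrapolation arithmetic and its invariants."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dphp_pbpk import ivive

LN2 = math.log(2.0)


class TestHalfLifeDecay:
    @pytest.mark.parametrize(
        "k, expected",
        [(LN2, 1.0), (0.086104, 8.05)],
    )
    def test_values(self, k, expected):
        assert ivive.half_life_from_decay(k) == pytest.approx(expected, rel=1e-3)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ivive.half_life_from_decay(0.0)
        with pytest.raises(ValueError):
            ivive.decay_from_half_life(-1.0)

    @given(st.floats(1e-6, 1e6))
    def test_round_trip(self, k):
        assert ivive.decay_from_half_life(ivive.half_life_from_decay(k)) == pytest.approx(
            k, rel=1e-12
        )


class TestInvitroClearance:
    def test_identity_case(self):
        inp = ivive.InVitroClearanceInput(T_half=LN2, incubation_volume=1.0, microsomal_protein=1.0)
        assert ivive.intrinsic_clearance_invitro(inp) == pytest.approx(1.0)

    def test_study_protein_concentration(self):
        # 0.5 mg microsomal protein per mL => 2 mL per mg
        inp = ivive.InVitroClearanceInput(T_half=8.05, incubation_volume=2.0, microsomal_protein=1.0)
        assert ivive.intrinsic_clearance_invitro(inp) == pytest.approx(0.17221, rel=1e-4)

    def test_protein_proportionality(self):
        a = ivive.InVitroClearanceInput(T_half=10.0, incubation_volume=1.0, microsomal_protein=0.5)
        b = ivive.InVitroClearanceInput(T_half=10.0, incubation_volume=1.0, microsomal_protein=1.0)
        assert ivive.intrinsic_clearance_invitro(a) == pytest.approx(
            2.0 * ivive.intrinsic_clearance_invitro(b)
        )

    def test_k_equivalent_to_half_life(self):
        # ln2/T_half path equals direct decay-constant path
        k = 0.086104
        via_k = ivive.InVitroClearanceInput(k=k, incubation_volume=2.0, microsomal_protein=1.0)
        via_t = ivive.InVitroClearanceInput(
            T_half=ivive.half_life_from_decay(k), incubation_volume=2.0, microsomal_protein=1.0
        )
        assert ivive.intrinsic_clearance_invitro(via_k) == pytest.approx(
            ivive.intrinsic_clearance_invitro(via_t), rel=1e-12
        )

    def test_inconsistent_pair_rejected(self):
        with pytest.raises(ValueError):
            ivive.InVitroClearanceInput(
                k=1.0, T_half=2.0, incubation_volume=1.0, microsomal_protein=1.0
            )
        with pytest.raises(ValueError):
            ivive.InVitroClearanceInput(T_half=1.0, incubation_volume=1.0, microsomal_protein=0.0)


def _ctx(**kw):
    base = dict(MPY=34.0, tissue_mass=2234.07, Q_H=20.8, fu=0.0146, rbc_plasma_ratio=6.67)
    base.update(kw)
    return ivive.ScalingContext(**base)


class TestScaling:
    def test_liver_scaling(self):
        # default MPY and a 3.09% liver of a 72.3 kg subject
        assert ivive.scale_intrinsic_clearance(0.17221, _ctx()) == pytest.approx(784.9, rel=2e-3)

    def test_gut_variant_is_same_formula(self):
        gut = _ctx(MPY=3.9, tissue_mass=0.015 * 72.3 * 1000)
        expected = 0.17221 * 3.9 * 0.015 * 72.3 * 1000 * 60 / 1000
        assert ivive.scale_intrinsic_clearance(0.17221, gut) == pytest.approx(expected, rel=1e-12)

    def test_zero_maps_to_zero(self):
        assert ivive.scale_intrinsic_clearance(0.0, _ctx()) == 0.0


class TestWellStirred:
    def test_hand_value(self):
        assert ivive.well_stirred_clearance(784.9, _ctx()) == pytest.approx(10.6, rel=5e-3)

    def test_low_clearance_limit(self):
        ctx = _ctx()
        clint = 1e-8
        assert ivive.well_stirred_clearance(clint, ctx) / (ctx.fu * clint) == pytest.approx(
            1.0, rel=1e-6
        )

    def test_high_clearance_limit(self):
        ctx = _ctx()
        assert ivive.well_stirred_clearance(1e12, ctx) == pytest.approx(
            ctx.Q_H * ctx.rbc_plasma_ratio, rel=1e-6
        )

    @given(
        st.floats(0.1, 1e5),
        st.floats(1.0, 500.0),
        st.floats(1e-4, 1.0),
        st.floats(0.1, 20.0),
    )
    def test_bounded_by_flow_and_capacity(self, clint, qh, fu, r):
        ctx = _ctx(Q_H=qh, fu=fu, rbc_plasma_ratio=r)
        cl = ivive.well_stirred_clearance(clint, ctx)
        assert cl <= min(qh * r, fu * clint) * (1 + 1e-12)
        assert cl >= 0


class TestFractionUnbound:
    def test_symmetry_point(self):
        assert ivive.fraction_unbound(0.4782 / 0.4485) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("logp, expected", [(5.3, 0.01247), (10.83, 4.18e-5)])
    def test_formula_values(self, logp, expected):
        # direct evaluation of the regression; the shipped configuration
        # defaults intentionally use the printed table values instead
        assert ivive.fraction_unbound(logp) == pytest.approx(expected, rel=2e-3)

    @given(st.floats(-8, 8), st.floats(0.01, 5.0))
    def test_monotone_decreasing_into_unit_interval(self, logp, step):
        lo, hi = ivive.fraction_unbound(logp + step), ivive.fraction_unbound(logp)
        assert 0.0 < lo < hi < 1.0

    def test_extreme_logp_saturates_within_unit_interval(self):
        assert 0.0 <= ivive.fraction_unbound(50.0) < 1e-15
        assert ivive.fraction_unbound(-50.0) == pytest.approx(1.0)


class TestFractionMetabolised:
    def test_equal_amounts(self):
        amounts = ivive.MetaboliteAmounts(1.0, 1.0, 1.0, 1.0)
        assert ivive.fraction_metabolised(amounts) == pytest.approx((0.25, 0.25))

    def test_hand_sum(self):
        amounts = ivive.MetaboliteAmounts(mphp=1.0, oh_mphp=2.0, cx_mphp=0.5, oxo_mphp=0.5)
        assert ivive.fraction_metabolised(amounts) == pytest.approx((0.5, 0.125))

    def test_study_report_format(self):
        # volunteer-A style fractions (0.396 OH, 0.02 cx) round-trip from
        # molar amounts summing to one
        amounts = ivive.MetaboliteAmounts(mphp=0.5, oh_mphp=0.396, cx_mphp=0.02, oxo_mphp=0.084)
        oh, cx = ivive.fraction_metabolised(amounts)
        assert (round(oh, 3), round(cx, 3)) == (0.396, 0.02)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            ivive.fraction_metabolised(ivive.MetaboliteAmounts(0, 0, 0, 0))

    @given(st.lists(st.floats(1e-9, 1e6), min_size=4, max_size=4))
    def test_all_four_fractions_sum_to_one(self, amounts):
        ma = ivive.MetaboliteAmounts(*amounts)
        oh, cx = ivive.fraction_metabolised(ma)
        other = (ma.mphp + ma.oxo_mphp) / ma.total
        assert oh + cx + other == pytest.approx(1.0, rel=1e-9)


def test_report_writer_round_trip(tmp_path):
    import csv

    path = tmp_path / "derived.csv"
    ivive.write_derived_parameter_report(
        path, {"CLint": (784.9, "L/h"), "fu": (0.0146, "fraction")}
    )
    with open(path) as fh:
        rows = list(csv.reader(fh))
    assert rows[0] == ["parameter", "value", "units"]
    assert float(rows[1][1]) == 784.9 and rows[2][2] == "fraction"
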