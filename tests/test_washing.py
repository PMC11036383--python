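"""Washing mechanisms: dispersion washout, piston displacement, well-mixed."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from isowash import (
    LiquidComposition,
    WashStage,
    apply_wash_stage,
    dispersion_exit_ratio,
    dispersion_washout,
    displacement_wash,
    run_wash_program,
    segment_wash_curve,
    well_mixed_wash,
)
from isowash.errors import (
    InvalidArgumentError,
    InvalidCurveError,
    InvalidStateError,
)
from isowash.washing import WashCurve

PURE_HEPTANE = LiquidComposition.pure("heptane")


def heptane_stage(**kw):
    return WashStage(wash_composition=PURE_HEPTANE, **kw)


class TestDispersionWashout:
    def test_no_wash_leaves_exit_at_mother_liquor(self):
        for pe in (0.5, 10.0, 1e4):
            assert dispersion_exit_ratio(0.0, pe) == 1.0

    def test_plug_flow_limit_is_a_step_at_one_pore_volume(self):
        assert dispersion_exit_ratio(0.5, 1e6) == pytest.approx(1.0, abs=1e-3)
        assert dispersion_exit_ratio(1.5, 1e6) == pytest.approx(0.0, abs=1e-3)

    def test_mass_balance_closes_by_quadrature(self):
        """Total solute carried out over W in [0, 10] equals the initial
        pore solute within 1% (exit curve integrates to one)."""
        integral, _ = quad(
            lambda w: dispersion_exit_ratio(w, 10.0), 0.0, 10.0,
            points=[1.0], limit=200,
        )
        assert integral == pytest.approx(1.0, rel=0.01)

    def test_monotone_non_increasing_in_wash_ratio(self):
        w = np.linspace(0.0, 5.0, 400)
        for pe in (0.5, 5.0, 50.0, 1e4):
            c = dispersion_exit_ratio(w, pe)
            assert np.all(np.diff(c) <= 1e-12)

    def test_tail_decreases_with_peclet(self):
        # sharper fronts (higher Pe) leave less solute to wash out late
        for w in (1.3, 2.0, 4.0):
            ratios = [dispersion_exit_ratio(w, pe) for pe in (2.0, 10, 1e3)]
            assert ratios == sorted(ratios, reverse=True)

    def test_converges_to_displacement_step_at_large_peclet(self):
        w = np.linspace(0.01, 3.0, 500)
        off_front = np.abs(w - 1.0) > 0.05
        step = np.where(w < 1.0, 1.0, 0.0)
        c = dispersion_exit_ratio(w, 1e6)
        assert np.max(np.abs(c[off_front] - step[off_front])) <= 1e-3

    def test_large_peclet_stays_finite(self):
        c = dispersion_exit_ratio(np.linspace(0, 10, 101), 1e8)
        assert np.all(np.isfinite(c))

    def test_invalid_peclet_rejected(self):
        with pytest.raises(InvalidArgumentError):
            dispersion_exit_ratio(1.0, 0.0)

    def test_washout_curve_grid_and_labels(self):
        curve = dispersion_washout(np.linspace(0.0, 6.0, 200), 10.0)
        labels = set(curve.stage_labels)
        assert labels == {"constant_rate", "intermediate", "diffusion"}


class TestDisplacement:
    def test_zero_wash_is_identity(self, mfa2_cake, db):
        stage = heptane_stage(mechanism="displacement", wash_ratio=0.0)
        res = displacement_wash(mfa2_cake, stage, db)
        assert res.final_cake.liquor_mass == pytest.approx(
            mfa2_cake.liquor_mass
        )
        assert res.per_stage[0].filtrate_mass == 0.0

    def test_full_wash_ratio_replaces_pore_liquor(self, mfa2_cake, db):
        stage = heptane_stage(mechanism="displacement", wash_ratio=1.0)
        res = displacement_wash(mfa2_cake, stage, db)
        assert res.final_cake.liquor.fraction("heptane") == pytest.approx(1.0)
        assert res.final_cake.species_masses().get("cba", 0.0) == 0.0

    def test_half_wash_ratio_removes_half_the_impurity(self, mfa2_cake, db):
        stage = heptane_stage(mechanism="displacement", wash_ratio=0.5)
        res = displacement_wash(mfa2_cake, stage, db)
        rec = res.per_stage[0]
        m0 = mfa2_cake.species_masses()
        # filtrate is half a pore volume of pure mother liquor
        assert rec.species_removed["cba"] == pytest.approx(0.5 * m0["cba"])
        assert rec.species_removed.get("heptane", 0.0) == pytest.approx(0.0)
        assert rec.filtrate_mass == pytest.approx(0.5 * mfa2_cake.liquor_mass)

    def test_unsaturated_cake_rejected(self, mfa2_cake, db):
        from dataclasses import replace

        dry = replace(mfa2_cake, liquor_volume=0.5 * mfa2_cake.liquor_volume)
        with pytest.raises(InvalidStateError):
            displacement_wash(
                dry, heptane_stage(mechanism="displacement", wash_ratio=1.0),
                db,
            )


class TestWellMixed:
    def test_zero_wash_is_identity_in_both_modes(self, mfa2_cake, db):
        for mode in ("accumulate", "feed_and_bleed"):
            stage = heptane_stage(
                mechanism="well_mixed", mixed_mode=mode, wash_ratio=0.0
            )
            res = well_mixed_wash(mfa2_cake, stage, db)
            assert res.final_cake.species_masses() == pytest.approx(
                mfa2_cake.species_masses()
            )

    def test_feed_and_bleed_unit_wash_ratio_is_e_minus_one(
        self, mfa2_cake, db
    ):
        stage = heptane_stage(
            mechanism="well_mixed", mixed_mode="feed_and_bleed", wash_ratio=1.0
        )
        res = well_mixed_wash(mfa2_cake, stage, db)
        ratio = (
            res.final_cake.species_masses()["cba"]
            / mfa2_cake.species_masses()["cba"]
        )
        assert ratio == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_accumulate_equal_volume_halves_concentration(
        self, mfa2_cake, db
    ):
        stage = heptane_stage(
            mechanism="well_mixed", mixed_mode="accumulate", wash_ratio=1.0
        )
        res = well_mixed_wash(mfa2_cake, stage, db)
        c0 = mfa2_cake.species_masses()["cba"] / mfa2_cake.liquor_volume
        c1 = (
            res.final_cake.species_masses()["cba"]
            / res.final_cake.liquor_volume
        )
        assert c1 / c0 == pytest.approx(0.5, rel=1e-12)
        # semibatch: no outflow, the held liquid grows by the wash volume
        assert res.per_stage[0].filtrate_mass == 0.0
        assert res.final_cake.liquor_volume == pytest.approx(
            2.0 * mfa2_cake.liquor_volume
        )


class TestWashProgram:
    def test_two_feed_and_bleed_stages_compose_exponentially(
        self, mfa2_cake, db
    ):
        stage = heptane_stage(
            mechanism="well_mixed", mixed_mode="feed_and_bleed", wash_ratio=1.0
        )
        res = run_wash_program(mfa2_cake, [stage, stage], db, curve_points=0)
        ratio = (
            res.final_cake.species_masses()["cba"]
            / mfa2_cake.species_masses()["cba"]
        )
        assert ratio == pytest.approx(math.exp(-2.0), rel=1e-9)

    def test_all_zero_stages_are_identity(self, mfa2_cake, db):
        stages = [
            heptane_stage(mechanism="displacement", wash_ratio=0.0),
            heptane_stage(mechanism="well_mixed", wash_ratio=0.0,
                          mixed_mode="feed_and_bleed"),
        ]
        res = run_wash_program(mfa2_cake, stages, db, curve_points=0)
        assert res.final_cake.species_masses() == pytest.approx(
            mfa2_cake.species_masses()
        )

    def test_mfa_program_first_stage_is_mother_liquor_dominated(
        self, mfa2, mfa2_cake
    ):
        """W=2 piston wash: stage 1 removes the entire pore impurity."""
        res = run_wash_program(
            mfa2_cake, mfa2.wash_program, mfa2.species_db, curve_points=0
        )
        rec = res.per_stage[0]
        m0 = mfa2_cake.species_masses()
        assert rec.species_removed["cba"] == pytest.approx(m0["cba"])
        # one of the two pore volumes of filtrate is pure mother liquor
        assert rec.filtrate_composition.fraction("diglyme_water") > 0.3

    @pytest.mark.parametrize("mechanism,kw", [
        ("displacement", {}),
        ("dispersion", {"peclet": 7.0}),
        ("well_mixed", {"mixed_mode": "accumulate"}),
        ("well_mixed", {"mixed_mode": "feed_and_bleed"}),
    ])
    def test_species_conservation_every_mechanism(
        self, mfa2_cake, db, mechanism, kw
    ):
        stages = [
            heptane_stage(mechanism=mechanism, wash_ratio=1.5, **kw),
            heptane_stage(mechanism=mechanism, wash_ratio=0.8, **kw),
        ]
        res = run_wash_program(mfa2_cake, stages, db, curve_points=0)
        wash_in = {}
        v0 = mfa2_cake.void_volume
        rho_w = db["heptane"].liquid_density
        held = mfa2_cake.liquor_volume
        for st_ in stages:
            wash_in["heptane"] = wash_in.get("heptane", 0.0) + (
                st_.wash_ratio * v0 * rho_w
            )
        assert res.mass_balance_error(wash_in) <= 1e-8

    @settings(derandomize=True, max_examples=30)
    @given(
        split=st.floats(0.05, 0.95),
        total=st.floats(0.5, 5.0),
    )
    def test_feed_and_bleed_split_invariance(self, split, total, mfa2_cake,
                                             db):
        """Residual impurity depends only on the total wash ratio."""
        one = run_wash_program(
            mfa2_cake,
            [heptane_stage(mechanism="well_mixed",
                           mixed_mode="feed_and_bleed", wash_ratio=total)],
            db, curve_points=0,
        )
        two = run_wash_program(
            mfa2_cake,
            [
                heptane_stage(mechanism="well_mixed",
                              mixed_mode="feed_and_bleed",
                              wash_ratio=split * total),
                heptane_stage(mechanism="well_mixed",
                              mixed_mode="feed_and_bleed",
                              wash_ratio=(1 - split) * total),
            ],
            db, curve_points=0,
        )
        a = one.final_cake.species_masses()["cba"]
        b = two.final_cake.species_masses()["cba"]
        assert b == pytest.approx(a, rel=1e-9)

    def test_accumulate_mode_is_split_sensitive(self, mfa2_cake, db):
        """Two equal dilutions beat one double-volume dilution and match
        the product formula prod_i V0/(V0+V_i)."""
        v0 = mfa2_cake.liquor_volume
        one = run_wash_program(
            mfa2_cake,
            [heptane_stage(mechanism="well_mixed", mixed_mode="accumulate",
                           volume=2.0 * v0)],
            db, curve_points=0,
        )
        two = run_wash_program(
            mfa2_cake,
            [heptane_stage(mechanism="well_mixed", mixed_mode="accumulate",
                           volume=v0),
             heptane_stage(mechanism="well_mixed", mixed_mode="accumulate",
                           volume=v0)],
            db, curve_points=0,
        )
        c0 = mfa2_cake.species_masses()["cba"] / v0
        c_one = one.final_cake.species_masses()["cba"] / one.final_cake.liquor_volume
        c_two = two.final_cake.species_masses()["cba"] / two.final_cake.liquor_volume
        assert c_one / c0 == pytest.approx(1.0 / 3.0, rel=1e-12)
        # (V0/(V0+V0))^2: half the impurity drains between the stages
        assert c_two / c0 == pytest.approx(0.25, rel=1e-12)
        assert c_two < c_one
        # the inter-stage drain is the second stage's filtrate
        assert two.per_stage[0].filtrate_mass == 0.0
        assert two.per_stage[1].filtrate_mass > 0.0

    def test_program_curve_covers_cumulative_wash_ratio(self, mfa2, mfa2_cake):
        res = run_wash_program(
            mfa2_cake, mfa2.wash_program, mfa2.species_db, curve_points=20
        )
        total_w = sum(s.wash_ratio for s in mfa2.wash_program)
        assert res.curve.wash_ratios[-1] == pytest.approx(total_w)
        for ratio in res.curve.exit_concentration_ratio.values():
            assert np.all(ratio <= 1 + 1e-9)
            assert np.all(ratio >= -1e-12)


class TestSegmentWashCurve:
    def test_step_curve_has_empty_intermediate_stage(self):
        w = np.linspace(0.0, 2.0, 21)
        curve = WashCurve(
            wash_ratios=w,
            exit_concentration_ratio={"x": np.where(w < 1.0, 1.0, 0.0)},
        )
        seg = segment_wash_curve(curve)
        assert "intermediate" not in seg.curve.stage_labels
        # boundaries coincide at breakthrough
        assert seg.constant_rate_end < 1.0 <= seg.diffusion_start

    def test_dispersion_curve_has_three_stages(self):
        w = np.linspace(0.0, 6.0, 400)
        curve = dispersion_washout(w, 10.0, label=False)
        seg = segment_wash_curve(curve)
        c = curve.exit_concentration_ratio["solute"]
        # boundaries agree with a direct threshold search
        direct_const = w[np.nonzero(c >= 0.95)[0][-1]]
        direct_diff = w[np.nonzero(c <= 0.05)[0][0]]
        assert seg.constant_rate_end == pytest.approx(direct_const)
        assert seg.diffusion_start == pytest.approx(direct_diff)

    def test_curve_above_breakthrough_is_all_constant_rate(self):
        w = np.linspace(0.0, 0.3, 10)
        curve = WashCurve(
            wash_ratios=w, exit_concentration_ratio={"x": np.ones_like(w)}
        )
        seg = segment_wash_curve(curve)
        assert set(seg.curve.stage_labels) == {"constant_rate"}
        assert seg.diffusion_start is None

    def test_non_monotone_curve_rejected(self):
        w = np.linspace(0.0, 2.0, 5)
        curve = WashCurve(
            wash_ratios=w,
            exit_concentration_ratio={"x": np.array([1, 0.5, 0.7, 0.2, 0.1])},
        )
        with pytest.raises(InvalidCurveError):
            segment_wash_curve(curve)


def test_stage_requires_exactly_one_size():
    with pytest.raises(InvalidArgumentError):
        WashStage(wash_composition=PURE_HEPTANE, wash_ratio=1.0, volume=1e-6)
    with pytest.raises(InvalidArgumentError):
        WashStage(wash_composition=PURE_HEPTANE)
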