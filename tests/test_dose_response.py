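"""Survival-curve normalization, AUSC integration and synergy scoring."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import trapezoid_oracle
from synercurve.dose_response import (
    AnchorError,
    GridError,
    InsufficientDataError,
    NormalizationError,
    SurvivalCurve,
    anchor_normalize,
    ausc,
    delta_ausc,
    densitometry,
    normalize_viability,
    panel_screen,
)
from synercurve.io_tables import PlateRecord


def _well(dose, signal, rep=1, primary_dose=0.0):
    return PlateRecord(
        cell_line="L1",
        primary_drug="EZH2i" if primary_dose > 0 else None,
        primary_dose=primary_dose,
        secondary_drug="pan" if dose > 0 else None,
        secondary_dose=dose,
        schedule="pretreat_4d",
        replicate=rep,
        signal=signal,
    )


class TestNormalizeViability:
    def test_single_replicate_fractions(self):
        recs = [_well(0.0, 10000.0), _well(5.0, 8000.0), _well(10.0, 5000.0)]
        curve = normalize_viability(recs)
        assert curve.doses == (0.0, 5.0, 10.0)
        assert curve.survival == pytest.approx((1.0, 0.8, 0.5))

    def test_scale_invariance(self):
        recs = [_well(0.0, 10000.0), _well(5.0, 8000.0), _well(10.0, 5000.0)]
        scaled = [_well(r.secondary_dose, r.signal * 3.7) for r in recs]
        c1, c2 = normalize_viability(recs), normalize_viability(scaled)
        assert c1.survival == pytest.approx(c2.survival)
        assert c1.sem == pytest.approx(c2.sem)

    def test_replicate_mean_and_sem(self):
        # normalized replicates {0.80, 0.84}: mean 0.82, SEM = sd/sqrt(2) = 0.02
        recs = [
            _well(0.0, 10000.0, rep=1),
            _well(0.0, 10000.0, rep=2),
            _well(5.0, 8000.0, rep=1),
            _well(5.0, 8400.0, rep=2),
        ]
        curve = normalize_viability(recs)
        i = curve.doses.index(5.0)
        assert curve.survival[i] == pytest.approx(0.82)
        assert curve.sem[i] == pytest.approx(0.02)

    def test_zero_control_raises(self):
        recs = [_well(0.0, 0.0), _well(5.0, 8000.0), _well(10.0, 100.0)]
        with pytest.raises(NormalizationError):
            normalize_viability(recs)

    def test_single_dose_raises(self):
        with pytest.raises(InsufficientDataError):
            normalize_viability([_well(0.0, 10000.0)])


class TestAnchorNormalize:
    def test_divides_by_zero_dose_point(self):
        c = SurvivalCurve("L", "x", (0.0, 5.0, 10.0), (0.6, 0.48, 0.30), (0.0,) * 3)
        a = anchor_normalize(c)
        assert a.survival == pytest.approx((1.0, 0.8, 0.5))
        assert a.survival[0] == 1.0

    def test_idempotent(self):
        c = SurvivalCurve("L", "x", (0.0, 5.0, 10.0), (0.6, 0.48, 0.30), (0.0,) * 3)
        once = anchor_normalize(c)
        twice = anchor_normalize(once)
        assert once == twice

    def test_missing_zero_dose_raises(self):
        c = SurvivalCurve("L", "x", (1.0, 5.0), (1.0, 0.5), (0.0, 0.0))
        with pytest.raises(AnchorError):
            anchor_normalize(c)

    def test_zero_anchor_raises(self):
        c = SurvivalCurve("L", "x", (0.0, 5.0), (0.0, 0.5), (0.0, 0.0))
        with pytest.raises(AnchorError):
            anchor_normalize(c)


class TestAusc:
    def test_constant_curve_is_height_times_span(self):
        c = SurvivalCurve("L", "x", (1.0, 10.0, 100.0, 1000.0), (1.0,) * 4, (0.0,) * 4)
        assert ausc(c, "log10_dose") == pytest.approx(3.0)

    def test_hand_computed_trapezoid(self):
        # survival [1.0, 0.8, 0.5, 0.2] at log10 doses [0,1,2,3]:
        # 0.9 + 0.65 + 0.35 = 1.90
        c = SurvivalCurve(
            "L", "x", (1.0, 10.0, 100.0, 1000.0), (1.0, 0.8, 0.5, 0.2), (0.0,) * 4
        )
        assert ausc(c, "log10_dose") == pytest.approx(1.90)

    def test_index_mode(self):
        c = SurvivalCurve("L", "x", (0.0, 5.0), (1.0, 0.0), (0.0, 0.0))
        assert ausc(c, "index") == pytest.approx(0.5)

    def test_zero_dose_excluded_on_log_axis(self):
        with_zero = SurvivalCurve(
            "L", "x", (0.0, 1.0, 10.0), (1.0, 0.9, 0.4), (0.0,) * 3
        )
        without = SurvivalCurve("L", "x", (1.0, 10.0), (0.9, 0.4), (0.0, 0.0))
        assert ausc(with_zero, "log10_dose") == pytest.approx(ausc(without, "log10_dose"))

    def test_too_few_nonzero_points_raises(self):
        c = SurvivalCurve("L", "x", (0.0, 5.0), (1.0, 0.5), (0.0, 0.0))
        with pytest.raises(InsufficientDataError):
            ausc(c, "log10_dose")

    @given(
        st.integers(min_value=4, max_value=12),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_matches_independent_trapezoid(self, n, seed):
        rng = np.random.default_rng(seed)
        doses = np.sort(rng.uniform(0.1, 1000.0, n))
        doses += np.arange(n) * 1e-6  # enforce strict increase
        surv = rng.uniform(0.0, 1.2, n)
        c = SurvivalCurve("L", "x", tuple(doses), tuple(surv), (0.0,) * n)
        expected = trapezoid_oracle(np.log10(doses), surv)
        assert ausc(c, "log10_dose") == pytest.approx(expected, abs=1e-12)

    def test_monotonicity(self, rng):
        for _ in range(50):
            n = rng.integers(4, 10)
            doses = tuple(np.sort(rng.uniform(0.1, 100, n)) + np.arange(n) * 1e-6)
            hi = rng.uniform(0.2, 1.2, n)
            lo = hi * rng.uniform(0.0, 1.0, n)
            c_hi = SurvivalCurve("L", "x", doses, tuple(hi), (0.0,) * n)
            c_lo = SurvivalCurve("L", "x", doses, tuple(lo), (0.0,) * n)
            assert ausc(c_lo, "log10_dose") <= ausc(c_hi, "log10_dose") + 1e-12


class TestDeltaAusc:
    def _curve(self, surv):
        doses = (0.0, 1.0, 10.0, 100.0)
        return SurvivalCurve("L", "x", doses, surv, (0.0,) * 4)

    def test_identical_curves_score_zero(self):
        c = self._curve((1.0, 0.9, 0.6, 0.3))
        s = delta_ausc(c, c)
        assert s.delta_ausc_rel == pytest.approx(0.0)
        assert s.delta_ausc_abs == pytest.approx(0.0)

    def test_hand_computed_relative_drop(self):
        # single [1,1,1] and combo [1,0,0] over log10 doses [0,1,2]:
        # (2.0 - 0.5)/2.0 = 0.75
        doses = (0.0, 1.0, 10.0, 100.0)
        single = SurvivalCurve("L", "s", doses, (1.0, 1.0, 1.0, 1.0), (0.0,) * 4)
        combo = SurvivalCurve("L", "c", doses, (1.0, 1.0, 0.0, 0.0), (0.0,) * 4)
        s = delta_ausc(single, combo)
        assert s.ausc_single == pytest.approx(2.0)
        assert s.ausc_combo == pytest.approx(0.5)
        assert s.delta_ausc_rel == pytest.approx(0.75)

    def test_dominated_combo_scores_nonnegative(self, rng):
        for _ in range(30):
            base = rng.uniform(0.2, 1.2, 4)
            combo_s = base * rng.uniform(0.0, 1.0, 4)
            single = self._curve(tuple(base))
            combo = self._curve(tuple(combo_s))
            assert delta_ausc(single, combo).delta_ausc_rel >= -1e-12

    def test_grid_mismatch_raises(self):
        a = self._curve((1.0, 0.9, 0.6, 0.3))
        b = SurvivalCurve("L", "x", (0.0, 2.0, 20.0, 200.0), (1.0, 0.9, 0.6, 0.3), (0.0,) * 4)
        with pytest.raises(GridError):
            delta_ausc(a, b)


class TestPanelScreen:
    def test_orders_synergistic_first(self):
        doses = (0.0, 1.0, 10.0, 100.0)

        def curve(line, cond, surv):
            return SurvivalCurve(line, cond, doses, surv, (0.0,) * 4)

        syn_pair = (
            curve("SYN", "s", (1.0, 1.0, 0.8, 0.5)),
            curve("SYN", "c", (1.0, 0.5, 0.2, 0.05)),
        )
        null_pair = (
            curve("NULL", "s", (1.0, 1.0, 0.8, 0.5)),
            curve("NULL", "c", (1.0, 1.0, 0.8, 0.5)),
        )
        res = panel_screen([null_pair, syn_pair])
        assert [s.cell_line for s in res.scores] == ["SYN", "NULL"]
        assert res.n_called == 1

    def test_empty_panel(self):
        res = panel_screen([])
        assert res.scores == () and res.n_called == 0

    def test_missing_single_agent_skipped(self, toy_curve):
        res = panel_screen([(None, toy_curve)])
        assert res.n_skipped == 1 and res.scores == ()


class TestDensitometry:
    @pytest.mark.parametrize(
        "treated,untreated,expected",
        [
            ((0.5, 1.0), (1.0, 1.0), 0.5),
            ((0.7, 1.4), (0.7, 1.4), 1.0),
            ((0.3, 0.6), (0.9, 0.6), 1 / 3),
        ],
    )
    def test_relative_ratio(self, treated, untreated, expected):
        r = densitometry(treated, untreated)
        assert r.relative_methylation == pytest.approx(expected)

    def test_zero_total_h3_raises(self):
        with pytest.raises(ValueError):
            densitometry((0.5, 0.0), (1.0, 1.0))

    def test_zero_untreated_ratio_raises(self):
        with pytest.raises(ValueError):
            densitometry((0.5, 1.0), (0.0, 1.0))
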