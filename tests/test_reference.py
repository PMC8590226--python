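"""Tests for reference construction, SDS scoring and individual assessment."""

import numpy as np
import pytest

from qepsgrowth.fitting import Measurement
from qepsgrowth.qeps_model import (
    DEFAULT_SHAPE,
    QEPSParams,
    ValidationError,
    age_p5,
)
from qepsgrowth.reference import (
    ALIGNED_GRID,
    IndividualCurve,
    OutOfReferenceRangeError,
    align_curve,
    assess_individual,
    build_reference,
    sds,
    value_at_sds,
)

SHAPE = DEFAULT_SHAPE["F"]


def wparams(**kw) -> QEPSParams:
    base = dict(c_Q=4.0, c_E=2.3, c_P=1.4, c_S=0.02, theta_P=11.0,
                sigma_P=0.9, trait="weight")
    base.update(kw)
    return QEPSParams(**base)


def wcurve(sid="s", whf=0.0, **kw) -> IndividualCurve:
    p = wparams(**kw)
    return IndividualCurve(subject_id=sid, params=p, shape=SHAPE, whf=whf,
                           age_p5=age_p5(p))


class TestAlignCurve:
    def test_default_grid_has_141_points(self):
        ac = align_curve(wcurve())
        assert ac.grid.size == 141
        assert ac.grid[0] == pytest.approx(-4.0)
        assert ac.grid[-1] == pytest.approx(10.0)

    def test_p_fraction_at_onset_is_five_percent(self):
        whf = 0.08
        ac = align_curve(wcurve(whf=whf))
        k = int(np.argmin(np.abs(ac.grid)))
        pmax = (1 + whf) * 1.4
        assert ac.values["p_specific"][k] == pytest.approx(0.05 * pmax,
                                                           rel=1e-6)

    def test_pubertal_component_invariant_to_timing_shift(self):
        a = align_curve(wcurve(theta_P=11.0))
        b = align_curve(wcurve(theta_P=12.0))
        np.testing.assert_allclose(a.values["p_specific"],
                                   b.values["p_specific"], rtol=1e-12)

    def test_alignment_uses_height_onset_when_given(self):
        ac = align_curve(wcurve(), height_age_p5=9.0)
        assert ac.age_p5 == 9.0

    def test_per_subject_component_additivity(self):
        ac = align_curve(wcurve(whf=0.1))
        vals = wcurve(whf=0.1).component_values(ac.age_p5 + ac.grid)
        np.testing.assert_allclose(
            vals["basic"] + vals["p_specific"], vals["total"], rtol=1e-12)


class TestBuildReference:
    def test_two_point_sample_statistics(self):
        # E component saturates early: curve values ~4 and ~6 at age 4
        a = wcurve("a", c_Q=0.0, c_E=4.0, c_P=1.0, c_S=0.0)
        b = wcurve("b", c_Q=0.0, c_E=6.0, c_P=2.0, c_S=0.0)
        table = build_reference([a, b], axis="chronological",
                                grid=np.array([4.0, 6.0, 8.0]), sex="F")
        assert table.median_at(4.0, "basic") == pytest.approx(5.0, abs=5e-3)
        assert table.sd_at(4.0, "basic") == pytest.approx(np.sqrt(2), abs=5e-3)

    def test_identical_subjects_rejected(self):
        with pytest.raises(ValidationError, match="SD"):
            build_reference([wcurve("a"), wcurve("b")], axis="chronological",
                            grid=np.array([5.0, 10.0]), sex="F")

    def test_single_subject_rejected(self):
        with pytest.raises(ValidationError):
            build_reference([wcurve("a")], axis="chronological", sex="F")

    def test_median_monotone_in_age(self, truth_weight_curves_500):
        table = build_reference(truth_weight_curves_500[:200],
                                axis="chronological", sex="F")
        grid = table.grid
        sel = (grid >= 4.0) & (grid <= 18.0)
        assert np.all(np.diff(np.asarray(table.median["total"])[sel]) >= 0)

    def test_aligned_reference_spans_pubertal_axis(self, truth_weight_curves_500):
        table = build_reference(truth_weight_curves_500[:100],
                                axis="puberty_aligned", sex="F")
        assert table.grid[0] == pytest.approx(-4.0)
        assert table.grid[-1] == pytest.approx(10.0)
        assert table.n_subjects == 100


@pytest.fixture(scope="module")
def ref_table(truth_weight_curves_500):
    return build_reference(truth_weight_curves_500[:100],
                           axis="chronological", sex="F")


class TestSDS:
    def test_median_scores_zero(self, ref_table):
        m = ref_table.median_at(10.0, "total")
        assert sds(m**2, 10.0, ref_table, "total") == pytest.approx(0.0,
                                                                    abs=1e-12)

    def test_two_sd_scores_two(self, ref_table):
        x = ref_table.median_at(10.0, "total") + 2 * ref_table.sd_at(10.0,
                                                                     "total")
        assert sds(x**2, 10.0, ref_table, "total") == pytest.approx(2.0)

    def test_round_trip(self, ref_table):
        rng = np.random.default_rng(0)
        n_ok = 0
        for _ in range(100):
            z = rng.uniform(-3, 3)
            age = rng.uniform(4.0, 20.0)
            comp = rng.choice(["total", "basic", "p_specific"])
            try:
                v = value_at_sds(z, age, ref_table, comp)
            except ValidationError:
                # low scores of a near-zero component have no kg preimage
                continue
            assert sds(v, age, ref_table, comp) == pytest.approx(z, abs=1e-9)
            n_ok += 1
        assert n_ok >= 70

    def test_out_of_range_errors(self, ref_table):
        with pytest.raises(OutOfReferenceRangeError):
            sds(30.0, 25.0, ref_table, "total")
        with pytest.raises(OutOfReferenceRangeError):
            sds(30.0, 2.0, ref_table, "total")


class TestAssessIndividual:
    @pytest.fixture()
    def aligned_tables(self, truth_weight_curves_500):
        w = build_reference(truth_weight_curves_500[:100],
                            axis="puberty_aligned", sex="F")
        return None, w

    def test_onset_measurement_maps_to_zero(self, aligned_tables):
        _, w = aligned_tables
        ms = [Measurement("kid", "F", 10.0, weight=32.0)]
        traj = assess_individual(ms, 10.0, None, w)
        assert traj.loc[0, "pubertal_age"] == 0.0
        assert traj.loc[0, "scored"]

    def test_onset_shift_moves_pubertal_age(self, aligned_tables):
        _, w = aligned_tables
        ms = [Measurement("kid", "F", 12.0, weight=40.0)]
        t1 = assess_individual(ms, 10.0, None, w).loc[0, "pubertal_age"]
        t2 = assess_individual(ms, 11.0, None, w).loc[0, "pubertal_age"]
        assert t1 - t2 == pytest.approx(1.0)

    def test_out_of_span_visits_unscored(self, aligned_tables):
        _, w = aligned_tables
        ms = [Measurement("kid", "F", 3.0, weight=15.0),
              Measurement("kid", "F", 12.0, weight=40.0)]
        traj = assess_individual(ms, 10.0, None, w)
        assert not traj.loc[0, "scored"]   # t' = -7 outside [-4, 10]
        assert traj.loc[1, "scored"]

    def test_coverage_of_population_children(self, truth_weight_curves_500):
        """Children from the generating population score mostly within ±2."""
        table = build_reference(truth_weight_curves_500,
                                axis="puberty_aligned", sex="F")
        child_ok = 0
        point_ok = point_total = 0
        children = truth_weight_curves_500[300:500]
        for curve in children:
            ages = np.array([6.0, 9.0, 11.0, 13.0, 16.0])
            sw = curve.component_values(ages)["total"]
            ms = [Measurement(curve.subject_id, "F", a, weight=float(v**2))
                  for a, v in zip(ages, sw)]
            traj = assess_individual(ms, curve.age_p5, None, table)
            scored = traj[traj.scored]
            assert len(scored) > 0
            if scored.weight_sds.abs().mean() < 2:
                child_ok += 1
            point_ok += int((scored.weight_sds.abs() < 2).sum())
            point_total += len(scored)
        assert child_ok / len(children) >= 0.95
        assert point_ok / point_total >= 0.90
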