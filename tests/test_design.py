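"""Inverse design: cost, seeding, neighborhood generation, greedy descent."""

import numpy as np
import pytest

from dropforge import physics
from dropforge.dataset import ObservationRecord
from dropforge.design import (
    ConstraintInfeasibleError,
    DesignSpec,
    accept_seed,
    cost,
    neighborhood,
    rank_seed_candidates,
    search,
)
from dropforge.physics import DesignPoint, Performance
from dropforge.synthetic import (
    SurrogateParams,
    SurrogatePredictor,
    generate_dataset,
    surrogate_truth,
)


def perf(d, f, d_inf=None, regime="dripping"):
    return Performance(regime=regime, diameter_um=d, rate_hz=f,
                       inferred_diameter_um=d_inf)


QD = physics.dispersed_rate_from(100.0, 100.0)


class TestCost:
    def test_exact_match_zero(self):
        spec = DesignSpec(desired_diameter_um=100, desired_rate_hz=100)
        assert cost(spec, perf(100, 100, d_inf=100), QD) == 0.0

    def test_hand_arithmetic(self):
        spec = DesignSpec(desired_diameter_um=100, desired_rate_hz=100)
        assert cost(spec, perf(90, 110, d_inf=95), QD) == pytest.approx(25.0)

    def test_diameter_only_mode_drops_rate_term(self):
        spec = DesignSpec(desired_diameter_um=100)
        assert cost(spec, perf(90, 110, d_inf=95), QD) == pytest.approx(15.0)

    def test_inferred_diameter_computed_when_missing(self):
        spec = DesignSpec(desired_diameter_um=100, desired_rate_hz=100)
        d_inf = physics.infer_diameter(QD, 110.0)
        expected = 10 + 10 + abs(100 - d_inf)
        assert cost(spec, perf(90, 110), QD) == pytest.approx(expected)


@pytest.fixture(scope="module")
def small_records(surrogate_params):
    return generate_dataset(20, surrogate_params, seed=11)


class TestRankSeedCandidates:
    def test_exact_performance_match_ranks_first(self, small_records):
        target = small_records[7].outcome
        spec = DesignSpec(desired_diameter_um=np.clip(target.diameter_um, 25, 250),
                          desired_rate_hz=np.clip(target.rate_hz, 5, 500))
        ranked = rank_seed_candidates(small_records, spec)
        assert ranked[0].outcome is target or (
            ranked[0].outcome.diameter_um == target.diameter_um)

    def test_matches_brute_force_sort(self, small_records):
        spec = DesignSpec(desired_diameter_um=80, desired_rate_hz=120)
        ranked = rank_seed_candidates(small_records, spec)
        # exhaustive oracle: scaled Euclidean distance in performance space
        def fitness(r):
            return np.hypot((80 - r.outcome.diameter_um) / 250.0,
                            (120 - r.outcome.rate_hz) / 500.0)
        expected = sorted(small_records, key=fitness)
        assert [r.outcome.diameter_um for r in ranked] == \
            [r.outcome.diameter_um for r in expected]

    def test_fixed_constraint_projects_candidates(self, small_records):
        spec = DesignSpec(desired_diameter_um=80, desired_rate_hz=120,
                          constraints={"aspect_ratio": 1.0})
        for r in rank_seed_candidates(small_records, spec):
            assert r.design.geometry.aspect_ratio == 1.0

    def test_interval_constraint_filters(self, small_records):
        spec = DesignSpec(desired_diameter_um=80, desired_rate_hz=120,
                          constraints={"orifice_width_um": (75.0, 150.0)})
        ranked = rank_seed_candidates(small_records, spec)
        assert all(r.design.geometry.orifice_width_um <= 150 for r in ranked)
        assert len(ranked) < len(small_records)

    def test_all_excluded_raises(self, small_records):
        spec = DesignSpec(desired_diameter_um=80, desired_rate_hz=120,
                          constraints={"orifice_width_um": (295.0, 300.0)})
        with pytest.raises(ConstraintInfeasibleError):
            rank_seed_candidates(small_records, spec)


class TestAcceptSeed:
    def make_record_with_outcome(self, predictor, d_offset=0.0, f_offset=0.0):
        point = DesignPoint.from_vector([150, 2, 2.5, 3, 3, 2, 0.1, 10])
        truth = predictor.predict(point)
        outcome = Performance(regime=truth.regime,
                              diameter_um=truth.diameter_um + d_offset,
                              rate_hz=truth.rate_hz + f_offset)
        return ObservationRecord(design=point, outcome=outcome), truth

    def test_zero_deviation_accepted(self, surrogate_predictor):
        record, truth = self.make_record_with_outcome(surrogate_predictor)
        spec = DesignSpec(desired_diameter_um=truth.diameter_um,
                          desired_rate_hz=np.clip(truth.rate_hz, 5, 500))
        assert accept_seed(spec, record, surrogate_predictor)

    def test_boundary_deviation_inclusive(self, surrogate_params):
        predictor = SurrogatePredictor(surrogate_params,
                                       diameter_tolerance_um=5.0,
                                       rate_tolerance_hz=1000.0)
        record, truth = self.make_record_with_outcome(predictor)
        spec = DesignSpec(desired_diameter_um=truth.diameter_um + 5.0,
                          desired_rate_hz=np.clip(truth.rate_hz, 5, 500))
        assert accept_seed(spec, record, predictor)

    def test_double_tolerance_rejected(self, surrogate_params):
        predictor = SurrogatePredictor(surrogate_params,
                                       diameter_tolerance_um=5.0,
                                       rate_tolerance_hz=1000.0)
        record, truth = self.make_record_with_outcome(predictor)
        spec = DesignSpec(desired_diameter_um=truth.diameter_um + 10.0,
                          desired_rate_hz=np.clip(truth.rate_hz, 5, 500))
        assert not accept_seed(spec, record, predictor)


class TestNeighborhood:
    BOUNDS = np.array([[75, 300], [1, 3], [1, 4], [2, 4], [1, 4], [1, 4],
                       [0.02, 0.8], [2, 40.0]], dtype=float)

    def test_interior_point_yields_sixteen(self, nominal_design):
        candidates = neighborhood(nominal_design, 0.05, self.BOUNDS)
        assert len(candidates) == 16

    def test_fixed_parameter_yields_fourteen(self, nominal_design):
        candidates = neighborhood(nominal_design, 0.05, self.BOUNDS,
                                  constraints={"aspect_ratio": 2.0})
        assert len(candidates) == 14
        assert all(c.geometry.aspect_ratio == 2.0 for c in candidates)

    def test_boundary_point_drops_clipped_duplicates(self):
        # enumeration oracle: a point at the orifice lower bound loses the
        # downward orifice candidate (it clips onto the point itself)
        at_bound = DesignPoint.from_vector([75, 2, 2.5, 3, 3, 2, 0.1, 10])
        candidates = neighborhood(at_bound, 0.05, self.BOUNDS)
        assert len(candidates) == 15
        assert all(c.geometry.orifice_width_um >= 75 for c in candidates)

    def test_nonpositive_step_rejected(self, nominal_design):
        with pytest.raises(ValueError):
            neighborhood(nominal_design, 0.0, self.BOUNDS)


class TestSearch:
    def test_spec_matching_record_is_seed_accepted(self, surrogate_params):
        predictor = SurrogatePredictor(surrogate_params,
                                       diameter_tolerance_um=10.0,
                                       rate_tolerance_hz=50.0)
        records = generate_dataset(200, surrogate_params, seed=2)
        record = next(r for r in records
                      if 25 <= r.outcome.diameter_um <= 250
                      and 5 <= r.outcome.rate_hz <= 500)
        spec = DesignSpec(desired_diameter_um=record.outcome.diameter_um,
                          desired_rate_hz=record.outcome.rate_hz)
        result = search(predictor, spec, records)
        assert result.status == "seed-accepted"
        assert result.iterations == 0

    def test_three_by_three_grid_meets_error_targets(
            self, surrogate_predictor, surrogate_params, records600):
        # surrogate truth is the oracle for the delivered performance
        for desired_d in (50, 100, 150):
            for desired_f in (50, 150, 300):
                spec = DesignSpec(desired_diameter_um=desired_d,
                                  desired_rate_hz=desired_f)
                result = search(surrogate_predictor, spec, records600)
                truth = surrogate_truth(result.design, surrogate_params)
                assert abs(truth.diameter_um - desired_d) / desired_d <= 0.05
                assert abs(truth.rate_hz - desired_f) / desired_f <= 0.15

    def test_cost_trace_non_increasing(self, surrogate_predictor, records600):
        for desired_d, desired_f in ((60, 80), (120, 200), (200, 40)):
            spec = DesignSpec(desired_diameter_um=desired_d,
                              desired_rate_hz=desired_f)
            result = search(surrogate_predictor, spec, records600)
            trace = result.cost_trace
            assert all(a >= b - 1e-12 for a, b in zip(trace, trace[1:]))

    def test_constraints_respected_in_final_design(self, surrogate_predictor,
                                                   records600):
        spec = DesignSpec(
            desired_diameter_um=60, desired_rate_hz=150,
            constraints={"aspect_ratio": 1.0,
                         "water_inlet_ratio": 2.0,
                         "orifice_width_um": (75.0, 200.0)})
        result = search(surrogate_predictor, spec, records600)
        g = result.design.geometry
        assert g.aspect_ratio == 1.0
        assert g.water_inlet_ratio == 2.0
        assert 75.0 <= g.orifice_width_um <= 200.0

    def test_deterministic(self, surrogate_predictor, records600):
        spec = DesignSpec(desired_diameter_um=80, desired_rate_hz=120)
        a = search(surrogate_predictor, spec, records600)
        b = search(surrogate_predictor, spec, records600)
        assert a.design.to_vector() == b.design.to_vector()
        assert a.cost_trace == b.cost_trace

    def test_diameter_only_mode(self, surrogate_predictor, records600,
                                surrogate_params):
        spec = DesignSpec(desired_diameter_um=90)
        result = search(surrogate_predictor, spec, records600)
        truth = surrogate_truth(result.design, surrogate_params)
        assert abs(truth.diameter_um - 90) / 90 <= 0.05

    def test_result_serializes_to_json(self, surrogate_predictor, records600):
        import json
        spec = DesignSpec(desired_diameter_um=80, desired_rate_hz=120)
        result = search(surrogate_predictor, spec, records600)
        payload = json.loads(result.to_json())
        assert set(payload) >= {"design_parameters", "continuous_rate_ml_h",
                                "dispersed_rate_ul_min", "predicted", "status"}
        assert payload["dispersed_rate_ul_min"] > 0


class TestRedundancyTerm:
    def test_inconsistent_rate_regressor_raises_cost(self, surrogate_params):
        """A corrupted rate prediction inflates the inferred-diameter term."""
        class CorruptedRate(SurrogatePredictor):
            def predict(self, design):
                clean = super().predict(design)
                broken_rate = clean.rate_hz * 8.0
                q_d = physics.dispersed_rate_from(clean.diameter_um,
                                                  clean.rate_hz)
                return Performance(
                    regime=clean.regime, diameter_um=clean.diameter_um,
                    rate_hz=broken_rate,
                    inferred_diameter_um=physics.infer_diameter(q_d,
                                                                broken_rate))

        clean = SurrogatePredictor(surrogate_params)
        broken = CorruptedRate(surrogate_params)
        point = DesignPoint.from_vector([150, 2, 2.5, 3, 3, 2, 0.1, 10])
        truth = clean.predict(point)
        spec = DesignSpec(desired_diameter_um=np.clip(truth.diameter_um, 25, 250))
        q_d = physics.dispersed_rate_from(truth.diameter_um, truth.rate_hz)
        assert cost(spec, broken.predict(point), q_d) > \
            cost(spec, clean.predict(point), q_d) + 1.0
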