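"""Immune optimizer: detector operators, schedules, optimization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glioseg import immune, network, phantom
from glioseg.immune import (
    Detector,
    Population,
    affinity,
    cbest,
    clonal_selection,
    clone_count,
    concentration_decay,
    expose_antigens,
    f_match,
    immune_mutation,
    inertial_weight,
    optimize,
    position_update,
    promote_and_reinforce,
    tolerance_step,
    tune_decision_layer,
)


def bits(s: str) -> np.ndarray:
    return np.array([int(c) for c in s], dtype=np.uint8)


class TestAffinity:
    def test_identical_strings(self):
        assert affinity(bits("1010"), bits("1010")) == 1.0

    def test_complement_strings(self):
        assert affinity(bits("1010"), bits("0101")) == 0.0

    def test_three_of_four(self):
        assert affinity(bits("1010"), bits("1011")) == 0.75

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            affinity(bits("10"), bits("101"))


class TestFMatch:
    def test_full_match_above_threshold(self):
        assert f_match(bits("11"), bits("11"), 0.5) == 1

    def test_boundary_is_strict(self):
        # affinity exactly equal to gamma does not match
        assert f_match(bits("1010"), bits("1011"), 0.75) == 0

    def test_above_gamma(self):
        assert f_match(bits("1011"), bits("1010"), 0.7) == 1


class TestToleranceStep:
    def test_self_matching_immature_deleted(self):
        pop = Population(gamma=0.5, alpha=3)
        pop.immature = [Detector(bits("1111"))]
        pop.self_set = [bits("1110")]  # affinity 0.75 > 0.5
        pop = tolerance_step(pop)
        assert pop.immature == [] and pop.mature == []

    def test_empty_self_set_increments_all(self):
        pop = Population(alpha=5)
        pop.immature = [Detector(bits("1010")), Detector(bits("0101"))]
        pop = tolerance_step(pop)
        assert [d.t for d in pop.immature] == [1, 1]

    def test_graduation_at_alpha(self):
        pop = Population(alpha=3)
        d = Detector(bits("1010"), t=2)
        pop.immature = [d]
        pop = tolerance_step(pop)
        assert pop.immature == [] and pop.mature == [d]
        assert d.t == 3

    def test_no_surviving_detector_matches_self(self):
        rng = np.random.default_rng(0)
        pop = Population(gamma=0.6, alpha=1)
        pop.self_set = [rng.integers(0, 2, 8).astype(np.uint8)
                        for _ in range(4)]
        pop.immature = [Detector(rng.integers(0, 2, 8)) for _ in range(50)]
        pop = tolerance_step(pop)
        for d in pop.mature + pop.immature:
            assert all(f_match(s, d, pop.gamma) == 0 for s in pop.self_set)


class TestCloneCount:
    def test_worst_rank_gets_none(self):
        assert clone_count(10, 10, 5.0) == 0

    def test_best_rank_gets_xi(self):
        assert clone_count(0, 10, 5.0) == 5

    def test_interpolates(self):
        assert clone_count(3, 10, 10.0) == 7

    def test_invalid_rank_raises(self):
        with pytest.raises(ValueError):
            clone_count(5, 4, 1.0)


class TestClonalSelection:
    def test_zero_xi_is_identity(self):
        pop = Population(xi=0.0)
        d = Detector(bits("1010"))
        pop.mature = [d]
        pop, clones = clonal_selection(pop, [bits("1010")])
        assert pop.mature == [d] and clones == []

    def test_single_mature_cloned_and_parent_removed(self):
        pop = Population(xi=2.0)
        parent = Detector(bits("1100"))
        pop.mature = [parent]
        pop, clones = clonal_selection(pop, [bits("1100")])
        assert len(clones) == 2
        assert parent not in pop.mature
        assert len(pop.mature) == 2

    def test_sets_stay_disjoint(self):
        rng = np.random.default_rng(1)
        pop = Population(xi=3.0)
        pop.mature = [Detector(rng.integers(0, 2, 6)) for _ in range(5)]
        pop.memory = [Detector(rng.integers(0, 2, 6)) for _ in range(3)]
        pop, _ = clonal_selection(pop, [rng.integers(0, 2, 6)])
        pop.check_invariants()


class TestImmuneMutation:
    def test_identical_detector_unchanged(self):
        rng = np.random.default_rng(0)
        d = Detector(bits("1010"))
        out = immune_mutation(d, bits("1010"), rng, p_mut=1.0)
        assert np.array_equal(out.ab, d.ab)

    def test_full_rate_converges_to_antigen(self):
        rng = np.random.default_rng(0)
        out = immune_mutation(Detector(bits("0000")), bits("1011"), rng, 1.0)
        assert np.array_equal(out.ab, bits("1011"))

    def test_zero_rate_is_identity(self):
        rng = np.random.default_rng(0)
        out = immune_mutation(Detector(bits("0000")), bits("1111"), rng, 0.0)
        assert np.array_equal(out.ab, bits("0000"))

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**10 - 1), st.integers(0, 2**10 - 1),
           st.integers(0, 1000))
    def test_matched_bits_never_change(self, a, g, seed):
        ab = np.array([(a >> i) & 1 for i in range(10)], dtype=np.uint8)
        ag = np.array([(g >> i) & 1 for i in range(10)], dtype=np.uint8)
        rng = np.random.default_rng(seed)
        out = immune_mutation(Detector(ab), ag, rng, p_mut=0.5)
        matched = ab == ag
        assert np.array_equal(out.ab[matched], ab[matched])


class TestPromotionAndDecay:
    def test_cnt_at_threshold_stays_mature(self):
        pop = Population(beta_act=5)
        d = Detector(bits("1"), cnt=5)
        pop.mature = [d]
        pop = promote_and_reinforce(pop)
        assert pop.mature == [d] and pop.memory == []

    def test_cnt_above_threshold_promotes_with_reset(self):
        pop = Population(beta_act=5, eta1=1.0)
        d = Detector(bits("1"), cnt=6, age=7, p=3.0)
        pop.mature = [d]
        pop = promote_and_reinforce(pop)
        assert pop.memory == [d] and pop.mature == []
        assert d.p == 1.0 and d.age == 0

    def test_rematched_memory_reinforced(self):
        pop = Population(eta1=1.0, eta2=0.5, gamma=0.5)
        d = Detector(bits("1111"), p=2.0, age=4)
        pop.memory = [d]
        pop.nonself_set = [bits("1111")]
        pop = promote_and_reinforce(pop)
        assert d.p == pytest.approx(1.0 + 0.5 * 2.0)
        assert d.age == 0

    def test_decay_formula(self):
        d = Detector(bits("1"), p=10.0, age=1)
        concentration_decay(d, theta_decay=5)
        assert d.p == pytest.approx(10.0 * (1 - 1 / 4))
        assert d.age == 2

    def test_decay_kills_at_horizon(self):
        d = Detector(bits("1"), p=10.0, age=4)
        concentration_decay(d, theta_decay=5)
        assert d.p == 0.0

    def test_expose_increments_matchers_only(self):
        pop = Population(gamma=0.7)
        a = Detector(bits("1111"))
        b = Detector(bits("0000"))
        pop.mature = [a, b]
        expose_antigens(pop, [bits("1110")])
        assert a.cnt == 1 and b.cnt == 0


class TestSchedules:
    def test_inertial_weight_endpoints(self):
        assert inertial_weight(0, 50) == pytest.approx(0.9)
        assert inertial_weight(50, 50) == pytest.approx(0.1)

    def test_inertial_weight_midpoint(self):
        assert inertial_weight(25, 50) == pytest.approx(0.5)

    def test_cbest_endpoints_and_midpoint(self):
        assert cbest(0, 10) == pytest.approx(2.0)
        assert cbest(10, 10) == pytest.approx(0.0)
        assert cbest(5, 10) == pytest.approx(1.0)

    def test_both_strictly_decreasing(self):
        iw = [inertial_weight(j, 20) for j in range(21)]
        cb = [cbest(j, 20) for j in range(21)]
        assert all(b < a for a, b in zip(iw, iw[1:]))
        assert all(b < a for a, b in zip(cb, cb[1:]))

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            inertial_weight(11, 10)
        with pytest.raises(ValueError):
            cbest(-1, 10)


class TestPositionUpdate:
    def test_fixed_point_at_gbest_without_randomization(self):
        rng = np.random.default_rng(0)
        x = np.array([0.3, -0.2])
        out = position_update(x, x, 3, 10, (np.array([-1.0, -1.0]),
                                            np.array([1.0, 1.0])), 0.0, rng)
        assert np.allclose(out, x)

    def test_initial_step_is_ninety_percent_of_gap(self):
        rng = np.random.default_rng(0)
        out = position_update(np.array([0.0]), np.array([1.0]), 0, 10,
                              (np.array([-2.0]), np.array([2.0])), 0.0, rng)
        assert out[0] == pytest.approx(0.9)

    def test_output_clipped_to_bounds(self):
        rng = np.random.default_rng(1)
        lb, ub = np.array([-0.5]), np.array([0.5])
        for j in range(5):
            out = position_update(np.array([0.4]), np.array([0.5]), j, 5,
                                  (lb, ub), 5.0, rng)
            assert lb[0] <= out[0] <= ub[0]


class TestOptimize:
    def test_elitism_on_sphere(self):
        res = optimize(lambda x: float(x @ x),
                       bounds=(np.array([-1.0, -1.0]), np.array([1.0, 1.0])),
                       pop_size=50, n_iters=20, seed=0)
        assert all(b <= a + 1e-12 for a, b in zip(res.trace, res.trace[1:]))
        assert res.fun <= res.trace[0]

    def test_quadratic_recovery(self):
        hits = 0
        for s in range(20):
            res = optimize(lambda x: (x[0] - 0.3) ** 2,
                           bounds=(np.array([-1.0]), np.array([1.0])),
                           pop_size=200, n_iters=50, seed=s)
            hits += int(abs(res.x[0] - 0.3) < 0.1)
        assert hits == 20

    def test_bitstring_matches_exhaustive_optimum(self):
        weights = np.array([0, 0, 1.0, 0, 2.0, 0, 0.5, 0])

        def score(mask):
            return -(float(mask @ weights) - 0.1 * mask.sum())

        best = min(
            (np.array([(m >> i) & 1 for i in range(8)], dtype=np.uint8)
             for m in range(256)),
            key=score,
        )
        res = optimize(score, length=8, pop_size=200, clone_rate=0.04,
                       n_iters=10, seed=3)
        assert np.array_equal(res.x, best)

    def test_requires_exactly_one_encoding(self):
        with pytest.raises(ValueError):
            optimize(lambda x: 0.0)
        with pytest.raises(ValueError):
            optimize(lambda x: 0.0, bounds=(np.zeros(1), np.ones(1)),
                     length=4)


@pytest.fixture(scope="module")
def fitted():
    images, labels = [], []
    for s in range(4):
        p = phantom.generate_phantom(800 + s, 48, 48)
        images.append(p.channels.astype(float))
        labels.append(p.labels)
    cfg = network.NetConfig(seed=2, n_hidden=8)
    res = network.SpikingSegmenter(images, labels, cfg).fit()
    return res, images, labels


class TestTuneDecisionLayer:
    def test_zero_iterations_returns_untuned_model(self, fitted):
        res, images, labels = fitted
        tuned, _ = tune_decision_layer(res.model, images[:1], labels[:1],
                                       seed=0, n_iters=0)
        assert tuned is res.model

    def test_tuning_never_reduces_validation_dice(self, fitted):
        from glioseg.metrics import dice
        from glioseg.phantom import region_masks

        res, images, labels = fitted
        val_im, val_lb = images[:2], labels[:2]

        def wt_dice(m):
            vals = []
            for im, lb in zip(val_im, val_lb):
                pred = network.predict_labels(im, m)
                vals.append(dice(region_masks(pred).wt, region_masks(lb).wt))
            return float(np.mean(vals))

        before = wt_dice(res.model)
        tuned, _ = tune_decision_layer(res.model, val_im, val_lb, seed=1,
                                       pop_size=30, n_iters=4)
        assert wt_dice(tuned) >= before - 1e-12

    def test_matches_exhaustive_mask_search(self, fitted):
        from glioseg.metrics import dice
        from glioseg.phantom import region_masks

        res, images, labels = fitted
        model = res.model
        val_im, val_lb = images[:1], labels[:1]

        def mask_dice(mask):
            if not mask.any():
                return 0.0
            beta = network.resolve_with_mask(model, mask)
            H = network._hidden_for_image(val_im[0], model)
            pred = model.classes[
                np.argmax(H[:, mask] @ beta, axis=1)
            ].reshape(val_lb[0].shape)
            return dice(region_masks(pred).wt, region_masks(val_lb[0]).wt)

        exhaustive = max(
            mask_dice(np.array([(m >> i) & 1 for i in range(8)], dtype=bool))
            for m in range(1, 256)
        )
        tuned, opt = tune_decision_layer(model, val_im, val_lb, seed=4,
                                         pop_size=60, n_iters=8,
                                         offset_bound=0.0)
        assert -opt.fun >= exhaustive - 0.02

    def test_empty_validation_set_rejected(self, fitted):
        res, *_ = fitted
        with pytest.raises(ValueError):
            tune_decision_layer(res.model, [], [], seed=0)
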