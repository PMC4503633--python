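"""The nearest-neighbor entropy estimator against closed forms and oracles."""

import numpy as np
import pytest

from confent.estimators import (
    EULER_GAMMA,
    STANDARD_STATE_VOLUME_A3,
    SampleSet,
    entropy_knn,
    entropy_profile,
    entropy_to_kcal_per_mol,
    knn_distances,
    mutual_information,
    relative_to_uniform,
)
from confent.spaces import MetricSpace
from confent.synthetic import DensitySpec, numeric_entropy_oracle, sample, sample_haar_rotations

TWO_PI = 2.0 * np.pi

# conservative per-sample standard deviation bound of the k=1 estimator
# (sqrt of trigamma(1) plus the log-density variance of the densities
# used here); the oracle tests allow three such standard errors
_SD_BOUND = 3.0


def _tol(n: int) -> float:
    return 3.0 * _SD_BOUND / np.sqrt(n)


class TestKnnDistances:
    @pytest.mark.parametrize(
        "k, expected",
        [(1, [1.0, 1.0, 2.0]), (2, [3.0, 2.0, 3.0])],
    )
    def test_three_points_on_a_line(self, k, expected):
        samples = SampleSet(np.array([[0.0], [1.0], [3.0]]), MetricSpace.line())
        assert knn_distances(samples, k) == pytest.approx(expected)

    def test_wrap_around_on_the_circle(self, circle):
        samples = SampleSet(np.array([[0.1], [TWO_PI - 0.1]]), circle)
        assert knn_distances(samples, 1) == pytest.approx([0.2, 0.2])

    def test_k_at_least_sample_count_rejected(self, circle):
        samples = SampleSet(np.array([[0.0], [1.0]]), circle)
        with pytest.raises(ValueError):
            knn_distances(samples, 2)

    def test_brute_force_matches_tree_path(self, rng):
        pts = rng.normal(size=(200, 3))
        euclid = MetricSpace.euclidean(3)
        tree = knn_distances(SampleSet(pts, euclid), 3)
        from confent.spaces import pairwise_distances

        mat = pairwise_distances(euclid, pts)
        np.fill_diagonal(mat, np.inf)
        brute = np.sort(mat, axis=1)[:, 2]
        assert tree == pytest.approx(brute)


class TestEntropyKnn:
    def test_two_point_closed_form(self):
        est = entropy_knn(SampleSet(np.array([[0.0], [1.0]]), MetricSpace.euclidean(1)))
        assert est.value == pytest.approx(np.log(4.0) + EULER_GAMMA)
        assert est.mean_nn_distance == pytest.approx(1.0)

    def test_uniform_circle_recovers_log_two_pi(self):
        samples = sample(DensitySpec("uniform_torus", periods=(TWO_PI,)), 10_000, seed=1)
        assert entropy_knn(samples).value == pytest.approx(np.log(TWO_PI), abs=0.05)

    def test_uniform_rotations_recover_log_four_pi_squared(self, rotation_space):
        samples = SampleSet(sample_haar_rotations(10_000, seed=2), rotation_space)
        assert entropy_knn(samples).value == pytest.approx(np.log(4 * np.pi**2), abs=0.05)

    def test_duplicates_dropped_with_warning(self, circle):
        pts = np.array([[0.0], [0.0], [1.0], [2.0], [2.0], [2.0]])
        est = entropy_knn(SampleSet(pts, circle))
        assert est.n == 3
        assert any("duplicate" in w for w in est.warnings)

    def test_too_few_distinct_samples_rejected(self, circle):
        with pytest.raises(ValueError):
            entropy_knn(SampleSet(np.zeros((5, 1)), circle))

    def test_wide_neighbor_distances_flag_uncorrected_volume(self, torus2):
        # antipodal pair: NN distance pi * sqrt(2) beyond half-periodicity
        pts = np.array([[0.0, 0.0], [np.pi, np.pi]])
        est = entropy_knn(SampleSet(pts, torus2))
        assert "uncorrected-volume" in est.warnings

    def test_shift_invariance_on_torus(self, torus2, rng):
        pts = rng.vonmises(0.0, 2.0, size=(400, 2))
        base = entropy_knn(SampleSet(pts, torus2)).value
        shifted = entropy_knn(SampleSet(pts + 2.5, torus2)).value
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_left_rotation_invariance(self, rotation_space, rng):
        from scipy.spatial.transform import Rotation

        mats = Rotation.from_rotvec(rng.normal(0, 0.2, size=(400, 3))).as_matrix()
        fixed = Rotation.from_rotvec([0.4, -1.0, 0.7]).as_matrix()
        rotated = np.einsum("ij,njk->nik", fixed, mats)
        a = entropy_knn(SampleSet(mats, rotation_space)).value
        b = entropy_knn(SampleSet(rotated, rotation_space)).value
        assert b == pytest.approx(a, abs=1e-7)

    @pytest.mark.parametrize(
        "spec",
        [
            DensitySpec("vonmises", kappa=(1.0,)),
            DensitySpec(
                "vonmises_mixture",
                weights=(1 / 3, 1 / 3, 1 / 3),
                mu=(-2.0, 0.0, 2.0),
                kappa=(40.0, 40.0, 40.0),
            ),
            DensitySpec("gaussian", sigma=(0.5,), dims=2),
            DensitySpec("capped_rotation", theta_max=np.pi / 2),
            DensitySpec("haar_rotation"),
        ],
        ids=["vonmises", "rotamer-mixture", "gaussian-2d", "capped-rotation", "haar"],
    )
    def test_oracle_equivalence_at_ten_thousand_samples(self, spec):
        n = 10_000
        est = entropy_knn(sample(spec, n, seed=11))
        assert est.value == pytest.approx(numeric_entropy_oracle(spec), abs=_tol(n))

    def test_consistency_error_shrinks_with_sample_size(self):
        spec = DensitySpec("uniform_torus", periods=(TWO_PI,))
        truth = np.log(TWO_PI)
        errors = {}
        for n in (100, 1000, 10_000):
            reps = [abs(entropy_knn(sample(spec, n, seed=s)).value - truth) for s in range(4)]
            errors[n] = np.mean(reps)
        assert errors[100] > errors[1000] > errors[10_000]


class TestEntropyProfile:
    def test_mean_distance_nondecreasing_in_k(self, rng):
        pts = rng.normal(0.0, 0.3, size=(300, 2))
        profile = entropy_profile(SampleSet(pts, MetricSpace.euclidean(2)), k_max=8)
        dists = [p[0] for p in profile]
        assert np.all(np.diff(dists) >= 0)

    def test_uniform_profile_flat_at_reference(self):
        samples = sample(DensitySpec("uniform_torus", periods=(TWO_PI, TWO_PI)), 3000, seed=3)
        profile = entropy_profile(samples, k_max=5)
        for _, value in profile:
            assert value == pytest.approx(2 * np.log(TWO_PI), abs=0.1)

    def test_multimodal_entropy_rises_with_smoothing(self):
        # three tight rotamers: small k resolves the modes, large k blurs
        # them toward the broader envelope (the resolution-loss trend)
        spec = DensitySpec(
            "vonmises_mixture",
            weights=(1 / 3, 1 / 3, 1 / 3),
            mu=(-2.0, 0.0, 2.0),
            kappa=(300.0, 300.0, 300.0),
        )
        profile = entropy_profile(sample(spec, 400, seed=4), k_max=250)
        values = np.array([v for _, v in profile])
        assert values[-1] > values[0] + 0.5
        # nondecreasing within noise: regression over k is positive
        assert np.polyfit(np.arange(len(values)), values, 1)[0] > 0

    def test_k_max_bounds_checked(self, circle):
        samples = SampleSet(np.linspace(0, 3, 10)[:, None], circle)
        with pytest.raises(ValueError):
            entropy_profile(samples, k_max=10)


class TestReferenceSubtraction:
    def test_reference_constants(self, torus2, rotation_space):
        dummy = entropy_knn(SampleSet(np.array([[0.0], [1.0]]), MetricSpace.euclidean(1)))
        t = relative_to_uniform(dummy, torus2)
        assert t.reference == pytest.approx(2 * np.log(TWO_PI))
        r = relative_to_uniform(dummy, rotation_space)
        assert r.reference == pytest.approx(np.log(4 * np.pi**2))
        e = relative_to_uniform(dummy, MetricSpace.euclidean(3))
        assert e.reference == pytest.approx(np.log(STANDARD_STATE_VOLUME_A3))
        assert e.reference == pytest.approx(np.log(1660), abs=1e-3)

    def test_line_requires_caller_reference(self):
        dummy = entropy_knn(SampleSet(np.array([[0.0], [1.0]]), MetricSpace.line()))
        with pytest.raises(ValueError):
            relative_to_uniform(dummy, MetricSpace.line())
        rel = relative_to_uniform(dummy, MetricSpace.line(), reference_volume=2.0)
        assert rel.reference == pytest.approx(np.log(2.0))

    def test_double_subtraction_rejected(self, torus2):
        dummy = entropy_knn(SampleSet(np.array([[0.0], [1.0]]), MetricSpace.euclidean(1)))
        rel = relative_to_uniform(dummy, torus2)
        with pytest.raises(ValueError):
            relative_to_uniform(rel, torus2)

    @pytest.mark.parametrize(
        "spec, space",
        [
            (DensitySpec("uniform_torus", periods=(TWO_PI, TWO_PI)), MetricSpace.torus([TWO_PI] * 2)),
            (DensitySpec("haar_rotation"), MetricSpace.rotation()),
        ],
        ids=["torus", "rotation"],
    )
    def test_uniform_samples_have_zero_relative_entropy(self, spec, space):
        est = entropy_knn(sample(spec, 4000, seed=5))
        rel = relative_to_uniform(est, space)
        assert rel.value == pytest.approx(0.0, abs=_tol(4000))


class TestMutualInformation:
    def test_independent_angles_give_zero(self, circle):
        a = sample(DensitySpec("vonmises", kappa=(0.0,)), 5000, seed=6)
        b = sample(DensitySpec("vonmises", kappa=(0.0,)), 5000, seed=7)
        assert mutual_information(a, b) == pytest.approx(0.0, abs=0.05)

    def test_correlated_gaussian_matches_closed_form(self):
        rho = 0.9
        rng = np.random.default_rng(8)
        xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=5000)
        line = MetricSpace.euclidean(1)
        mi = mutual_information(SampleSet(xy[:, :1], line), SampleSet(xy[:, 1:], line))
        assert mi == pytest.approx(-0.5 * np.log(1 - rho**2), abs=0.1)

    def test_identical_samples_degenerate_but_flagged(self, rng):
        pts = rng.normal(size=(500, 1))
        line = MetricSpace.euclidean(1)
        mi = mutual_information(SampleSet(pts, line), SampleSet(pts.copy(), line))
        assert mi > 2.0  # near-deterministic dependence

    def test_noise_floor_for_independent_samples(self):
        for seed in range(3):
            a = sample(DensitySpec("gaussian", sigma=(1.0,), dims=1), 2000, seed=seed)
            b = sample(DensitySpec("gaussian", sigma=(1.0,), dims=1), 2000, seed=seed + 50)
            assert mutual_information(a, b) >= -0.1

    def test_length_mismatch_rejected(self, circle):
        a = sample(DensitySpec("vonmises", kappa=(1.0,)), 100, seed=0)
        b = sample(DensitySpec("vonmises", kappa=(1.0,)), 99, seed=0)
        with pytest.raises(ValueError):
            mutual_information(a, b)


def test_kcal_conversion_at_room_temperature():
    # 1 kB at 300 K is 0.596 kcal/mol
    assert entropy_to_kcal_per_mol(-1.0, 300.0) == pytest.approx(0.596, abs=1e-3)
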