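import numpy as np
import pytest

from spiralshape.io_formats import LandmarkConfiguration
from spiralshape.shape_core import (
    bending_energy,
    bending_energy_matrix,
    gpa,
    mirror,
    necklace_slide,
    procrustes_distance,
    resample_equidistant,
    species_mean,
)
from spiralshape.synthetic import SpiralParams, generate_cochlea


def _config(points, **kw):
    defaults = dict(specimen_id="s", species_id="sp", side="right")
    defaults.update(kw)
    return LandmarkConfiguration(points=np.asarray(points, float), **defaults)


def _random_rotation(rng):
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


class TestResample:
    def test_straight_segment_equal_spacing(self):
        cfg = _config([[0, 0, 0], [5, 0, 0], [10, 0, 0]])
        out = resample_equidistant(cfg, m=4)
        np.testing.assert_allclose(out.points[:, 0], [0, 2, 4, 6, 8, 10])
        assert out.fixed_index_set == frozenset({0, 5})
        assert len(out.semi_index_set) == 4

    def test_default_yields_67_semilandmarks(self, cochlea):
        out = resample_equidistant(cochlea)
        assert len(out.semi_index_set) == 67
        assert len(out.fixed_index_set) == 3
        assert out.k == 70

    def test_dense_circle_equal_chords(self):
        th = np.linspace(0, 1.5 * np.pi, 2000)
        pts = np.column_stack([np.cos(th), np.sin(th), np.zeros_like(th)])
        out = resample_equidistant(_config(pts), m=20)
        d = np.linalg.norm(np.diff(out.points, axis=0), axis=1)
        assert d.max() - d.min() < 1e-6

    def test_degenerate_curve_rejected(self):
        cfg = _config(np.zeros((5, 3)) + [[1, 2, 3]] * 5)
        with pytest.raises(ValueError, match="degenerate|zero-length"):
            resample_equidistant(cfg, m=4)


class TestMirror:
    def test_involution(self, cochlea):
        back = mirror(mirror(cochlea))
        np.testing.assert_array_equal(back.points, cochlea.points)
        assert back.side == cochlea.side

    def test_chirality_is_a_true_shape_difference(self):
        """A chiral helix and its mirror are NOT superimposable by
        rotation-only Procrustes."""
        cfg = generate_cochlea(SpiralParams(n_turns=2.5, n_points=80, seed=2))
        d = procrustes_distance(cfg.points, mirror(cfg).points)
        assert d > 0.05


class TestGPA:
    def test_identical_copies_align_perfectly(self, rng):
        pts = rng.normal(size=(10, 3))
        sample = gpa([_config(pts, specimen_id=f"s{i}") for i in range(4)])
        for c in sample.configurations:
            assert np.linalg.norm(c.points - sample.mean_shape) < 1e-10

    def test_similarity_invariance(self, rng):
        pts = rng.normal(size=(15, 3))
        for _ in range(5):
            R = _random_rotation(rng)
            s = rng.uniform(0.1, 10)
            t = rng.normal(size=3)
            other = s * pts @ R.T + t
            sample = gpa([_config(pts), _config(other, specimen_id="b")])
            d = np.linalg.norm(sample.configurations[0].points
                               - sample.configurations[1].points)
            assert d < 1e-10

    def test_two_config_rotation_matches_orthogonal_procrustes(self, rng):
        """Rotation aligning one centered/scaled shape onto another equals
        the closed-form SVD solution computed independently."""
        A = rng.normal(size=(8, 3))
        B = rng.normal(size=(8, 3))
        sample = gpa([_config(A), _config(B, specimen_id="b")])
        # independent oracle: direct orthogonal Procrustes of the two
        # unit-size shapes onto each other
        An = (A - A.mean(0)) / np.linalg.norm(A - A.mean(0))
        Bn = (B - B.mean(0)) / np.linalg.norm(B - B.mean(0))
        U, _, Vt = np.linalg.svd(Bn.T @ An)
        D = np.diag([1, 1, np.sign(np.linalg.det(U @ Vt))])
        R = U @ D @ Vt
        oracle = np.linalg.norm(Bn @ R - An)
        aligned = np.linalg.norm(sample.configurations[1].points
                                 - sample.configurations[0].points)
        assert aligned == pytest.approx(oracle, abs=1e-8)

    def test_unit_centroid_size_contract(self, rng):
        sample = gpa([_config(rng.normal(size=(9, 3)), specimen_id=f"{i}")
                      for i in range(3)])
        for c in sample.configurations:
            assert np.linalg.norm(c.points) == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(c.points.mean(axis=0), 0.0, atol=1e-9)

    def test_mismatched_k_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            gpa([_config(rng.normal(size=(5, 3))),
                 _config(rng.normal(size=(6, 3)))])


class TestBendingEnergy:
    def test_affine_null_space(self, rng):
        ref = rng.normal(size=(20, 3))
        bem = bending_energy_matrix(ref)
        assert np.abs(bem.B @ np.ones(20)).max() < 1e-8
        assert np.abs(bem.B @ ref).max() < 1e-8

    def test_positive_semidefinite(self, rng):
        bem = bending_energy_matrix(rng.normal(size=(15, 3)))
        w = np.linalg.eigvalsh(bem.B)
        assert w.min() > -1e-10

    def test_energy_matches_independent_dense_solve(self, rng):
        ref = rng.normal(size=(12, 3))
        T = rng.normal(size=(12, 3))
        bem = bending_energy_matrix(ref)
        e = bending_energy(bem, T)
        # independent path: solve the full TPS system for the spline
        # coefficients and evaluate W^T K W per coordinate
        k = 12
        dist = np.sqrt(((ref[:, None] - ref[None, :]) ** 2).sum(2))
        K = -dist
        Q = np.hstack([np.ones((k, 1)), ref])
        L = np.zeros((k + 4, k + 4))
        L[:k, :k] = K
        L[:k, k:] = Q
        L[k:, :k] = Q.T
        e_dense = 0.0
        for d in range(3):
            sol = np.linalg.solve(L, np.r_[T[:, d], np.zeros(4)])
            e_dense += sol[:k] @ K @ sol[:k]
        assert e == pytest.approx(e_dense, rel=1e-8)

    def test_invariance_under_affine_offsets_of_reference(self, rng):
        """Adding any affine function of the reference to the target costs
        no bending energy; rigid motions of the target cost none either."""
        ref = rng.normal(size=(14, 3))
        T = rng.normal(size=(14, 3))
        bem = bending_energy_matrix(ref)
        e = bending_energy(bem, T)
        Q = np.hstack([np.ones((14, 1)), ref])
        C = rng.normal(size=(4, 3))
        assert bending_energy(bem, T + Q @ C) == pytest.approx(e, rel=1e-8)
        R = _random_rotation(rng)
        assert bending_energy(bem, T @ R + rng.normal(size=3)) == \
            pytest.approx(e, rel=1e-8)

    def test_coincident_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        with pytest.raises(ValueError, match="[Cc]oincident"):
            bending_energy_matrix(pts)

    def test_collinear_reference_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            bending_energy_matrix(pts)


def _slide_sample(n=5, turns=(1.6, 3.8), n_points=160, m=30, seed=0,
                  noise=0.0):
    rng = np.random.default_rng(seed)
    configs = []
    for i in range(n):
        p = SpiralParams(
            n_turns=float(rng.uniform(*turns)),
            taper=float(rng.uniform(0.02, 0.2)),
            pitch=float(rng.uniform(0.05, 0.12)),
            n_points=n_points, noise_sd=noise,
            seed=int(rng.integers(2**31 - 1)),
        )
        cfg = generate_cochlea(p)
        cfg.specimen_id = f"s{i}"
        cfg.species_id = f"sp{i}"
        configs.append(resample_equidistant(cfg, m=m))
    return gpa(configs)


class TestNecklaceSlide:
    def test_loop_freedom_and_energy_descent(self):
        sample = _slide_sample(n=6, m=25)
        mean0 = sample.mean_shape
        bem0 = bending_energy_matrix(mean0)
        start_energy = [
            bending_energy(bem0, c.points) for c in sample.configurations
        ]
        slid, states = necklace_slide(sample, max_outer=3)
        assert slid.alignment_log["loop_violations"] == 0
        for st, e0 in zip(states, start_energy):
            assert np.all(np.diff(st.params) > 0)  # strictly increasing
            # first-iteration energy (same reference) must not exceed start
            assert st.energy_trace[0] <= e0 + 1e-12

    def test_specimen_identical_to_mean_is_a_fixed_point(self):
        cfg = resample_equidistant(
            generate_cochlea(SpiralParams(n_turns=2.0, n_points=150, seed=5)),
            m=20,
        )
        sample = gpa([cfg])
        slid, states = necklace_slide(sample, max_outer=2)
        # single specimen: it IS the mean; energy of the deformation is 0
        assert states[0].energy_trace[0] == pytest.approx(0.0, abs=1e-9)

    def test_missing_source_curve_rejected(self, rng):
        cfg = LandmarkConfiguration("a", "a", "right", rng.normal(size=(8, 3)))
        sample = gpa([cfg])
        with pytest.raises(ValueError, match="source_curve"):
            necklace_slide(sample)

    def test_matches_exhaustive_coordinate_grid_search(self):
        """On a 6-semi-landmark toy, slid parameters agree with a brute
        force cyclic grid search (200 steps per parameter) within one
        grid step."""
        from spiralshape.shape_core import (
            _cumulative_arclength,
            _interp_on_curve,
            _slide_one,
            _initial_state,
        )

        cfg = resample_equidistant(
            generate_cochlea(SpiralParams(n_turns=1.8, taper=0.15,
                                          n_points=120, seed=11)),
            m=6,
        )
        sample = gpa([cfg])
        mean = sample.mean_shape
        # perturb the reference so sliding has a nontrivial optimum
        rng = np.random.default_rng(1)
        ref = mean + 0.03 * rng.normal(size=mean.shape)
        bem = bending_energy_matrix(ref)

        curve = cfg.source_curve
        s_cum = _cumulative_arclength(curve)
        total = s_cum[-1]

        # our optimizer
        st = _initial_state(cfg)
        for _ in range(8):
            _slide_one(cfg, st, bem, gap=1e-6 * total, xtol=1e-6 * total)
        ours = st.params.copy()

        # oracle: cyclic per-parameter grid search to convergence
        st2 = _initial_state(cfg)
        params = st2.params.copy()
        free = [i for i in range(cfg.k) if not st2.fixed_mask[i]]

        def energy_of(par):
            X = _interp_on_curve(curve, s_cum, par)
            return bending_energy(bem, X)

        grid_step = None
        for _ in range(40):
            moved = False
            for i in free:
                lo, hi = params[i - 1], params[i + 1]
                grid = np.linspace(lo, hi, 202)[1:-1]
                grid_step = grid[1] - grid[0]
                best, best_e = params[i], energy_of(params)
                for g in grid:
                    trial = params.copy()
                    trial[i] = g
                    e = energy_of(trial)
                    if e < best_e - 1e-15:
                        best, best_e = g, e
                if abs(best - params[i]) > 1e-12:
                    params[i] = best
                    moved = True
            if not moved:
                break

        for i in free:
            assert abs(ours[i] - params[i]) <= 1.5 * grid_step


class TestSpeciesMean:
    def test_single_specimen_passthrough(self, rng):
        pts = rng.normal(size=(8, 3))
        sample = gpa([_config(pts, specimen_id="a", species_id="spA")])
        out = species_mean(sample)
        assert out.n == 1
        d = procrustes_distance(out.configurations[0].points,
                                sample.configurations[0].points)
        assert d < 1e-10

    def test_mean_is_coordinatewise_average(self, rng):
        base = rng.normal(size=(10, 3))
        other = base + 0.05 * rng.normal(size=(10, 3))
        sample = gpa([
            _config(base, specimen_id="a", species_id="sp"),
            _config(other, specimen_id="b", species_id="sp"),
        ])
        expected = np.mean(
            [c.points for c in sample.configurations], axis=0)
        out = species_mean(sample)
        d = procrustes_distance(out.configurations[0].points, expected)
        assert d < 1e-9

    def test_unmapped_specimen_rejected(self, rng):
        sample = gpa([_config(rng.normal(size=(6, 3)), specimen_id="a")])
        with pytest.raises(KeyError):
            species_mean(sample, species_of={"other": "sp"})
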