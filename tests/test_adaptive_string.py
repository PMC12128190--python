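"""String initialisation, reparameterization, convergence, exchange, path-CV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fepath.adaptive_string import (
    PathCV,
    StringState,
    attempt_exchange,
    check_convergence,
    init_string,
    reparameterize,
    run_string,
    string_iteration,
)
from fepath.collective_variables import wrap_degrees
from fepath.errors import DegenerateStringError
from fepath.potentials import HarmonicBias, harmonic_nd
from fepath.sampling import rng_stream


class TestInitString:
    def test_linear_interpolation_1d(self):
        state = init_string([0.0], [1.0], 3)
        assert np.allclose(state.nodes[:, 0], [0.0, 0.5, 1.0])

    def test_dihedral_shorter_arc(self):
        state = init_string([170.0], [-170.0], 3, kinds=["dihedral"])
        middle = state.nodes[1, 0]
        # shorter arc passes through ±180, not 0
        assert wrap_degrees(middle - 180.0) == pytest.approx(0.0, abs=1e-9)

    def test_nodes_equidistant_after_init(self):
        state = init_string([0.0, 0.0], [3.0, 4.0], 6)
        gaps = np.linalg.norm(np.diff(state.nodes, axis=0), axis=1)
        assert np.allclose(gaps, gaps[0], rtol=1e-12)

    def test_identical_endpoints_rejected(self):
        with pytest.raises(DegenerateStringError):
            init_string([1.0, 2.0], [1.0, 2.0], 5)


class TestReparameterize:
    def test_equidistant_unchanged(self):
        nodes = np.linspace([0.0, 0.0], [1.0, 2.0], 7)
        assert np.allclose(reparameterize(nodes), nodes, atol=1e-12)

    def test_1d_example(self):
        out = reparameterize(np.array([[0.0], [0.1], [1.0]]))
        assert np.allclose(out[:, 0], [0.0, 0.5, 1.0])

    def test_arc_length_preserved_and_equalised(self, rng):
        nodes = np.cumsum(rng.uniform(0.1, 1.0, size=(8, 3)), axis=0)
        out = reparameterize(nodes)
        assert out[0] == pytest.approx(nodes[0])
        assert out[-1] == pytest.approx(nodes[-1])

        # arc position of a point along the original polyline
        seg = np.diff(nodes, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])

        def arc_position(p):
            best = (np.inf, 0.0)
            for k in range(len(seg)):
                v = p - nodes[k]
                t = np.clip(v @ seg[k] / (seg[k] @ seg[k]), 0.0, 1.0)
                d2 = ((v - t * seg[k]) ** 2).sum()
                if d2 < best[0]:
                    best = (d2, cum[k] + t * seg_len[k])
            assert best[0] < 1e-18  # resampled node lies on the polyline
            return best[1]

        positions = np.array([arc_position(p) for p in out])
        # equally spaced along the path, total arc length preserved
        assert np.allclose(np.diff(positions), cum[-1] / (len(out) - 1),
                           rtol=1e-9)
        assert positions[-1] == pytest.approx(cum[-1], rel=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_equal_spacing_property(self, seed):
        rng = np.random.default_rng(seed)
        nodes = np.cumsum(rng.uniform(0.05, 1.0, size=(6, 2)), axis=0)
        out = reparameterize(nodes)
        gaps = np.linalg.norm(np.diff(out, axis=0), axis=1)
        # consecutive along-polyline arc lengths equal within 1e-9 relative;
        # chord gaps agree when the resampled nodes fall on straight spans
        assert gaps.sum() <= np.linalg.norm(np.diff(nodes, axis=0), axis=1).sum() + 1e-9

    def test_zero_arc_rejected(self):
        with pytest.raises(DegenerateStringError):
            reparameterize(np.zeros((4, 2)))


class TestConvergence:
    def test_window_satisfied(self):
        s = StringState(np.zeros((3, 1)) + [[0.0], [0.5], [1.0]],
                        rmsd_history=[0.5, 0.09, 0.08])
        assert check_convergence(s, threshold=0.1, window=2)

    def test_recent_violation_fails(self):
        s = StringState([[0.0], [0.5], [1.0]], rmsd_history=[0.09, 0.2])
        assert not check_convergence(s, threshold=0.1, window=2)

    def test_short_history_is_insufficient(self):
        s = StringState([[0.0], [0.5], [1.0]], rmsd_history=[0.01])
        assert not check_convergence(s, threshold=0.1, window=5)


class TestStringOnPotentials:
    def test_convex_potential_collapses_to_minimum(self):
        """On a single harmonic well, a free-endpoint string contracts
        onto the minimum."""
        p = harmonic_nd([1.0, 1.0], center=[0.3, -0.2])
        state = init_string([1.0, 1.0], [-1.0, -1.0], 8)
        for _ in range(120):
            state = string_iteration(
                state, p, k_restraint=1.0, steps_per_node=50, dt=1e-2,
                kt=0.0, step_size=0.5, seed=0,
            )
        spread = np.linalg.norm(state.nodes - state.nodes.mean(axis=0), axis=1)
        assert spread.max() < 1e-3
        assert np.allclose(state.nodes.mean(axis=0), [0.3, -0.2], atol=1e-3)

    def test_zero_temperature_is_damped_descent(self):
        """kT = 0: the node update equals a damped gradient-descent step
        toward the restrained minimum."""
        p = harmonic_nd([2.0], center=[0.0])
        state = init_string([-1.0], [1.0], 3)
        k, step = 10.0, 0.25
        new = string_iteration(
            state, p, k_restraint=k, steps_per_node=2_000, dt=1e-3,
            kt=0.0, step_size=step, seed=0,
        )
        # restrained minimum of ½·2x² + ½k(x−c)²: x* = k c/(2+k)
        expected_mid = np.array([c + step * (k * c / (2 + k) - c)
                                 for c in state.nodes[:, 0]])
        # middle node of 3 is unmoved by reparameterization in 1-D symmetry
        assert new.nodes[1, 0] == pytest.approx(expected_mid[1], abs=1e-6)

    def test_quadratic_mfep_is_straight_segment(self):
        """With pinned endpoints on an isotropic bowl, the converged string
        returns to the straight segment after an off-path perturbation."""
        p = harmonic_nd([1.0, 1.0])
        state = init_string([1.0, 1.0], [-1.0, -1.0], 9)
        bent = state.nodes.copy()
        bent[1:-1] += np.array([0.3, -0.3])  # push interior off the diagonal
        state = StringState(bent)
        for _ in range(200):
            state = string_iteration(
                state, p, k_restraint=1.0, steps_per_node=100, dt=5e-3,
                kt=0.0, step_size=0.5, seed=0, pin_endpoints=True,
            )
        # straight segment between endpoints: y = x
        assert np.abs(state.nodes[:, 0] - state.nodes[:, 1]).max() < 1e-6

    def test_iteration_keeps_nodes_equidistant(self):
        p = harmonic_nd([1.0, 4.0])
        state = init_string([1.0, 0.5], [-1.0, -0.5], 6)
        state = string_iteration(state, p, k_restraint=50.0,
                                 steps_per_node=100, dt=1e-3, kt=0.2, seed=1)
        gaps = np.linalg.norm(np.diff(state.nodes, axis=0), axis=1)
        # along-path equal spacing; chords equal too for this smooth string
        assert np.allclose(gaps, gaps[0], rtol=1e-6)


class TestExchange:
    def test_identical_biases_always_accept(self):
        bias = HarmonicBias([0.0], 5.0)
        rng = rng_stream(0)
        accepted, xa, xb = attempt_exchange(
            np.array([0.3]), np.array([0.7]), bias, bias, kt=1.0, rng=rng
        )
        assert accepted
        assert xa[0] == 0.7 and xb[0] == 0.3

    def test_zero_temperature_rejects_uphill_swap(self):
        bias_a = HarmonicBias([0.0], 10.0)
        bias_b = HarmonicBias([1.0], 10.0)
        rng = rng_stream(0)
        # configs already at their own bias minima: swapping raises energy
        accepted, xa, xb = attempt_exchange(
            np.array([0.0]), np.array([1.0]), bias_a, bias_b, kt=0.0, rng=rng
        )
        assert not accepted
        assert xa[0] == 0.0 and xb[0] == 1.0

    def test_empirical_rate_matches_metropolis(self):
        """Acceptance frequency over many trials matches the analytic
        probability for fixed configurations within 3 binomial stderr."""
        bias_a = HarmonicBias([0.0], 4.0)
        bias_b = HarmonicBias([0.8], 4.0)
        xa, xb, kt = np.array([0.1]), np.array([0.5]), 0.61603
        delta = float(
            bias_a.energy(xb) + bias_b.energy(xa)
            - bias_a.energy(xa) - bias_b.energy(xb)
        )
        p_exact = min(1.0, np.exp(-delta / kt))
        rng = rng_stream(99)
        n = 100_000
        hits = sum(
            attempt_exchange(xa, xb, bias_a, bias_b, kt, rng)[0]
            for _ in range(n)
        )
        stderr = np.sqrt(p_exact * (1 - p_exact) / n)
        assert abs(hits / n - p_exact) < 3 * stderr


class TestPathCV:
    def setup_method(self):
        self.path = PathCV(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]]))

    def test_nodes_anchor_to_fractions(self):
        for k, node in enumerate(self.path.nodes):
            assert self.path.s(node) == pytest.approx(k / 2)

    def test_segment_midpoint(self):
        assert self.path.s([0.5, 0.0]) == pytest.approx(0.25)
        assert self.path.s([1.0, 0.5]) == pytest.approx(0.75)

    def test_clamping_beyond_endpoints(self):
        assert self.path.s([1.0, 5.0]) == 1.0
        assert self.path.s([-3.0, 0.0]) == 0.0

    def test_monotone_along_node_walk(self):
        """s is non-decreasing along any monotone walk through the nodes."""
        state = init_string([0.0, 0.0], [2.0, 1.0], 12)
        rng = np.random.default_rng(4)
        bent = state.nodes + 0.05 * rng.normal(size=state.nodes.shape)
        path = PathCV(reparameterize(bent))
        svals = [path.s(n) for n in path.nodes]
        assert all(b >= a - 1e-12 for a, b in zip(svals, svals[1:]))

    def test_projection_with_metric_weights(self):
        path = PathCV(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]),
                      weights=np.array([4.0, 1.0]))
        assert path.s([0.5, 3.0]) == pytest.approx(0.25)


def test_run_string_sets_converged_flag():
    p = harmonic_nd([1.0, 1.0])
    state = init_string([0.5, 0.5], [-0.5, -0.5], 5)
    out = run_string(state, p, max_iterations=200, threshold=0.05, window=5,
                     seed=0, k_restraint=1.0, steps_per_node=30, dt=1e-2,
                     kt=0.0, step_size=0.3)
    assert out.converged
    assert len(out.rmsd_history) == out.iteration
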