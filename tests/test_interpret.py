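"""g statistic, characteristic/similar partition and residue displacement tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynawass.errors import DegenerateDistributionError, PreconditionError
from dynawass.interpret import (
    GSeries,
    classify_windows,
    compute_g,
    displacement_table,
    rank_residues,
    short_term_displacement,
)
from dynawass.lde import dense_windows

from conftest import linear_critic, make_ptraj, materialized_ensemble, zero_critic


def first_coord_critic():
    """Rigged critic computing f(x) = first flattened coordinate (x >= 0)."""
    d = np.zeros(3)
    d[0] = 1.0
    return linear_critic(3, direction=d)


class TestComputeG:
    @staticmethod
    def _ens(values, sid):
        disp = np.zeros((len(values), 1, 1, 3))
        disp[:, 0, 0, 0] = values
        return materialized_ensemble(disp, sid=sid)

    def test_direct_arithmetic(self):
        g = compute_g(first_coord_critic(), self._ens([1.0, 3.0], "i"), self._ens([0.0, 2.0], "j"))
        np.testing.assert_allclose(g.g_values, [0.0, 2.0])
        assert g.reference_mean == pytest.approx(1.0)

    def test_constant_critic_gives_zero(self):
        g = compute_g(zero_critic(3), self._ens([1.0, 2.0], "i"), self._ens([3.0], "j"))
        np.testing.assert_array_equal(g.g_values, 0.0)

    def test_mean_identity_is_exact(self):
        """E_i[g] equals the critic-gap estimate on the same samples (algebraic)."""
        rng = np.random.default_rng(0)
        ei = self._ens(rng.normal(size=400), "i")
        ej = self._ens(rng.normal(1.0, 1.0, size=300), "j")
        from dynawass.critic import Critic, CriticConfig

        critic = Critic(CriticConfig(input_dim=3, hidden_widths=(16, 16)), 1)
        g = compute_g(critic, ei, ej)
        gap = critic.forward(ei.windows()).mean() - critic.forward(ej.windows()).mean()
        assert abs(g.g_values.mean() - gap) <= 1e-9 * max(abs(gap), 1e-12)


class TestClassify:
    @staticmethod
    def _series(values):
        return GSeries(ordered_pair=("i", "j"), g_values=np.asarray(values, float), reference_mean=0.0)

    def test_deciles_of_1_to_100(self):
        part = classify_windows(self._series(np.arange(1.0, 101.0)), 0.10)
        np.testing.assert_array_equal(np.sort(part.similar), np.arange(10))
        np.testing.assert_array_equal(np.sort(part.characteristic), np.arange(90, 100))
        assert part.middle.size == 80

    def test_half_fraction_empties_middle(self):
        part = classify_windows(self._series(np.arange(20.0)), 0.5)
        assert part.middle.size == 0
        assert part.characteristic.size + part.similar.size == 20

    def test_degenerate_distribution(self):
        with pytest.raises(DegenerateDistributionError):
            classify_windows(self._series(np.ones(50)), 0.1)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.sampled_from([0.05, 0.10, 0.25]))
    def test_group_sizes_near_fraction(self, seed, fraction):
        g = np.random.default_rng(seed).normal(size=200)
        part = classify_windows(self._series(g), fraction)
        target = fraction * g.size
        assert abs(part.characteristic.size - target) <= 1
        assert abs(part.similar.size - target) <= 1
        assert part.characteristic.size + part.middle.size + part.similar.size == g.size


class TestShortTermDisplacement:
    def test_static_particle_zero(self):
        ens = dense_windows(make_ptraj([np.full((50, 1, 3), 0.4)], dt=2.0), 16.0)
        d = short_term_displacement(ens, np.arange(ens.n_windows), 4.0, 16.0)
        np.testing.assert_allclose(d, 0.0, atol=1e-14)

    def test_constant_velocity_arithmetic_mean(self):
        # |r(t+lag) - r(t)| = v*lag; mean over lags T0..T (step delta) = v*(T0+T)/2
        v, dt = 0.01, 2.0
        frames = np.zeros((200, 1, 3))
        frames[:, 0, 0] = v * dt * np.arange(200)
        ens = dense_windows(make_ptraj([frames], dt=dt), 128.0)
        d = short_term_displacement(ens, np.arange(ens.n_windows), 32.0, 128.0)
        assert d[0] == pytest.approx(v * (32.0 + 128.0) / 2)

    def test_gaussian_lags_match_chi_mean(self):
        # iid 3D Gaussian displacements with per-axis std s: E||d|| = 2 s sqrt(2/pi)
        rng = np.random.default_rng(1)
        s = 0.2
        disp = rng.normal(scale=s, size=(40_000, 1, 4, 3))
        ens = materialized_ensemble(disp)
        d = short_term_displacement(ens, np.arange(ens.n_windows), 1.0, 4.0)
        assert d[0] == pytest.approx(2 * s * np.sqrt(2 / np.pi), rel=0.02)

    def test_lag_bounds_validated(self):
        ens = materialized_ensemble(np.zeros((10, 1, 4, 3)))
        with pytest.raises(PreconditionError):
            short_term_displacement(ens, np.arange(10), 2.0, 6.0)
        with pytest.raises(PreconditionError):
            short_term_displacement(ens, np.array([], dtype=int), 1.0, 4.0)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.floats(0.25, 4.0), st.floats(-2.0, 2.0))
    def test_translation_invariant_and_scale_covariant(self, c, shift):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(60, 2, 3))
        ens0 = dense_windows(make_ptraj([base]), 5.0)
        ens1 = dense_windows(make_ptraj([base * c + shift]), 5.0)
        idx = np.arange(ens0.n_windows)
        d0 = short_term_displacement(ens0, idx, 1.0, 5.0)
        d1 = short_term_displacement(ens1, idx, 1.0, 5.0)
        np.testing.assert_allclose(d1, c * d0, rtol=1e-9)


class TestRanking:
    def test_identical_tables_stable_order(self):
        d = np.array([0.1, 0.2, 0.3])
        ranked = rank_residues(d, d, residue_ids=(7, 8, 9))
        assert list(ranked["residue_id"]) == [7, 8, 9]
        np.testing.assert_array_equal(ranked["gap"], 0.0)

    def test_planted_gap_ranks_first(self):
        dc = np.array([0.1, 0.6, 0.1, 0.1])
        ds = np.array([0.1, 0.1, 0.1, 0.1])
        ranked = rank_residues(dc, ds)
        assert ranked.iloc[0]["residue_id"] == 1
        assert ranked.iloc[0]["gap"] == pytest.approx(0.5)

    def test_residue_mismatch_rejected(self):
        with pytest.raises(PreconditionError):
            rank_residues(np.zeros(3), np.zeros(4))


def test_displacement_table_covers_groups():
    rng = np.random.default_rng(3)
    ens = dense_windows(make_ptraj([rng.normal(size=(300, 2, 3))], dt=1.0), 4.0)
    critic = linear_critic(ens.flat_dim)
    ref = dense_windows(make_ptraj([rng.normal(size=(300, 2, 3))], dt=1.0, sid="j"), 4.0)
    part = classify_windows(compute_g(critic, ens, ref), 0.10)
    table = displacement_table(ens, part, 1.0, 4.0, residue_ids=(4, 5))
    frame = table.to_frame()
    assert list(frame["residue_id"]) == [4, 5]
    assert (frame[["d_characteristic", "d_middle", "d_similar"]] >= 0).all().all()
    assert sum(table.group_sizes.values()) == ens.n_windows
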