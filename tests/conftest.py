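"""Shared fixtures: programmatic trajectories, ensembles and hand-built critics."""

from __future__ import annotations

import numpy as np
import pytest

from dynawass.critic import Critic, CriticConfig
from dynawass.lde import LDEnsemble
from dynawass.trajio import AtomRecord, ParticleTrajectory, SystemTrajectory


def make_system(runs, elements, resids, names=None, ligand=(), resnames=None, dt=2.0, sid="sys"):
    """SystemTrajectory from raw arrays; masses from the standard table."""
    from dynawass.trajio import ATOMIC_MASSES

    names = names or [f"A{i}" for i in range(len(elements))]
    resnames = resnames or ["RES"] * len(elements)
    atoms = [
        AtomRecord(
            atom_index=i,
            residue_id=resids[i],
            residue_name=resnames[i],
            name=names[i],
            element=elements[i],
            mass=ATOMIC_MASSES[elements[i]],
        )
        for i in range(len(elements))
    ]
    return SystemTrajectory(
        system_id=sid,
        runs=[np.asarray(r, dtype=float) for r in runs],
        frame_interval_ps=dt,
        atoms=atoms,
        ligand_atom_indices=frozenset(ligand),
    )


def make_ptraj(runs, dt=1.0, sid="p"):
    runs = [np.asarray(r, dtype=float) for r in runs]
    return ParticleTrajectory(
        system_id=sid, runs=runs, frame_interval_ps=dt, residue_ids=tuple(range(runs[0].shape[1]))
    )


def materialized_ensemble(displacements, sid="ens", dt=1.0, window_ps=None):
    disp = np.asarray(displacements, dtype=float)
    return LDEnsemble(
        system_id=sid,
        frame_interval_ps=dt,
        window_ps=window_ps if window_ps is not None else disp.shape[2] * dt,
        displacements=disp,
    )


def gaussian_ensemble(mu, n=4096, seed=0, sid="g"):
    """1-particle / 1-lag windows: N(mu, 1) on axis 0, zeros elsewhere."""
    rng = np.random.default_rng(seed)
    disp = np.zeros((n, 1, 1, 3))
    disp[:, 0, 0, 0] = rng.normal(mu, 1.0, size=n)
    return materialized_ensemble(disp, sid=sid)


def linear_critic(input_dim, direction=None, slope=0.01):
    """Critic rigged to compute f(x) = direction . x for inputs in the active cone.

    One wide-enough path through the hidden layers with positive weights so
    that positive pre-activations pass unchanged; exact for inputs whose
    projections stay positive, which the tests arrange.
    """
    cfg = CriticConfig(input_dim=input_dim, hidden_widths=(1, 1, 1), leaky_slope=slope)
    c = Critic(cfg, 0)
    d = np.ones(input_dim) if direction is None else np.asarray(direction, float)
    c.weights = [d[None, :], np.ones((1, 1)), np.ones((1, 1))]
    c.biases = [np.zeros(1)] * 3
    c.w_out = np.ones(1)
    return c


def zero_critic(input_dim):
    cfg = CriticConfig(input_dim=input_dim, hidden_widths=(4, 4), leaky_slope=0.01)
    c = Critic(cfg, 0)
    c.weights = [np.zeros_like(w) for w in c.weights]
    c.biases = [np.zeros_like(b) for b in c.biases]
    c.w_out = np.zeros_like(c.w_out)
    return c


@pytest.fixture(scope="session")
def benchmark_run(tmp_path_factory):
    """One full synthetic-suite pipeline run (desk preset, default conditions).

    Shared by the end-to-end acceptance checks; also exposes the artifacts
    needed for the residue-level interpretation check.
    """
    from dynawass.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("benchmark")
    cfg = PipelineConfig(synthetic={}, preset="desk", seed=1, out_dir=str(out))
    summary = run_pipeline(cfg)
    return {"summary": summary, "out": out, "config": cfg}
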