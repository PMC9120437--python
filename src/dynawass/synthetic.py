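"""Synthetic binding-site dynamics with known ground truth.

Each pseudo-residue is an independent 3D Ornstein-Uhlenbeck particle:
mean-reverting with stiffness k (ps^-1) and noise amplitude sigma
(nm ps^-1/2), mimicking harmonic-like binding-site fluctuations.  A bound
ligand is emulated by scaling the stiffness of a known subset of "key"
residues: stiffer means smaller fluctuations, as holo binding sites are
more rigid than apo ones.  The pseudo binding free energy of holo system
s is dG_s = -a * ln(c_s) for stiffness scale c_s, so affinity strength is
monotone in the planted rigidification and the whole pipeline can be
checked for parameter recovery.

Sampling uses the exact discrete OU transition (not an Euler scheme), so
the closed forms hold at any frame interval:

    x(t+d) = x(t) e^{-k d} + eta,   eta ~ N(0, (sigma^2/2k)(1 - e^{-2k d}))

with stationary per-axis variance sigma^2/(2k), lag-D autocorrelation
e^{-k D}, and stationary mean-square increment per axis
(sigma^2/k)(1 - e^{-k D}).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import PreconditionError
from .trajio import AtomRecord, BindingSite, ParticleTrajectory, SystemTrajectory, residue_centers_of_mass

__all__ = [
    "OUSystemSpec",
    "BenchmarkSuite",
    "simulate_ou_site",
    "particle_trajectory",
    "make_benchmark_suite",
    "DEFAULT_SCALE_FACTORS",
    "DEFAULT_KEY_RESIDUES",
]

DEFAULT_SCALE_FACTORS = (1.5, 2.0, 3.0, 4.0, 6.0)
DEFAULT_KEY_RESIDUES = (1, 3)


@dataclass(frozen=True)
class OUSystemSpec:
    """One synthetic system: independent OU particles, possibly per-residue k."""

    system_id: str
    n_residues: int = 10
    stiffness_ps: float | tuple[float, ...] = 0.05  # k, ps^-1
    sigma_nm_sqrt_ps: float = 0.1  # noise amplitude
    frame_interval_ps: float = 2.0
    frames_per_run: int = 50_000
    n_runs: int = 2
    seed: int = 0

    def stiffness_array(self) -> np.ndarray:
        k = np.broadcast_to(np.asarray(self.stiffness_ps, dtype=float), (self.n_residues,)).copy()
        if (k <= 0).any():
            raise PreconditionError("stiffness must be positive")
        return k

    def __post_init__(self) -> None:
        if self.n_residues < 1 or self.n_runs < 1 or self.frames_per_run < 2:
            raise PreconditionError("invalid OU spec sizes")
        if self.sigma_nm_sqrt_ps < 0 or self.frame_interval_ps <= 0:
            raise PreconditionError("sigma must be >= 0 and frame interval positive")
        self.stiffness_array()

    def stationary_std_nm(self) -> np.ndarray:
        """Per-axis stationary standard deviation sigma/sqrt(2k)."""
        return self.sigma_nm_sqrt_ps / np.sqrt(2.0 * self.stiffness_array())


def _pseudo_atoms(n_residues: int) -> list[AtomRecord]:
    return [
        AtomRecord(
            atom_index=i, residue_id=i, residue_name="OUP", name="X", element="X", mass=1.0
        )
        for i in range(n_residues)
    ]


def simulate_ou_site(spec: OUSystemSpec) -> SystemTrajectory:
    """Exact-transition OU sampling; residues are unit-mass pseudo-atoms."""
    k = spec.stiffness_array()
    delta = spec.frame_interval_ps
    a = np.exp(-k * delta)  # (n,)
    stat_std = spec.stationary_std_nm()
    step_std = stat_std * np.sqrt(1.0 - a**2)

    ss = np.random.SeedSequence([spec.seed])
    run_seeds = ss.spawn(spec.n_runs)
    runs = []
    for child in run_seeds:
        rng = np.random.default_rng(child)
        drive = rng.standard_normal((spec.frames_per_run, spec.n_residues, 3))
        drive *= step_std[None, :, None]
        drive[0] = rng.standard_normal((spec.n_residues, 3)) * stat_std[:, None]
        coords = np.empty_like(drive)
        for r in range(spec.n_residues):
            coords[:, r, :] = lfilter([1.0], [1.0, -a[r]], drive[:, r, :], axis=0)
        runs.append(coords)
    return SystemTrajectory(
        system_id=spec.system_id,
        runs=runs,
        frame_interval_ps=delta,
        atoms=_pseudo_atoms(spec.n_residues),
    )


def particle_trajectory(spec: OUSystemSpec) -> ParticleTrajectory:
    """Simulate and reduce to per-residue centers (identity for pseudo-atoms)."""
    traj = simulate_ou_site(spec)
    site = BindingSite(residue_ids=tuple(range(spec.n_residues)))
    return residue_centers_of_mass(traj, site, heavy_only=True)


@dataclass
class BenchmarkSuite:
    """One apo plus M holo OU systems with planted key-residue rigidification."""

    apo_spec: OUSystemSpec
    holo_specs: list[OUSystemSpec]
    key_residues: tuple[int, ...]
    scale_factors: tuple[float, ...]
    affinity_coefficient: float
    seed: int
    affinities: pd.DataFrame = field(repr=False)

    @property
    def specs(self) -> list[OUSystemSpec]:
        return [self.apo_spec, *self.holo_specs]

    @property
    def system_ids(self) -> list[str]:
        return [s.system_id for s in self.specs]

    def simulate(self) -> dict[str, ParticleTrajectory]:
        return {s.system_id: particle_trajectory(s) for s in self.specs}

    def write_fixtures(self, out_dir) -> dict[str, Path]:
        """HDF5 particle trajectories plus the pseudo-affinity CSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for sid, ptraj in self.simulate().items():
            path = out_dir / f"{sid}.h5"
            ptraj.to_hdf5(path)
            paths[sid] = path
        self.affinities.to_csv(out_dir / "affinities.csv", index=False)
        paths["affinities"] = out_dir / "affinities.csv"
        return paths


def make_benchmark_suite(
    scale_factors=DEFAULT_SCALE_FACTORS,
    key_residues=DEFAULT_KEY_RESIDUES,
    base_spec: OUSystemSpec | None = None,
    affinity_coefficient: float = 1.0,
    seed: int = 0,
    out_dir=None,
) -> BenchmarkSuite:
    """Build the apo + M-holo suite; holo s scales key-residue stiffness by c_s.

    Pseudo-affinities dG_s = -a ln(c_s) (kcal/mol) are strictly decreasing
    in c_s, so stronger rigidification means stronger binding.  Identical
    seeds produce identical suites (and byte-identical fixture files).
    """
    scale_factors = tuple(float(c) for c in scale_factors)
    if len(set(scale_factors)) != len(scale_factors):
        raise PreconditionError("duplicate stiffness scale factors")
    if any(c <= 1.0 for c in scale_factors):
        raise PreconditionError("scale factors must be > 1 (apo has c = 1)")
    if list(scale_factors) != sorted(scale_factors):
        raise PreconditionError("scale factors must be strictly increasing")
    if affinity_coefficient <= 0:
        raise PreconditionError("affinity coefficient must be positive")

    base = base_spec or OUSystemSpec(system_id="S0")
    key_residues = tuple(int(r) for r in key_residues)
    if any(r < 0 or r >= base.n_residues for r in key_residues):
        raise PreconditionError("key residues out of range")

    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(scale_factors) + 1)]
    base_k = np.broadcast_to(np.asarray(base.stiffness_ps, dtype=float), (base.n_residues,))

    from dataclasses import replace

    apo = replace(base, system_id="S0", seed=seeds[0])
    holo = []
    rows = []
    for s, c in enumerate(scale_factors, start=1):
        k = base_k.copy()
        k[list(key_residues)] *= c
        holo.append(
            replace(base, system_id=f"S{s}", stiffness_ps=tuple(k), seed=seeds[s])
        )
        rows.append(
            {
                "system_id": f"S{s}",
                "stiffness_scale": c,
                "delta_g_kcal_per_mol": -affinity_coefficient * np.log(c),
            }
        )
    suite = BenchmarkSuite(
        apo_spec=apo,
        holo_specs=holo,
        key_residues=key_residues,
        scale_factors=scale_factors,
        affinity_coefficient=affinity_coefficient,
        seed=seed,
        affinities=pd.DataFrame(rows),
    )
    if out_dir is not None:
        suite.write_fixtures(out_dir)
    return suite
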