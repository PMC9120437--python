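"""Trajectory input and reduction to binding-site particle trajectories.

This stage turns raw MD output (a topology plus one coordinate file per
independent run) into the per-residue center-of-mass particle trajectories
that all downstream stages consume.  It also implements the contact-based
binding-site selection rule (a residue is "active" in a run when its
minimum heavy-atom distance to the ligand is below a cutoff in more than a
given fraction of early frames) and rigid-body superposition onto a common
reference so that coordinate frames are comparable across systems.

Units: coordinates in nm (converted from the Angstrom convention of the
readers on load), times in ps, masses in atomic mass units.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    FormatError,
    NoBindingSiteError,
    PreconditionError,
)

__all__ = [
    "AtomRecord",
    "SystemTrajectory",
    "ResidueActivity",
    "BindingSite",
    "ParticleTrajectory",
    "load_trajectory",
    "compute_activity_ratio",
    "select_binding_site",
    "superpose_frames",
    "kabsch",
    "residue_centers_of_mass",
    "rmsf_per_residue",
]

ANGSTROM_TO_NM = 0.1

#: Standard atomic masses (u) for elements that occur in protein/ligand systems.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38, "SE": 78.971,
    "BR": 79.904, "I": 126.904,
    # pseudo-particle element used by the synthetic generator
    "X": 1.0,
}

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

# two-letter element symbols that can appear in PDB atom names
_TWO_LETTER = frozenset({"CL", "BR", "NA", "MG", "ZN", "FE", "MN", "SE", "CU", "NI", "CO"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology."""

    atom_index: int
    residue_id: int
    residue_name: str
    name: str
    element: str
    mass: float

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")

    @property
    def is_backbone(self) -> bool:
        return self.name in _BACKBONE_NAMES


@dataclass
class SystemTrajectory:
    """Multi-run coordinate series of one system (apo or holo).

    ``runs`` holds one ``(frames, atoms, 3)`` array per independent
    simulation, in nm; all runs share ``atoms``.  ``ligand_atom_indices``
    is empty for an apo system.
    """

    system_id: str
    runs: list[np.ndarray]
    frame_interval_ps: float
    atoms: list[AtomRecord]
    ligand_atom_indices: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.frame_interval_ps <= 0:
            raise PreconditionError("frame_interval_ps must be positive")
        n_atoms = len(self.atoms)
        for i, run in enumerate(self.runs):
            if run.ndim != 3 or run.shape[1] != n_atoms or run.shape[2] != 3:
                raise FormatError(
                    f"run {i} of {self.system_id!r} has shape {run.shape}, "
                    f"expected (frames, {n_atoms}, 3)"
                )
            if run.shape[0] < 2:
                raise PreconditionError(f"run {i} has fewer than 2 frames")
            if not np.isfinite(run).all():
                raise FormatError(f"run {i} contains non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue_atom_indices(self, residue_id: int, heavy_only: bool = False) -> np.ndarray:
        idx = [
            a.atom_index
            for a in self.atoms
            if a.residue_id == residue_id
            and a.atom_index not in self.ligand_atom_indices
            and (a.is_heavy or not heavy_only)
        ]
        return np.asarray(idx, dtype=int)


@dataclass(frozen=True)
class ResidueActivity:
    """Contact activity of one residue in one run: ratio = n/N."""

    residue_id: int
    n_contact_frames: int
    n_total_frames: int

    @property
    def ratio(self) -> float:
        return self.n_contact_frames / self.n_total_frames


@dataclass(frozen=True)
class BindingSite:
    """Ordered residue set defining the local-dynamics particles."""

    residue_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.residue_ids)) != len(self.residue_ids):
            raise PreconditionError("binding site contains duplicate residues")

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)


@dataclass
class ParticleTrajectory:
    """Per-residue center-of-mass particle series, one array per run."""

    system_id: str
    runs: list[np.ndarray]  # each (frames, n_residues, 3), nm
    frame_interval_ps: float
    residue_ids: tuple[int, ...]

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as h5:
            h5.attrs["system_id"] = self.system_id
            h5.attrs["frame_interval_ps"] = self.frame_interval_ps
            h5.attrs["residue_ids"] = np.asarray(self.residue_ids, dtype=int)
            for i, run in enumerate(self.runs):
                h5.create_dataset(f"run_{i}", data=run)

    @classmethod
    def from_hdf5(cls, path) -> "ParticleTrajectory":
        with h5py.File(path, "r") as h5:
            runs = [h5[k][()] for k in sorted(h5.keys(), key=lambda s: int(s.split("_")[1]))]
            return cls(
                system_id=str(h5.attrs["system_id"]),
                runs=runs,
                frame_interval_ps=float(h5.attrs["frame_interval_ps"]),
                residue_ids=tuple(int(r) for r in h5.attrs["residue_ids"]),
            )


def _element_from_atom(name: str, element_attr: str | None) -> str:
    if element_attr:
        sym = element_attr.strip().upper()
        if sym:
            return sym
    stripped = "".join(ch for ch in name if ch.isalpha()).upper()
    if not stripped:
        raise FormatError(f"cannot infer element for atom name {name!r}")
    if stripped[:2] in _TWO_LETTER:
        return stripped[:2]
    return stripped[0]


def _mass_for(element: str, atom_name: str) -> float:
    try:
        return ATOMIC_MASSES[element]
    except KeyError:
        raise FormatError(
            f"unknown element {element!r} (atom {atom_name!r}); "
            "extend the atomic-mass table rather than guessing"
        ) from None


def load_trajectory(
    topology_path,
    coordinate_paths: Sequence | None = None,
    frame_interval_ps: float | None = None,
    system_id: str | None = None,
    ligand_selection: str | None = None,
) -> SystemTrajectory:
    """Read a topology plus coordinate files into a :class:`SystemTrajectory`.

    Each coordinate file becomes one run.  If ``coordinate_paths`` is omitted
    the topology itself must carry frames (multi-frame PDB).  Coordinates are
    converted to nm.  ``ligand_selection`` is an MDAnalysis selection string
    (e.g. ``"resname LIG"``) marking ligand atoms; omit it for apo systems.
    """
    import MDAnalysis as mda

    topology_path = str(topology_path)
    paths = [str(p) for p in coordinate_paths] if coordinate_paths else [None]

    runs: list[np.ndarray] = []
    first_universe = None
    dt_meta: float | None = None
    for path in paths:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                u = mda.Universe(topology_path) if path is None else mda.Universe(topology_path, path)
            except OSError as exc:
                raise FormatError(f"cannot read {path or topology_path!r}: {exc}") from exc
            except Exception as exc:
                raise FormatError(
                    f"coordinate file {path!r} is inconsistent with topology "
                    f"{topology_path!r}: {exc}"
                ) from exc
            if first_universe is None:
                first_universe = u
            if len(u.atoms) != len(first_universe.atoms):
                raise FormatError(
                    f"coordinate file {path!r} has {len(u.atoms)} atoms, "
                    f"topology has {len(first_universe.atoms)}"
                )
            coords = np.asarray(
                [u.atoms.positions.copy() for _ in u.trajectory], dtype=np.float64
            )
            if path is not None and path.lower().endswith((".xtc", ".trr", ".dcd")):
                dt_meta = float(u.trajectory.dt)
        runs.append(coords * ANGSTROM_TO_NM)

    if frame_interval_ps is None:
        if dt_meta is None or dt_meta <= 0:
            raise ConfigurationError(
                "frame_interval_ps not given and the trajectory carries no time metadata"
            )
        frame_interval_ps = dt_meta

    u = first_universe
    elements = getattr(u.atoms, "elements", [None] * len(u.atoms))
    atoms = []
    for i, atom in enumerate(u.atoms):
        element = _element_from_atom(atom.name, elements[i])
        atoms.append(
            AtomRecord(
                atom_index=i,
                residue_id=int(atom.resid),
                residue_name=str(atom.resname),
                name=str(atom.name),
                element=element,
                mass=_mass_for(element, atom.name),
            )
        )

    ligand_indices: frozenset[int] = frozenset()
    if ligand_selection:
        ligand_indices = frozenset(int(i) for i in u.select_atoms(ligand_selection).ix)

    return SystemTrajectory(
        system_id=system_id or topology_path,
        runs=runs,
        frame_interval_ps=float(frame_interval_ps),
        atoms=atoms,
        ligand_atom_indices=ligand_indices,
    )


def compute_activity_ratio(
    traj: SystemTrajectory,
    candidate_residues: Sequence[int],
    cutoff_nm: float = 0.5,
    analysis_window_ps: float = 200_000.0,
) -> list[dict[int, ResidueActivity]]:
    """Per-run contact activity n/N of each candidate residue with the ligand.

    A frame counts as a contact when the minimum heavy-atom distance between
    the residue and the ligand is strictly below ``cutoff_nm``; only frames
    within the first ``analysis_window_ps`` of each run are considered.
    """
    if not traj.ligand_atom_indices:
        raise PreconditionError(f"system {traj.system_id!r} has no ligand atoms (apo?)")
    if not candidate_residues:
        raise PreconditionError("candidate residue list is empty")
    if cutoff_nm <= 0:
        raise PreconditionError("cutoff_nm must be positive")

    lig_heavy = np.asarray(
        [i for i in sorted(traj.ligand_atom_indices) if traj.atoms[i].is_heavy], dtype=int
    )
    if lig_heavy.size == 0:
        raise PreconditionError("ligand has no heavy atoms")

    res_heavy = {}
    for rid in candidate_residues:
        idx = traj.residue_atom_indices(rid, heavy_only=True)
        if idx.size == 0:
            raise PreconditionError(f"residue {rid} has no heavy atoms in the topology")
        res_heavy[rid] = idx

    out: list[dict[int, ResidueActivity]] = []
    for run in traj.runs:
        n_frames = min(run.shape[0], int(np.floor(analysis_window_ps / traj.frame_interval_ps)) + 1)
        n_frames = max(n_frames, 1)
        lig = run[:n_frames, lig_heavy]  # (F, L, 3)
        per_res: dict[int, ResidueActivity] = {}
        for rid, idx in res_heavy.items():
            res = run[:n_frames, idx]  # (F, R, 3)
            d2 = ((res[:, :, None, :] - lig[:, None, :, :]) ** 2).sum(axis=-1)
            min_d = np.sqrt(d2.reshape(n_frames, -1).min(axis=1))
            per_res[rid] = ResidueActivity(
                residue_id=rid,
                n_contact_frames=int((min_d < cutoff_nm).sum()),
                n_total_frames=n_frames,
            )
        out.append(per_res)
    return out


def select_binding_site(
    activities: Iterable[Iterable[Mapping[int, ResidueActivity]]],
    threshold: float = 0.5,
) -> BindingSite:
    """Union, over all holo systems and runs, of residues with ratio > threshold.

    ``activities`` is an iterable over systems, each an iterable over runs of
    ``{residue_id: ResidueActivity}``.  The inequality is strict and the
    result is sorted ascending so the particle order is reproducible.
    """
    selected: set[int] = set()
    saw_any = False
    for per_system in activities:
        for per_run in per_system:
            saw_any = True
            for rid, act in per_run.items():
                if act.ratio > threshold:
                    selected.add(rid)
    if not saw_any:
        raise PreconditionError("no activity tables provided")
    if not selected:
        raise NoBindingSiteError(
            f"no residue exceeded activity ratio {threshold} in any run"
        )
    return BindingSite(residue_ids=tuple(sorted(selected)))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` minimizes the RMSD to
    ``reference``; ``R`` is a proper rotation (reflections excluded).
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise PreconditionError("mobile/reference must both be (n_atoms, 3)")
    if mobile.shape[0] < 3:
        raise DegenerateGeometryError("at least 3 fit atoms are required")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    ref_c = reference - cr
    sv = np.linalg.svd(ref_c, compute_uv=False)
    if sv[1] <= 1e-10 * max(sv[0], 1e-30):
        raise DegenerateGeometryError("reference fit atoms are (near-)collinear")
    h = (mobile - cm).T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    return rot, trans


def superpose_frames(
    traj: SystemTrajectory,
    reference_coords: np.ndarray,
    fit_atom_indices: Iterable[int],
) -> SystemTrajectory:
    """Rigidly fit every frame onto ``reference_coords`` over the fit atoms.

    The optimal rotation/translation is computed on ``fit_atom_indices``
    (typically the binding-site backbone) and applied to all atoms.
    ``reference_coords`` may be the full shared structure (n_atoms, 3) or
    just the fit-atom coordinates (n_fit, 3) in fit-index order — the
    latter allows one common reference across systems whose topologies
    differ away from the binding site.
    """
    fit_idx = np.asarray(sorted(set(int(i) for i in fit_atom_indices)), dtype=int)
    if fit_idx.size and (fit_idx.min() < 0 or fit_idx.max() >= traj.n_atoms):
        raise PreconditionError("fit atom index out of range")
    reference_coords = np.asarray(reference_coords, dtype=np.float64)
    if reference_coords.shape == (traj.n_atoms, 3):
        ref_fit = reference_coords[fit_idx]
    elif reference_coords.shape == (fit_idx.size, 3):
        ref_fit = reference_coords
    else:
        raise PreconditionError(
            f"reference must be ({traj.n_atoms}, 3) or ({fit_idx.size}, 3), "
            f"got {reference_coords.shape}"
        )

    new_runs = []
    for run in traj.runs:
        out = np.empty_like(run)
        for f in range(run.shape[0]):
            rot, trans = kabsch(run[f, fit_idx], ref_fit)
            out[f] = run[f] @ rot.T + trans
        new_runs.append(out)
    return dataclasses.replace(traj, runs=new_runs)


def residue_centers_of_mass(
    traj: SystemTrajectory,
    site: BindingSite,
    heavy_only: bool = True,
) -> ParticleTrajectory:
    """Reduce atoms to one mass-weighted center per binding-site residue."""
    if site.n_residues == 0:
        raise PreconditionError("binding site is empty")
    selections = []
    for rid in site.residue_ids:
        idx = traj.residue_atom_indices(rid, heavy_only=heavy_only)
        if idx.size == 0:
            raise PreconditionError(
                f"residue {rid} has no {'heavy ' if heavy_only else ''}atoms in "
                f"system {traj.system_id!r}"
            )
        masses = np.asarray([traj.atoms[i].mass for i in idx])
        selections.append((idx, masses / masses.sum()))

    runs = []
    for run in traj.runs:
        centers = np.empty((run.shape[0], site.n_residues, 3))
        for r, (idx, w) in enumerate(selections):
            centers[:, r, :] = np.einsum("fat,a->ft", run[:, idx, :], w)
        runs.append(centers)
    return ParticleTrajectory(
        system_id=traj.system_id,
        runs=runs,
        frame_interval_ps=traj.frame_interval_ps,
        residue_ids=site.residue_ids,
    )


def rmsf_per_residue(ptraj: ParticleTrajectory, burn_in_ps: float = 0.0) -> np.ndarray:
    """Root-mean-square fluctuation of each particle about its pooled mean.

    Frames from all runs after the burn-in are pooled before computing the
    time-mean; the RMSF is the 3D norm fluctuation, so an isotropic Gaussian
    with per-axis std s yields s*sqrt(3).
    """
    start = int(np.ceil(burn_in_ps / ptraj.frame_interval_ps))
    pooled = [run[start:] for run in ptraj.runs if run.shape[0] > start]
    if not pooled or sum(p.shape[0] for p in pooled) < 2:
        raise PreconditionError("fewer than 2 frames remain after burn-in")
    x = np.concatenate(pooled, axis=0)  # (F, n, 3)
    dev = x - x.mean(axis=0, keepdims=True)
    return np.sqrt((dev**2).sum(axis=2).mean(axis=0))


def activities_to_frame(
    activities: Mapping[str, list[dict[int, ResidueActivity]]],
    residue_names: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Flatten per-system/run activity tables to a tidy DataFrame for CSV export."""
    rows = []
    for system_id, per_system in activities.items():
        for run, per_run in enumerate(per_system):
            for rid, act in sorted(per_run.items()):
                rows.append(
                    {
                        "system_id": system_id,
                        "residue_id": rid,
                        "residue_name": (residue_names or {}).get(rid, ""),
                        "run": run,
                        "ratio": act.ratio,
                    }
                )
    return pd.DataFrame(rows)
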