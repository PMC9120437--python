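"""Local dynamics ensembles (LDEs).

An LDE window is the short-term displacement trace of the binding-site
particles from a time origin t0: entry k (k = 1..L, L = window/interval)
is r(t0 + k*delta) - r(t0).  The collection of such windows, swept over a
trajectory, is an empirical distribution over short-term local dynamics;
the Wasserstein stage compares these distributions between systems.

Ensembles are trajectory-backed: they keep the particle trajectory plus an
array of window origins and materialize displacement tensors on demand, so
dense training origins (one per frame) cost no memory.  An ensemble loaded
from an HDF5 displacement dump is "materialized" and behaves identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import h5py
import numpy as np

from .errors import PreconditionError
from .trajio import ParticleTrajectory

__all__ = [
    "LDEWindow",
    "LDEnsemble",
    "extract_window",
    "enumerate_windows",
    "dense_windows",
    "sample_training_batch",
    "protocol_window_count",
]


def _frames_from_time(t_ps: float, delta_ps: float, what: str) -> int:
    k = t_ps / delta_ps
    if abs(k - round(k)) > 1e-9:
        raise PreconditionError(f"{what} ({t_ps} ps) is not a multiple of the frame interval {delta_ps} ps")
    return int(round(k))


@dataclass(frozen=True)
class LDEWindow:
    """One short-term displacement window: (n_residues, L, 3) in nm."""

    displacements: np.ndarray
    origin_time_ps: float
    run_index: int

    def __post_init__(self) -> None:
        if self.displacements.ndim != 3 or self.displacements.shape[2] != 3:
            raise PreconditionError("displacements must be (n_residues, L, 3)")
        if not np.isfinite(self.displacements).all():
            raise PreconditionError("window contains non-finite displacements")


class LDEnsemble:
    """A system's empirical distribution of short-term displacement windows."""

    def __init__(
        self,
        system_id: str,
        frame_interval_ps: float,
        window_ps: float,
        burn_in_ps: float = 0.0,
        runs: Sequence[np.ndarray] | None = None,
        origins: np.ndarray | None = None,
        displacements: np.ndarray | None = None,
    ):
        self.system_id = system_id
        self.frame_interval_ps = float(frame_interval_ps)
        self.window_ps = float(window_ps)
        self.burn_in_ps = float(burn_in_ps)
        self.lags = _frames_from_time(window_ps, frame_interval_ps, "window length")
        if self.lags < 1:
            raise PreconditionError("window must span at least one frame interval")
        self._runs = [np.asarray(r, dtype=np.float64) for r in runs] if runs is not None else None
        self._displacements = displacements
        if displacements is not None:
            origins = np.zeros((displacements.shape[0], 2), dtype=int) if origins is None else origins
        if origins is None or len(origins) == 0:
            raise PreconditionError(f"ensemble for {system_id!r} is empty")
        self.origins = np.asarray(origins, dtype=int)

    # -- shape contract -------------------------------------------------
    @property
    def n_windows(self) -> int:
        return self.origins.shape[0]

    @property
    def n_residues(self) -> int:
        if self._displacements is not None:
            return self._displacements.shape[1]
        return self._runs[0].shape[1]

    @property
    def window_shape(self) -> tuple[int, int, int]:
        return (self.n_residues, self.lags, 3)

    @property
    def flat_dim(self) -> int:
        n, L, d = self.window_shape
        return n * L * d

    # -- materialization ------------------------------------------------
    def windows(self, indices: np.ndarray | None = None) -> np.ndarray:
        """Displacement tensors, shape (W, n_residues, L, 3)."""
        if indices is None:
            indices = np.arange(self.n_windows)
        indices = np.asarray(indices, dtype=int)
        if self._displacements is not None:
            return self._displacements[indices]
        L = self.lags
        out = np.empty((indices.size, self.n_residues, L, 3))
        sel = self.origins[indices]
        for run_idx in np.unique(sel[:, 0]):
            mask = sel[:, 0] == run_idx
            o = sel[mask, 1]
            run = self._runs[run_idx]
            idx = o[:, None] + np.arange(1, L + 1)[None, :]
            disp = run[idx] - run[o][:, None, :, :]  # (B, L, n, 3)
            out[mask] = disp.transpose(0, 2, 1, 3)
        return out

    def window(self, i: int) -> LDEWindow:
        run_idx, frame = self.origins[i]
        return LDEWindow(
            displacements=self.windows(np.asarray([i]))[0],
            origin_time_ps=float(frame) * self.frame_interval_ps,
            run_index=int(run_idx),
        )

    def origin_times_ps(self) -> np.ndarray:
        return self.origins[:, 1].astype(float) * self.frame_interval_ps

    def sample_windows(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Uniform with-replacement draw of windows (by run and origin frame)."""
        idx = rng.integers(0, self.n_windows, size=size)
        return self.windows(idx)

    # -- persistence ----------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as h5:
            h5.create_dataset("displacements", data=self.windows())
            h5.create_dataset("origins", data=self.origins)
            h5.attrs["system_id"] = self.system_id
            h5.attrs["delta_ps"] = self.frame_interval_ps
            h5.attrs["window_ps"] = self.window_ps
            h5.attrs["burn_in_ps"] = self.burn_in_ps

    @classmethod
    def from_hdf5(cls, path) -> "LDEnsemble":
        with h5py.File(path, "r") as h5:
            return cls(
                system_id=str(h5.attrs["system_id"]),
                frame_interval_ps=float(h5.attrs["delta_ps"]),
                window_ps=float(h5.attrs["window_ps"]),
                burn_in_ps=float(h5.attrs["burn_in_ps"]),
                displacements=h5["displacements"][()],
                origins=h5["origins"][()],
            )


def extract_window(
    ptraj: ParticleTrajectory,
    t0_ps: float,
    window_ps: float,
    run_index: int = 0,
) -> LDEWindow:
    """Displacements r(t0 + k*delta) - r(t0), k = 1..window/delta, one run."""
    delta = ptraj.frame_interval_ps
    o = _frames_from_time(t0_ps, delta, "origin time")
    L = _frames_from_time(window_ps, delta, "window length")
    run = ptraj.runs[run_index]
    if o < 0 or o + L > run.shape[0] - 1:
        raise PreconditionError(
            f"window [{t0_ps}, {t0_ps + window_ps}] ps does not fit inside run "
            f"{run_index} ({run.shape[0]} frames); windows never span runs"
        )
    disp = run[o + 1 : o + L + 1] - run[o]  # (L, n, 3)
    return LDEWindow(
        displacements=disp.transpose(1, 0, 2), origin_time_ps=float(t0_ps), run_index=run_index
    )


def _origin_table(
    ptraj: ParticleTrajectory, lags: int, stride_frames: int, burn_frames: int
) -> np.ndarray:
    origins = []
    for run_idx, run in enumerate(ptraj.runs):
        last = run.shape[0] - 1 - lags
        for o in range(burn_frames, last + 1, stride_frames):
            origins.append((run_idx, o))
    if not origins:
        raise PreconditionError("no window fits inside any run (burn-in too large or window too long)")
    return np.asarray(origins, dtype=int)


def enumerate_windows(
    ptraj: ParticleTrajectory,
    window_ps: float,
    stride_ps: float,
    burn_in_ps: float = 0.0,
) -> LDEnsemble:
    """Deterministic sweep of origins: burn_in, burn_in + stride, ... per run."""
    delta = ptraj.frame_interval_ps
    lags = _frames_from_time(window_ps, delta, "window length")
    stride = _frames_from_time(stride_ps, delta, "stride")
    if stride < 1:
        raise PreconditionError("stride must be at least one frame interval")
    burn = int(np.ceil(burn_in_ps / delta - 1e-9))
    origins = _origin_table(ptraj, lags, stride, burn)
    return LDEnsemble(
        system_id=ptraj.system_id,
        frame_interval_ps=delta,
        window_ps=window_ps,
        burn_in_ps=burn_in_ps,
        runs=ptraj.runs,
        origins=origins,
    )


def dense_windows(ptraj: ParticleTrajectory, window_ps: float, burn_in_ps: float = 0.0) -> LDEnsemble:
    """Ensemble with one origin per post-burn-in frame (training-time sampling pool)."""
    return enumerate_windows(ptraj, window_ps, ptraj.frame_interval_ps, burn_in_ps)


def sample_training_batch(
    ensemble_i: LDEnsemble,
    ensemble_j: LDEnsemble,
    batch_size: int,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One minibatch per side: uniform random (run, origin) with replacement."""
    if batch_size < 1:
        raise PreconditionError("batch_size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return (
        ensemble_i.sample_windows(rng, batch_size),
        ensemble_j.sample_windows(rng, batch_size),
    )


def protocol_window_count(
    n_runs: int,
    run_length_ps: float,
    frame_interval_ps: float,
    window_ps: float,
    stride_ps: float | None = None,
    burn_in_ps: float = 0.0,
) -> int:
    """Number of windows a recording protocol yields, without materializing it.

    A run of ``run_length_ps`` recorded every ``frame_interval_ps`` holds
    run_length/interval frames; origins sweep from the burn-in at the given
    stride (default: every frame) while the window fits.
    """
    delta = frame_interval_ps
    frames = _frames_from_time(run_length_ps, delta, "run length")
    lags = _frames_from_time(window_ps, delta, "window length")
    stride = _frames_from_time(stride_ps, delta, "stride") if stride_ps is not None else 1
    burn = int(np.ceil(burn_in_ps / delta - 1e-9))
    last = frames - 1 - lags
    if last < burn:
        return 0
    per_run = (last - burn) // stride + 1
    return n_runs * per_run
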