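"""Residue-level interpretation of a pairwise dynamics difference.

For an ordered pair (i, j) the per-window statistic

    g_ij(x_i) = f_ij(x_i) - E_{x ~ y_j}[f_ij(x)]

scores how distinctive one short-term window of system i is relative to
system j's average local dynamics; its mean over system-i windows equals
the critic-gap W1 estimate on the same samples.  Windows in the top /
bottom quantile of g form the "characteristic" / "similar" groups, and a
per-residue mean displacement norm over a lag range [T0, T] computed in
each group localizes the difference: residues with a large gap between
the characteristic and similar groups are the ones the ligand influences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .critic import Critic
from .errors import DegenerateDistributionError, PreconditionError
from .lde import LDEnsemble

__all__ = [
    "GSeries",
    "CharacteristicPartition",
    "ResidueDisplacementTable",
    "compute_g",
    "classify_windows",
    "short_term_displacement",
    "displacement_table",
    "rank_residues",
]

DEFAULT_REFERENCE_SUBSAMPLE = 8192


@dataclass
class GSeries:
    """g values of every evaluation window of system i against reference j."""

    ordered_pair: tuple[str, str]
    g_values: np.ndarray
    reference_mean: float
    origin_times_ps: np.ndarray | None = None
    run_indices: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"g": self.g_values}
        if self.origin_times_ps is not None:
            data["origin_time_ps"] = self.origin_times_ps
        if self.run_indices is not None:
            data["run"] = self.run_indices
        return pd.DataFrame(data)


@dataclass
class CharacteristicPartition:
    """Quantile split of evaluation windows into characteristic/middle/similar."""

    g_upper: float
    g_lower: float
    characteristic: np.ndarray  # window indices, X^C
    middle: np.ndarray  # X^M
    similar: np.ndarray  # X^S
    fraction: float

    @property
    def group_sizes(self) -> dict[str, int]:
        return {
            "characteristic": self.characteristic.size,
            "middle": self.middle.size,
            "similar": self.similar.size,
        }


@dataclass
class ResidueDisplacementTable:
    """Per-residue mean short-term displacement norms per window group."""

    residue_ids: tuple[int, ...]
    d_characteristic: np.ndarray
    d_middle: np.ndarray
    d_similar: np.ndarray
    group_sizes: dict[str, int]
    t0_ps: float
    t_ps: float

    def to_frame(self) -> pd.DataFrame:
        gap = np.abs(self.d_characteristic - self.d_similar)
        order = np.argsort(-gap, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(1, order.size + 1)
        return pd.DataFrame(
            {
                "residue_id": self.residue_ids,
                "d_characteristic": self.d_characteristic,
                "d_middle": self.d_middle,
                "d_similar": self.d_similar,
                "gap": gap,
                "rank": rank,
            }
        )


def compute_g(
    critic: Critic,
    eval_ensemble: LDEnsemble,
    reference_ensemble: LDEnsemble,
    reference_subsample: int = DEFAULT_REFERENCE_SUBSAMPLE,
    seed: int = 0,
    mean_input: bool = False,
) -> GSeries:
    """g(x_i) = f(x_i) - E_j[f] for every evaluation window of system i.

    The reference expectation is computed once over a fixed seeded
    subsample of system-j windows (all of them if fewer) and reused for
    every evaluation window.  ``mean_input=True`` instead feeds the mean
    reference window through the critic (an alternative reading of the
    protocol; not the default).
    """
    if reference_ensemble.n_windows == 0:
        raise PreconditionError("reference ensemble is empty")
    if eval_ensemble.flat_dim != critic.config.input_dim:
        raise PreconditionError(
            f"window dimension {eval_ensemble.flat_dim} does not match critic "
            f"input {critic.config.input_dim}"
        )
    if reference_ensemble.n_windows <= reference_subsample:
        ref = reference_ensemble.windows()
    else:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        ref = reference_ensemble.sample_windows(rng, reference_subsample)
    if mean_input:
        reference_mean = float(critic.forward(ref.mean(axis=0, keepdims=True))[0])
    else:
        reference_mean = float(critic.forward(ref).mean())
    f_eval = critic.forward(eval_ensemble.windows())
    return GSeries(
        ordered_pair=(eval_ensemble.system_id, reference_ensemble.system_id),
        g_values=f_eval - reference_mean,
        reference_mean=reference_mean,
        origin_times_ps=eval_ensemble.origin_times_ps(),
        run_indices=eval_ensemble.origins[:, 0].copy(),
    )


def classify_windows(g_series: GSeries, fraction: float = 0.10) -> CharacteristicPartition:
    """Quantile partition of windows by g (ties join the extreme groups)."""
    if not 0 < fraction <= 0.5:
        raise PreconditionError("fraction must be in (0, 0.5]")
    g = np.asarray(g_series.g_values, dtype=float)
    if g.size < int(np.ceil(2.0 / fraction)):
        raise PreconditionError(
            f"need at least {int(np.ceil(2.0 / fraction))} windows for fraction {fraction}"
        )
    if np.ptp(g) == 0:
        raise DegenerateDistributionError("all g values are identical")
    g_lower = float(np.quantile(g, fraction))
    g_upper = float(np.quantile(g, 1.0 - fraction))
    characteristic = np.nonzero(g >= g_upper)[0]
    in_char = np.zeros(g.size, dtype=bool)
    in_char[characteristic] = True
    similar = np.nonzero((g <= g_lower) & ~in_char)[0]
    in_sim = np.zeros(g.size, dtype=bool)
    in_sim[similar] = True
    middle = np.nonzero(~in_char & ~in_sim)[0]
    return CharacteristicPartition(
        g_upper=g_upper,
        g_lower=g_lower,
        characteristic=characteristic,
        middle=middle,
        similar=similar,
        fraction=fraction,
    )


def short_term_displacement(
    ensemble: LDEnsemble,
    window_indices: np.ndarray,
    t0_ps: float,
    t_ps: float,
) -> np.ndarray:
    """Per-residue mean displacement norm over lags T0..T within a window group.

    For each residue the displacement norms ||r(t + lag) - r(t)|| at lags
    T0, T0 + delta, ..., T are averaged over the lag terms and over the
    group's windows.  Normalization is by the count of discrete lag terms.
    """
    window_indices = np.asarray(window_indices, dtype=int)
    if window_indices.size == 0:
        raise PreconditionError("window group is empty")
    delta = ensemble.frame_interval_ps
    k0 = t0_ps / delta
    k1 = t_ps / delta
    if abs(k0 - round(k0)) > 1e-9 or abs(k1 - round(k1)) > 1e-9:
        raise PreconditionError("T0 and T must be multiples of the frame interval")
    k0, k1 = int(round(k0)), int(round(k1))
    if not (1 <= k0 < k1 <= ensemble.lags):
        raise PreconditionError(
            f"lag bounds [{t0_ps}, {t_ps}] ps must satisfy 0 < T0 < T <= window "
            f"({ensemble.window_ps} ps)"
        )
    disp = ensemble.windows(window_indices)  # (W, n, L, 3)
    norms = np.sqrt((disp[:, :, k0 - 1 : k1, :] ** 2).sum(axis=3))
    return norms.mean(axis=(0, 2))


def displacement_table(
    ensemble: LDEnsemble,
    partition: CharacteristicPartition,
    t0_ps: float,
    t_ps: float,
    residue_ids: tuple[int, ...] | None = None,
) -> ResidueDisplacementTable:
    """Eq.-style per-residue displacement statistics for all three groups."""
    n = ensemble.n_residues
    rids = residue_ids if residue_ids is not None else tuple(range(n))
    if len(rids) != n:
        raise PreconditionError("residue id list does not match particle count")

    def group_d(idx: np.ndarray) -> np.ndarray:
        if idx.size == 0:
            return np.full(n, np.nan)
        return short_term_displacement(ensemble, idx, t0_ps, t_ps)

    return ResidueDisplacementTable(
        residue_ids=tuple(int(r) for r in rids),
        d_characteristic=group_d(partition.characteristic),
        d_middle=group_d(partition.middle),
        d_similar=group_d(partition.similar),
        group_sizes=partition.group_sizes,
        t0_ps=t0_ps,
        t_ps=t_ps,
    )


def rank_residues(
    d_characteristic: np.ndarray | ResidueDisplacementTable,
    d_similar: np.ndarray | None = None,
    residue_ids: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Residues sorted by descending |d_C - d_S| gap (stable on ties)."""
    if isinstance(d_characteristic, ResidueDisplacementTable):
        table = d_characteristic
        dc, ds = table.d_characteristic, table.d_similar
        rids = table.residue_ids
    else:
        dc = np.asarray(d_characteristic, dtype=float)
        ds = np.asarray(d_similar, dtype=float)
        if dc.shape != ds.shape:
            raise PreconditionError("characteristic/similar tables cover different residues")
        rids = residue_ids if residue_ids is not None else tuple(range(dc.size))
        if len(rids) != dc.size:
            raise PreconditionError("residue id list does not match table size")
    gap = np.abs(dc - ds)
    order = np.argsort(-gap, kind="stable")
    return pd.DataFrame(
        {
            "residue_id": [rids[i] for i in order],
            "d_characteristic": dc[order],
            "d_similar": ds[order],
            "gap": gap[order],
            "rank": np.arange(1, gap.size + 1),
        }
    )
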