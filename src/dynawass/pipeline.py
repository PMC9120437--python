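"""End-to-end orchestration from a single YAML config.

Stages: load (or synthesize) systems -> binding-site selection and
reduction to particle trajectories -> local dynamics ensembles ->
all-pairs Wasserstein distance matrix -> stress embedding + PCA +
affinity correlation -> residue-level interpretation of a chosen pair.
Every stage writes its outputs under the run directory and the whole run
is summarized in ``summary.json``.

All randomness derives from one global seed; stage s uses the seed
SeedSequence([seed, s]).  The distance matrix and its critics are cached
keyed by a hash of the stage-relevant configuration, so re-running with
an unchanged config reuses them bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Any, Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import lde, synthetic, trajio, wdist
from .critic import Critic, CriticConfig
from .embed import EmbeddingConfig, embed_distances, pca_project, pearson
from .errors import ConfigurationError, PreconditionError
from .interpret import classify_windows, compute_g, displacement_table, rank_residues
from .trajio import BindingSite, ParticleTrajectory

logger = logging.getLogger("dynawass")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "PRESETS"]

#: Stage parameter presets.  "paper" carries the published protocol values
#: (128 ps windows, 50 ns burn-in, 2048-wide critic, 500k steps, 64 ps
#: evaluation stride, 10% quantiles, 3 embedding dimensions); "desk" is a
#: reduced configuration for single-CPU runs on the synthetic benchmark.
PRESETS: dict[str, dict[str, dict[str, Any]]] = {
    "paper": {
        "lde": {"window_ps": 128.0, "burn_in_ps": 50_000.0, "eval_stride_ps": 64.0},
        "wdist": {
            "hidden_widths": (2048, 2048, 2048),
            "max_steps": 500_000,
            "avg_window_steps": 10_000,
        },
        "embed": {"dims": 3, "n_restarts": 32},
        "interpret": {"fraction": 0.10, "t0_ps": 32.0, "t_ps": 128.0},
    },
    "desk": {
        "lde": {"window_ps": 16.0, "burn_in_ps": 0.0, "eval_stride_ps": 64.0},
        "wdist": {
            "hidden_widths": (128, 128, 128),
            "max_steps": 4_000,
            "avg_window_steps": 500,
        },
        "embed": {"dims": 3, "n_restarts": 16},
        "interpret": {"fraction": 0.10, "t0_ps": 4.0, "t_ps": 16.0},
    },
}


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class SystemEntry(_Block):
    id: str
    apo: bool = False
    fixture: Optional[str] = None  # HDF5 particle trajectory
    topology: Optional[str] = None
    coordinates: tuple[str, ...] = ()
    ligand_selection: Optional[str] = None
    binding_energy: Optional[float] = None

    @model_validator(mode="after")
    def _one_source(self):
        if (self.fixture is None) == (self.topology is None):
            raise ValueError(f"system {self.id!r}: give exactly one of fixture or topology")
        return self


class TrajioParams(_Block):
    cutoff_nm: float = Field(0.5, gt=0)
    activity_threshold: float = Field(0.5, ge=0, lt=1)
    analysis_window_ps: float = Field(200_000.0, gt=0)
    binding_site: Optional[tuple[int, ...]] = None  # skip selection when given
    heavy_only: bool = True


class LDEParams(_Block):
    window_ps: Optional[float] = Field(None, gt=0)
    burn_in_ps: Optional[float] = Field(None, ge=0)
    eval_stride_ps: Optional[float] = Field(None, gt=0)


class WdistParams(_Block):
    hidden_widths: Optional[tuple[int, ...]] = None
    leaky_slope: float = Field(0.01, gt=0, lt=1)
    learning_rate: float = Field(1e-4, gt=0)
    adam_beta1: float = Field(0.5, gt=0, lt=1)
    adam_beta2: float = Field(0.9, gt=0, lt=1)
    batch_size: int = Field(64, ge=1)
    gp_coefficient: float = Field(50.0, ge=0)
    max_steps: Optional[int] = Field(None, ge=1)
    avg_window_steps: Optional[int] = Field(None, ge=1)
    convergence_rel_tol: float = Field(1e-3, gt=0)


class EmbedParams(_Block):
    dims: Optional[int] = Field(None, ge=1)
    n_restarts: Optional[int] = Field(None, ge=1)
    sa_steps: int = Field(2000, ge=0)
    sa_cooling_factor: float = Field(0.995, gt=0, lt=1)
    gd_learning_rate: float = Field(1e-2, gt=0)
    gd_steps: int = Field(5000, ge=1)


class InterpretParams(_Block):
    fraction: Optional[float] = Field(None, gt=0, lt=0.5)
    t0_ps: Optional[float] = Field(None, gt=0)
    t_ps: Optional[float] = Field(None, gt=0)
    reference_subsample: int = Field(8192, ge=1)
    pair: Optional[tuple[str, str]] = None  # default: apo vs PC1-extreme holo


class SyntheticParams(_Block):
    scale_factors: tuple[float, ...] = synthetic.DEFAULT_SCALE_FACTORS
    key_residues: tuple[int, ...] = synthetic.DEFAULT_KEY_RESIDUES
    n_residues: int = Field(10, ge=1)
    stiffness_ps: float = Field(0.05, gt=0)
    sigma_nm_sqrt_ps: float = Field(0.1, ge=0)
    frame_interval_ps: float = Field(2.0, gt=0)
    frames_per_run: int = Field(50_000, ge=2)
    n_runs: int = Field(2, ge=1)
    affinity_coefficient: float = Field(1.0, gt=0)


class PipelineConfig(_Block):
    model_config = ConfigDict(extra="forbid", frozen=False)

    seed: int = 0
    out_dir: str = "dynawass_out"
    preset: Literal["paper", "desk"] = "desk"
    systems: tuple[SystemEntry, ...] = ()
    energies_csv: Optional[str] = None
    synthetic: Optional[SyntheticParams] = None
    trajio: TrajioParams = TrajioParams()
    lde: LDEParams = LDEParams()
    wdist: WdistParams = WdistParams()
    embed: EmbedParams = EmbedParams()
    interpret: InterpretParams = InterpretParams()

    @model_validator(mode="after")
    def _check_systems(self):
        if self.synthetic is None:
            if not self.systems:
                raise ValueError("either a systems manifest or a synthetic block is required")
            n_apo = sum(s.apo for s in self.systems)
            if n_apo != 1:
                raise ValueError(f"exactly one system must be flagged apo, found {n_apo}")
            ids = [s.id for s in self.systems]
            if len(set(ids)) != len(ids):
                raise ValueError("duplicate system ids")
        return self

    # -- preset resolution ---------------------------------------------
    def _preset(self, stage: str, key: str):
        return PRESETS[self.preset][stage][key]

    def lde_resolved(self) -> dict[str, float]:
        p = self.lde
        return {
            "window_ps": p.window_ps if p.window_ps is not None else self._preset("lde", "window_ps"),
            "burn_in_ps": p.burn_in_ps if p.burn_in_ps is not None else self._preset("lde", "burn_in_ps"),
            "eval_stride_ps": p.eval_stride_ps
            if p.eval_stride_ps is not None
            else self._preset("lde", "eval_stride_ps"),
        }

    def critic_config(self, input_dim: int) -> CriticConfig:
        widths = self.wdist.hidden_widths or self._preset("wdist", "hidden_widths")
        return CriticConfig(
            input_dim=input_dim, hidden_widths=tuple(widths), leaky_slope=self.wdist.leaky_slope
        )

    def train_config(self, seed: int) -> wdist.TrainConfig:
        p = self.wdist
        return wdist.TrainConfig(
            learning_rate=p.learning_rate,
            adam_beta1=p.adam_beta1,
            adam_beta2=p.adam_beta2,
            batch_size=p.batch_size,
            gp_coefficient=p.gp_coefficient,
            max_steps=p.max_steps if p.max_steps is not None else self._preset("wdist", "max_steps"),
            avg_window_steps=p.avg_window_steps
            if p.avg_window_steps is not None
            else self._preset("wdist", "avg_window_steps"),
            convergence_rel_tol=p.convergence_rel_tol,
            seed=seed,
        )

    def embedding_config(self, seed: int) -> EmbeddingConfig:
        p = self.embed
        return EmbeddingConfig(
            dims=p.dims if p.dims is not None else self._preset("embed", "dims"),
            n_restarts=p.n_restarts
            if p.n_restarts is not None
            else self._preset("embed", "n_restarts"),
            sa_steps=p.sa_steps,
            sa_cooling_factor=p.sa_cooling_factor,
            gd_learning_rate=p.gd_learning_rate,
            gd_steps=p.gd_steps,
            seed=seed,
        )

    def interpret_resolved(self) -> dict[str, Any]:
        p = self.interpret
        return {
            "fraction": p.fraction if p.fraction is not None else self._preset("interpret", "fraction"),
            "t0_ps": p.t0_ps if p.t0_ps is not None else self._preset("interpret", "t0_ps"),
            "t_ps": p.t_ps if p.t_ps is not None else self._preset("interpret", "t_ps"),
            "reference_subsample": p.reference_subsample,
            "pair": p.pair,
        }


def validate_config(path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config, reporting all violations."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file {path} does not exist")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except Exception as exc:  # pydantic collects all violations in one error
        raise ConfigurationError(str(exc)) from exc


def _stage_seed(global_seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([global_seed, stage]).generate_state(1)[0] % (2**31))


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _load_systems(config: PipelineConfig, out: Path):
    """Returns (particle trajectories by id, apo id, energies by id)."""
    energies: dict[str, float] = {}
    if config.energies_csv:
        df = pd.read_csv(config.energies_csv)
        energies = dict(zip(df["system_id"].astype(str), df["delta_g_kcal_per_mol"]))

    if config.synthetic is not None:
        sp = config.synthetic
        suite = synthetic.make_benchmark_suite(
            scale_factors=sp.scale_factors,
            key_residues=sp.key_residues,
            base_spec=synthetic.OUSystemSpec(
                system_id="S0",
                n_residues=sp.n_residues,
                stiffness_ps=sp.stiffness_ps,
                sigma_nm_sqrt_ps=sp.sigma_nm_sqrt_ps,
                frame_interval_ps=sp.frame_interval_ps,
                frames_per_run=sp.frames_per_run,
                n_runs=sp.n_runs,
            ),
            affinity_coefficient=sp.affinity_coefficient,
            seed=_stage_seed(config.seed, 0),
        )
        suite.write_fixtures(out / "fixtures")
        ptrajs = suite.simulate()
        if not energies:
            energies = dict(
                zip(suite.affinities["system_id"], suite.affinities["delta_g_kcal_per_mol"])
            )
        return ptrajs, "S0", energies

    ptrajs: dict[str, ParticleTrajectory] = {}
    apo_id = next(s.id for s in config.systems if s.apo)
    raw_entries = [s for s in config.systems if s.topology is not None]
    fixtures = [s for s in config.systems if s.fixture is not None]
    for entry in fixtures:
        pt = ParticleTrajectory.from_hdf5(entry.fixture)
        pt.system_id = entry.id
        ptrajs[entry.id] = pt
        if entry.binding_energy is not None:
            energies[entry.id] = entry.binding_energy

    if raw_entries:
        ptrajs.update(_reduce_raw_systems(config, raw_entries, apo_id))
        for entry in raw_entries:
            if entry.binding_energy is not None:
                energies[entry.id] = entry.binding_energy
    return ptrajs, apo_id, energies


def _reduce_raw_systems(config: PipelineConfig, entries, apo_id):
    """Topology+coordinates route: select site, superpose, reduce to centers."""
    tp = config.trajio
    ldep = config.lde_resolved()
    trajs = {
        e.id: trajio.load_trajectory(
            e.topology,
            e.coordinates or None,
            frame_interval_ps=None,
            system_id=e.id,
            ligand_selection=e.ligand_selection,
        )
        for e in entries
    }
    if tp.binding_site is not None:
        site = BindingSite(residue_ids=tuple(tp.binding_site))
    else:
        holo = [t for sid, t in trajs.items() if sid != apo_id and t.ligand_atom_indices]
        if not holo:
            raise ConfigurationError("no holo system with a ligand selection to select the site from")
        candidate = sorted(
            {a.residue_id for t in holo for a in t.atoms if a.atom_index not in t.ligand_atom_indices}
        )
        acts = [
            trajio.compute_activity_ratio(t, candidate, tp.cutoff_nm, tp.analysis_window_ps)
            for t in holo
        ]
        site = trajio.select_binding_site(acts, tp.activity_threshold)
        logger.info("selected binding site: %s", site.residue_ids)

    apo = trajs.get(apo_id)
    if apo is None:
        raise ConfigurationError("raw-trajectory runs need the apo system among the raw entries")
    # common reference: first post-burn-in apo frame, run 1, binding-site backbone
    burn_frames = int(np.ceil(ldep["burn_in_ps"] / apo.frame_interval_ps))
    burn_frames = min(burn_frames, apo.runs[0].shape[0] - 1)
    ref_frame = apo.runs[0][burn_frames]

    def backbone_indices(traj):
        idx = [
            a.atom_index
            for a in traj.atoms
            if a.residue_id in site.residue_ids
            and a.is_backbone
            and a.atom_index not in traj.ligand_atom_indices
        ]
        return np.asarray(idx, dtype=int)

    apo_fit = backbone_indices(apo)
    ref_fit_coords = ref_frame[apo_fit]
    out = {}
    for sid, traj in trajs.items():
        fit_idx = backbone_indices(traj)
        if fit_idx.size != apo_fit.size:
            raise PreconditionError(
                f"system {sid!r} has {fit_idx.size} binding-site backbone atoms, "
                f"apo has {apo_fit.size}; the particle set must match across systems"
            )
        fitted = trajio.superpose_frames(traj, ref_fit_coords, fit_idx)
        out[sid] = trajio.residue_centers_of_mass(fitted, site, heavy_only=tp.heavy_only)
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns the summary dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "cache").mkdir(exist_ok=True)
    ldep = config.lde_resolved()

    ptrajs, apo_id, energies = _load_systems(config, out)
    ids = list(ptrajs)
    ids.sort(key=lambda s: (s != apo_id, s))  # apo first, then lexical
    logger.info("systems: %s (apo=%s)", ids, apo_id)

    train_ens = {
        sid: lde.dense_windows(ptrajs[sid], ldep["window_ps"], ldep["burn_in_ps"]) for sid in ids
    }
    eval_ens = {
        sid: lde.enumerate_windows(
            ptrajs[sid], ldep["window_ps"], ldep["eval_stride_ps"], ldep["burn_in_ps"]
        )
        for sid in ids
    }

    # ---- distance matrix (cached) ------------------------------------
    wseed = _stage_seed(config.seed, 1)
    whash = _config_hash(
        {
            "systems": ids,
            "lde": ldep,
            "wdist": self_dict(config.wdist),
            "preset": config.preset,
            "seed": wseed,
        }
    )
    matrix_path = out / "cache" / f"distance_matrix_{whash}.csv"
    critic_dir = out / "cache" / f"critics_{whash}"
    pair_critics: dict[tuple[str, str], Critic] = {}
    if matrix_path.exists():
        logger.info("reusing cached distance matrix %s", matrix_path)
        matrix = wdist.DistanceMatrix.from_csv(matrix_path)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                pair_critics[(a, b)] = Critic.from_npz(critic_dir / f"{a}__{b}.npz")
    else:
        first = train_ens[ids[0]]
        critic_cfg = config.critic_config(first.flat_dim)
        train_cfg = config.train_config(wseed)
        matrix, pairs = wdist.distance_matrix(
            [train_ens[sid] for sid in ids], critic_cfg, train_cfg
        )
        matrix.to_csv(matrix_path)
        critic_dir.mkdir(exist_ok=True)
        for (a, b), res in pairs.items():
            pair_critics[(a, b)] = res.critic
            res.critic.to_npz(critic_dir / f"{a}__{b}.npz")
            pd.DataFrame({"step": np.arange(res.steps_run), "gap": res.training_curve}).to_csv(
                out / "cache" / f"curve_{whash}_{a}__{b}.csv", index=False
            )
    matrix.to_csv(out / "distance_matrix.csv")

    # ---- embedding + PCA + correlation -------------------------------
    eseed = _stage_seed(config.seed, 2)
    emb = embed_distances(matrix, config.embedding_config(eseed))
    apo_index = ids.index(apo_id)
    feat = pca_project(emb.points, reference_index=apo_index)
    coords = pd.DataFrame(
        emb.points, index=ids, columns=[f"x{i + 1}" for i in range(emb.points.shape[1])]
    )
    coords.index.name = "system_id"
    coords.to_csv(out / "embedding.csv")
    scores = pd.DataFrame(feat.pc_scores, index=ids, columns=["PC1", "PC2"])
    scores.index.name = "system_id"
    scores["explained_variance_fraction_pc1"] = feat.explained_variance_fractions[0]
    scores["explained_variance_fraction_pc2"] = feat.explained_variance_fractions[1]
    scores.to_csv(out / "pc_scores.csv")

    pearson_r = None
    holo_with_energy = [sid for sid in ids if sid != apo_id and sid in energies]
    if len(holo_with_energy) >= 3:
        pc1 = np.asarray([scores.loc[sid, "PC1"] for sid in holo_with_energy])
        dg = np.asarray([energies[sid] for sid in holo_with_energy])
        pearson_r = pearson(pc1, dg)
        with open(out / "correlation.json", "w") as fh:
            json.dump({"pearson_r": pearson_r, "n_systems": len(holo_with_energy)}, fh)
    else:
        warnings.warn(
            "binding energies missing or too few holo systems; correlation skipped",
            stacklevel=2,
        )

    # ---- interpretation ----------------------------------------------
    intp = config.interpret_resolved()
    pair = intp["pair"]
    if pair is None:
        holo_ids = [sid for sid in ids if sid != apo_id]
        far = max(holo_ids, key=lambda sid: abs(scores.loc[sid, "PC1"] - scores.loc[apo_id, "PC1"]))
        pair = (apo_id, far)
    i_id, j_id = pair
    key = (i_id, j_id) if (i_id, j_id) in pair_critics else (j_id, i_id)
    gseries = compute_g(
        pair_critics[key],
        eval_ens[i_id],
        train_ens[j_id],
        reference_subsample=intp["reference_subsample"],
        seed=_stage_seed(config.seed, 3),
    )
    gseries.to_frame().to_csv(out / f"g_series_{i_id}_vs_{j_id}.csv", index=False)
    partition = classify_windows(gseries, intp["fraction"])
    table = displacement_table(
        eval_ens[i_id],
        partition,
        intp["t0_ps"],
        intp["t_ps"],
        residue_ids=ptrajs[i_id].residue_ids,
    )
    table.to_frame().to_csv(out / f"residue_table_{i_id}_vs_{j_id}.csv", index=False)
    ranking = rank_residues(table)
    pd.DataFrame(
        [
            {
                "group": name,
                "size": size,
                "g_lower": partition.g_lower,
                "g_upper": partition.g_upper,
            }
            for name, size in partition.group_sizes.items()
        ]
    ).to_csv(out / f"partition_{i_id}_vs_{j_id}.csv", index=False)

    summary = {
        "n_systems": len(ids),
        "system_ids": ids,
        "apo_id": apo_id,
        "stress": emb.stress,
        "pearson_r": pearson_r,
        "interpreted_pair": list(pair),
        "top_residues": [int(r) for r in ranking["residue_id"].head(3)],
        "pc1": {sid: float(scores.loc[sid, "PC1"]) for sid in ids},
        "preset": config.preset,
        "seed": config.seed,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("summary: %s", summary)
    return summary


def self_dict(model: BaseModel) -> dict:
    return json.loads(model.model_dump_json())
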