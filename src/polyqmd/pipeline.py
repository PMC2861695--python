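"""End-to-end analysis pipeline: build → replex → WHAM → screen → SS → cluster.

One :class:`RunConfig` drives the whole study of a single polypeptide
model. Every stage's table is written as TSV stamped with the config hash
and seed, so re-running the same configuration reproduces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as qio
from .cluster import (DEFAULT_MIN_SEPARATION_TU, DEFAULT_RMSD_CUTOFF,
                      DELTA_POLYP_Q47_CUTOFF, DistanceMatrix, single_linkage,
                      subsample_frames)
from .constructs import ConstructKind, ConstructModel, build_construct
from .dmd import DEFAULT_EQUILIBRATION_TU, ForceField
from .replex import DEFAULT_TEMPERATURES, ReplexResult, ReplicaSchedule, \
    run_replex
from .screen import (CompactEnsemble, ScreenHistogram, ScreenVariable,
                     count_crossings, propose_energy_cutoff,
                     propose_rg_cutoff, select_compact)
from .secstruct import SSProfile, region_average, \
    ss_probability_profile
from .units import temperature_to_kelvin
from .wham import (find_transition, heat_capacity, histogram_energies,
                   solve_wham)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one model's simulation + analysis."""

    construct: str = "XN1"
    n_repeats: int = 23
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    swap_interval: float = 500.0
    duration: float = 1.0e6
    save_interval: float = 10.0
    equilibration_tu: float = DEFAULT_EQUILIBRATION_TU
    rg_cutoff: float | None = None         # None: propose from histogram
    energy_cutoff: float | None = None     # None: propose from mixture fit
    ppii: bool = False
    rmsd_cutoff: float | None = None       # None: 2 Å (2.5 for ΔpolyP Q47)
    min_separation_tu: float = DEFAULT_MIN_SEPARATION_TU
    max_cluster_structures: int = 2000
    eps_qq: float = ForceField.eps_qq
    eps_bb: float = ForceField.eps_bb
    seed: int = 0

    def __post_init__(self) -> None:
        ConstructKind[self.construct]           # validate early
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def model(self) -> ConstructModel:
        return build_construct(self.construct, self.n_repeats)

    def schedule(self) -> ReplicaSchedule:
        return ReplicaSchedule(tuple(self.temperatures), self.swap_interval,
                               self.duration, self.save_interval)

    def forcefield(self) -> ForceField:
        return ForceField(eps_qq=self.eps_qq, eps_bb=self.eps_bb)

    def effective_rmsd_cutoff(self) -> float:
        if self.rmsd_cutoff is not None:
            return self.rmsd_cutoff
        if self.construct == "XN1_DP" and self.n_repeats == 47:
            return DELTA_POLYP_Q47_CUTOFF
        return DEFAULT_RMSD_CUTOFF

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["temperatures"] = list(self.temperatures)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        if "temperatures" in d:
            d["temperatures"] = tuple(d["temperatures"])
        return cls(**d)

    def hash(self) -> str:
        return qio.config_hash(self.to_yaml())


@dataclass
class PipelineResult:
    config: RunConfig
    replex: ReplexResult
    transition: object               # TransitionPeak or None
    cv_table: pd.DataFrame
    compact: CompactEnsemble
    profile: SSProfile
    region_table: pd.DataFrame
    clusters: object                 # ClusterResult
    summary: pd.DataFrame

    @property
    def model_name(self) -> str:
        return self.config.model().name


def _pooled_frames(result: ReplexResult):
    """Concatenate analysis frames of all replicas, keeping provenance."""
    times, rgs, pes, poss, reps = [], [], [], [], []
    for k, traj in enumerate(result.trajectories):
        m = traj.analysis_mask
        times.append(traj.times[m])
        rgs.append(traj.rg[m])
        pes.append(traj.potential[m])
        poss.append(traj.positions[m])
        reps.append(np.full(int(m.sum()), k))
    return (np.concatenate(times), np.concatenate(rgs),
            np.concatenate(pes), np.concatenate(poss),
            np.concatenate(reps))


def run_pipeline(config: RunConfig,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full study for one model and optionally write reports."""
    model = config.model()
    schedule = config.schedule()
    meta = {"config_hash": config.hash(), "seed": config.seed,
            "model": model.name}

    # --- simulation ------------------------------------------------------
    replex = run_replex(model, schedule, seed=config.seed,
                        forcefield=config.forcefield(),
                        equilibration_tu=config.equilibration_tu)

    # --- WHAM thermodynamics --------------------------------------------
    energies = replex.energies_by_temperature()
    hists = histogram_energies(energies)
    dos = solve_wham(hists)
    tmin, tmax = min(config.temperatures), max(config.temperatures)
    t_grid = np.linspace(0.8 * tmin, 1.2 * tmax, 200)
    curve = heat_capacity(dos, t_grid)
    peak = find_transition(curve)
    cv_table = pd.DataFrame({
        "temperature": curve.temperatures,
        "temperature_K": [temperature_to_kelvin(t)
                          for t in curve.temperatures],
        "heat_capacity": curve.c_v,
        "mean_energy": curve.mean_energy,
    })

    # --- compact-ensemble screening -------------------------------------
    times, rgs, pes, poss, reps = _pooled_frames(replex)
    rg_hist = ScreenHistogram.from_samples(ScreenVariable.RG, rgs)
    rg_cut = (config.rg_cutoff if config.rg_cutoff is not None
              else propose_rg_cutoff(rg_hist))
    e_cut = (config.energy_cutoff if config.energy_cutoff is not None
             else propose_energy_cutoff(pes, seed=config.seed))
    n_events = sum(
        count_crossings(traj.potential[traj.analysis_mask], e_cut)
        for traj in replex.trajectories)
    compact = select_compact(rgs, pes, rg_cut, e_cut, n_events=n_events)

    # --- secondary structure --------------------------------------------
    compact_pos = poss[compact.frame_indices]
    profile = ss_probability_profile(compact_pos, ppii_enabled=config.ppii,
                                     n_events=max(n_events, 1))
    region_rows = []
    for reg in model.regions:
        stats = region_average(profile, range(reg.start, reg.end))
        row = {"region": reg.name, "start": reg.start, "end": reg.end}
        for cls, (m, err) in stats.items():
            row[f"p_{cls.value}"] = m
            row[f"se_{cls.value}"] = err
        region_rows.append(row)
    region_table = pd.DataFrame(region_rows)

    # --- clustering ------------------------------------------------------
    sel: list[int] = []
    for k in range(schedule.n_replicas):
        in_rep = np.nonzero(reps[compact.frame_indices] == k)[0]
        rep_times = times[compact.frame_indices[in_rep]]
        keep = subsample_frames(rep_times, config.min_separation_tu)
        sel.extend(compact.frame_indices[in_rep[keep]])
    sel_arr = np.array(sorted(sel), dtype=int)
    if len(sel_arr) > config.max_cluster_structures:
        stride = int(np.ceil(len(sel_arr) / config.max_cluster_structures))
        sel_arr = sel_arr[::stride]
    if len(sel_arr) == 0:
        raise RuntimeError("screening produced an empty compact ensemble")
    dist = DistanceMatrix.from_frames(poss[sel_arr], sel_arr)
    clusters = single_linkage(dist, config.effective_rmsd_cutoff())

    # --- summary ---------------------------------------------------------
    summary = pd.DataFrame([{
        "model": model.name,
        "n_frames_total": replex.total_frames,
        "t_peak": peak.temperature if peak else np.nan,
        "t_peak_K": peak.temperature_kelvin if peak else np.nan,
        "cv_peak": peak.height if peak else np.nan,
        "cooperative": bool(peak.cooperative) if peak else False,
        "rg_cutoff": rg_cut,
        "energy_cutoff": e_cut,
        "n_compact": compact.n_frames,
        "compact_fraction": compact.fraction,
        "n_events": n_events,
        "n_clustered": len(sel_arr),
        "n_clusters": clusters.n_clusters,
        "largest_cluster": len(clusters.clusters[0]),
        "largest_fraction": clusters.largest_fraction,
        "exchange_acceptance": replex.acceptance_rate(),
    }])

    result = PipelineResult(config, replex, peak, cv_table, compact,
                            profile, region_table, clusters, summary)
    if outdir is not None:
        _write_reports(result, Path(outdir), meta, poss, sel_arr, model)
    return result


def _write_reports(result: PipelineResult, outdir: Path, meta: dict,
                   poss: np.ndarray, sel_arr: np.ndarray,
                   model: ConstructModel) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(result.config.to_yaml())
    qio.write_energy_series(result.cv_table, outdir / "heat_capacity.tsv",
                            meta)
    qio.write_energy_series(result.region_table,
                            outdir / "ss_regions.tsv", meta)
    qio.write_energy_series(result.summary, outdir / "summary.tsv", meta)
    for k, traj in enumerate(result.replex.trajectories):
        df = pd.DataFrame({"time": traj.times, "potential": traj.potential,
                           "kinetic": traj.kinetic, "rg": traj.rg,
                           "temperature":
                               result.replex.frame_temperatures[k]})
        qio.write_energy_series(df, outdir / f"replica_{k}.tsv", meta)
    result.replex.exchange_log().to_csv(outdir / "exchange_log.tsv",
                                        sep="\t", index=False)
    rep_frame = poss[[sel_arr[result.clusters.representative]]]
    qio.write_multi_model_pdb(rep_frame, model.sequence,
                              outdir / "representative.pdb")
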