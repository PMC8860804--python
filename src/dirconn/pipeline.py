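"""End-to-end orchestration: simulate -> preprocess -> connectivity ->
statistics -> distance profile, with file outputs and a run log.

Every stage is a pure function of (inputs, config, seed); rerunning a
stage with the same config reproduces byte-identical numeric outputs.
The config is one YAML mapping whose defaults mirror the analysis'
printed parameters (initial cluster threshold p < 0.0005, initial NBS
link threshold p < 0.005, final threshold p < 0.05, 5000 permutations).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import network_stats as ns
from .preprocess import preprocess_trials
from .simulate import (
    CONDITIONS,
    PlantedLagLink,
    PlantedPacLink,
    SimulationConfig,
    SyntheticDataset,
    gen_dataset,
    read_dataset,
    write_dataset,
)
from .source_roi import condition_average_power

STAGES = ("simulate", "connectivity", "power", "nbs", "distances")


@dataclass
class PipelineConfig:
    """All tunable analysis parameters, YAML-loadable.

    ``simulation`` carries the synthetic-dataset conditions; the alpha
    and permutation settings are the statistical thresholds applied at
    every stage.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filter_order: int = 4
    alpha_init_cluster: float = 0.0005
    alpha_init_nbs: float = 0.005
    alpha_final: float = 0.05
    n_perm: int = 5000
    seed: int = 0
    outdir: str = "dirconn_out"
    measures: tuple[str, ...] = ("dpli_theta", "dpli_gamma", "nmi")
    data_dir: str | None = None  # load a written dataset instead of simulating

    def __post_init__(self) -> None:
        for a in (self.alpha_init_cluster, self.alpha_init_nbs, self.alpha_final):
            if not (0.0 < a < 1.0):
                raise ValueError("alpha thresholds must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        unknown = set(self.measures) - {"dpli_theta", "dpli_gamma", "nmi"}
        if unknown:
            raise ValueError(f"unknown measures {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        for key, typ in (
            ("planted_dpli_links", PlantedLagLink),
            ("planted_pac_links", PlantedPacLink),
        ):
            if key in sim_raw:
                sim_raw[key] = tuple(
                    typ(**d) if isinstance(d, dict) else typ(*d) for d in sim_raw[key]
                )
        for key in ("theta_band", "gamma_band"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        if "measures" in raw:
            raw["measures"] = tuple(raw["measures"])
        return cls(simulation=SimulationConfig(**sim_raw), **raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def subject_connectivity(
    trials: list[np.ndarray],
    fs: float,
    theta_band: tuple[float, float],
    gamma_band: tuple[float, float],
    artifacts: list[list[tuple[float, float]]] | None = None,
    filter_order: int = 4,
    subject: int | None = None,
    condition: str | None = None,
) -> dict[str, conn.ConnectivityMatrix]:
    """One subject/condition's matrix set from raw ROI trials.

    Both bands are trimmed by one cycle of the theta low edge so the
    theta phase and gamma amplitude stay sample-aligned for the nMI.
    """
    trim = int(round(fs / theta_band[0]))
    min_samples = int(np.ceil(3.0 * fs / min(theta_band[0], gamma_band[0])))
    theta = preprocess_trials(
        trials, fs, theta_band, artifacts, order=filter_order,
        trim_samples=trim, min_samples=min_samples,
    )
    gamma = preprocess_trials(
        trials, fs, gamma_band, artifacts, order=filter_order,
        trim_samples=trim, min_samples=min_samples,
    )
    return conn.connectivity_matrices(theta, gamma, subject=subject, condition=condition)


def all_connectivity(
    ds: SyntheticDataset, filter_order: int = 4
) -> dict[str, dict[str, np.ndarray]]:
    """Stacked per-subject raw and logit matrices for every measure and
    condition: result[measure][condition] is (n_subjects, n_roi, n_roi)
    on the logit scale; raw stacks under ``measure + '_raw'``."""
    cfg = ds.config
    out: dict[str, dict[str, list[np.ndarray]]] = {}
    for subj in range(cfg.n_subjects):
        for cond in CONDITIONS:
            mats = subject_connectivity(
                ds.signals[(subj, cond)],
                cfg.sampling_rate,
                cfg.theta_band,
                cfg.gamma_band,
                ds.artifacts(subj, cond),
                filter_order=filter_order,
                subject=subj,
                condition=cond,
            )
            for measure, mat in mats.items():
                out.setdefault(measure, {}).setdefault(cond, []).append(
                    mat.to_logit().values
                )
                out.setdefault(measure + "_raw", {}).setdefault(cond, []).append(
                    mat.values
                )
    return {
        m: {c: np.stack(v) for c, v in conds.items()} for m, conds in out.items()
    }


def band_power_maps(ds: SyntheticDataset, band: tuple[float, float], filter_order: int = 4):
    """Per-subject average standardized band power per ROI and condition.

    Power is the squared analytic amplitude; per subject it is z-scored
    across the pooled clean samples of both conditions and then averaged
    within each condition (see
    :func:`dirconn.source_roi.condition_average_power`).
    """
    cfg = ds.config
    trim = int(round(cfg.sampling_rate / band[0]))
    maps = {cond: [] for cond in CONDITIONS}
    for subj in range(cfg.n_subjects):
        power_by_cond = {}
        for cond in CONDITIONS:
            series = preprocess_trials(
                ds.signals[(subj, cond)], cfg.sampling_rate, band,
                ds.artifacts(subj, cond), order=filter_order, trim_samples=trim,
            )
            power_by_cond[cond] = [series.amplitude.T ** 2]
        avg, _valid = condition_average_power(power_by_cond)
        for cond in CONDITIONS:
            maps[cond].append(avg[cond])
    return {cond: np.stack(v) for cond, v in maps.items()}


def run(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the selected stages in dependency order and write artifacts.

    Outputs land under ``config.outdir``; every file set is indexed by a
    manifest and the run log records per-stage parameters, wall time and
    the config hash.
    """
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}")
    stages = tuple(s for s in STAGES if s in stages)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    results: dict = {"config_hash": config.config_hash()}

    def _log(stage: str, t0: float, **info) -> None:
        log.append(
            {
                "stage": stage,
                "seconds": round(time.perf_counter() - t0, 3),
                "seed": config.seed,
                "config_hash": config.config_hash(),
                **info,
            }
        )

    ds: SyntheticDataset | None = None
    if config.data_dir is not None:
        ds = read_dataset(config.data_dir, config.simulation)
    elif "simulate" in stages:
        t0 = time.perf_counter()
        ds = gen_dataset(config.simulation)
        write_dataset(ds, outdir / "dataset")
        _log("simulate", t0, n_subjects=config.simulation.n_subjects)

    needs_data = {"connectivity", "power", "nbs", "distances"} & set(stages)
    if needs_data and ds is None:
        raise FileNotFoundError(
            "stage requires a dataset: run 'simulate' first or set data_dir"
        )
    results["dataset"] = ds

    stacks = None
    if {"connectivity", "nbs", "distances"} & set(stages):
        t0 = time.perf_counter()
        stacks = all_connectivity(ds, filter_order=config.filter_order)
        mat_dir = outdir / "matrices"
        mat_dir.mkdir(exist_ok=True)
        manifest = []
        for measure in config.measures:
            for cond, stack in stacks[measure + "_raw"].items():
                for subj in range(stack.shape[0]):
                    name = f"{measure}_{cond}_sub{subj:02d}.tsv"
                    pd.DataFrame(
                        stack[subj], columns=ds.roi_table.abbrevs
                    ).to_csv(mat_dir / name, sep="\t", index=False)
                    manifest.append(
                        {"measure": measure, "condition": cond, "subject": subj,
                         "scale": "raw", "file": name}
                    )
        pd.DataFrame(manifest).to_csv(mat_dir / "manifest.tsv", sep="\t", index=False)
        results["connectivity"] = stacks
        _log("connectivity", t0, n_matrices=len(manifest))

    if "power" in stages:
        t0 = time.perf_counter()
        adjacency = ns.grid_adjacency(ds.roi_table.centroids)
        clusters = {}
        for band_name, band in (
            ("theta", config.simulation.theta_band),
            ("gamma", config.simulation.gamma_band),
        ):
            maps = band_power_maps(ds, band, filter_order=config.filter_order)
            clusters[band_name] = ns.cluster_perm_power(
                maps["memory"], maps["math"], adjacency,
                alpha_init=config.alpha_init_cluster,
                alpha_cluster=config.alpha_final,
                n_perm=config.n_perm,
                seed=np.random.default_rng([config.seed, 1]),
                coords=ds.roi_table.centroids,
            )
        rows = [
            {"band": band_name, "cluster": i, "n_sources": len(c.members),
             "sum_t": c.mass, "p": c.p_value, "peak_t": c.peak_t,
             "peak_x": c.peak_coord[0], "peak_y": c.peak_coord[1],
             "peak_z": c.peak_coord[2]}
            for band_name, cl in clusters.items()
            for i, c in enumerate(cl)
        ]
        pd.DataFrame(
            rows, columns=["band", "cluster", "n_sources", "sum_t", "p",
                           "peak_t", "peak_x", "peak_y", "peak_z"]
        ).to_csv(outdir / "power_clusters.tsv", sep="\t", index=False)
        results["power_clusters"] = clusters
        _log("power", t0, n_clusters=sum(len(c) for c in clusters.values()))

    networks: dict[str, list[ns.DirectedNetwork]] = {}
    if "nbs" in stages or "distances" in stages:
        t0 = time.perf_counter()
        if "nmi" in config.measures:
            networks["nmi"] = ns.nbs_paired(
                stacks["nmi"]["memory"], stacks["nmi"]["math"],
                alpha_init=config.alpha_init_nbs, alpha_comp=config.alpha_final,
                n_perm=config.n_perm, seed=np.random.default_rng([config.seed, 2]),
                measure="nmi",
            )
        for k, measure in enumerate(("dpli_theta", "dpli_gamma")):
            if measure not in config.measures:
                continue
            per_cond = {
                cond: ns.nbs_onesample_dpli(
                    stacks[measure][cond],
                    alpha_init=config.alpha_init_nbs, alpha_comp=config.alpha_final,
                    n_perm=config.n_perm,
                    seed=np.random.default_rng([config.seed, 3 + k, i]),
                    measure=measure,
                )
                for i, cond in enumerate(CONDITIONS)
            }
            networks[measure] = per_cond["memory"]
            networks[measure + "_math"] = per_cond["math"]
            results.setdefault("condition_overlap", {})[measure] = ns.network_overlap(
                per_cond["memory"], per_cond["math"]
            )
        edge_rows, node_rows = [], []
        for measure, nets in networks.items():
            for net in nets:
                edge_rows.extend(
                    net.to_frame(ds.roi_table.abbrevs).to_dict("records")
                )
                for node, typ in net.node_types.items():
                    node_rows.append(
                        {"abbrev": ds.roi_table.abbrevs[node], "type": typ,
                         "degree": net.degree(node), "measure": measure}
                    )
        pd.DataFrame(
            edge_rows, columns=["src", "dst", "t", "measure", "component_p"]
        ).to_csv(outdir / "networks_edges.tsv", sep="\t", index=False)
        pd.DataFrame(
            node_rows, columns=["abbrev", "type", "degree", "measure"]
        ).to_csv(outdir / "networks_nodes.tsv", sep="\t", index=False)
        results["networks"] = networks
        _log("nbs", t0, n_networks=sum(len(v) for v in networks.values()))

    if "distances" in stages:
        t0 = time.perf_counter()
        groups = {
            m: ns.link_distances(networks.get(m, []), ds.roi_table.centroids)
            for m in config.measures
        }
        try:
            anova = ns.link_distance_anova(groups)
            anova["posthoc"].to_csv(outdir / "distance_posthoc.tsv", sep="\t", index=False)
            results["distance_anova"] = anova
        except ValueError as err:
            results["distance_anova"] = None
            results["distance_anova_note"] = str(err)
        _log("distances", t0)

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    results["log"] = log
    return results
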