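"""End-to-end orchestration: simulate → build → slide → metrics → fit → report.

``run_pipeline`` executes the stages in dependency order on a synthetic
cohort, writing every stage's tables as delimited text under a run directory
before the next stage starts, together with a config snapshot and a plain-text
log. All stage seeds derive from one master seed via a stable hash, so a rerun
with the same config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .communities import consensus_partition, nmi
from .dataset import write_dataset
from .metrics import community_density, nodal_and_global_metrics
from .morphometry import depth_profile_association, regional_rates
from .network import (BootstrapConfig, bootstrap_mean_correlations,
                      build_thresholded_network)
from .spin import SpinConfig, spin_pvalue
from .synthetic import (MAIN_MT_DEPTH, MT_DEPTHS, CohortSpec,
                        default_covariance_model, generate_cohort,
                        generate_regions)
from .trajectories import (bootstrap_age_min_ci, fit_trajectory,
                           nodal_significance, trajectory_params)
from .windows import WindowingConfig, make_windows

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Stage seed derived from the master seed by a stable hash (< 2^31)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Aggregated configuration for one pipeline run.

    The full profile matches the canonical study design (B = 1000 bootstraps,
    10 000 spin permutations, edge alpha 0.01, trajectory alpha 0.05,
    df <= 3.5); ``RunConfig.reduced()`` is a smaller profile (100 regions,
    B = 200, 1000 permutations) for quick runs and continuous testing.
    """

    n_participants: int = 297
    n_regions: int = 308
    n_modules: int = 7
    age_range: tuple[float, float] = (14.0, 24.0)
    n_strata: int = 5
    window: WindowingConfig = field(default_factory=WindowingConfig)
    n_boot: int = 1000
    edge_alpha: float = 0.01
    gamma: float = 1.0
    consensus_runs: int = 100
    tau: float = 0.5
    n_perm: int = 10000
    trajectory_alpha: float = 0.05
    edf_max: float = 3.5
    mt_depths: tuple[str, ...] = MT_DEPTHS
    seed: int = 0

    @classmethod
    def reduced(cls, seed: int = 0) -> "RunConfig":
        return cls(n_regions=100, n_boot=200, n_perm=1000, consensus_runs=50,
                   seed=seed)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["window"] = dataclasses.asdict(self.window)
        return json.dumps(d, indent=1)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage and write result tables under ``out_dir``.

    Returns a dict of the in-memory results (tables, fits, partitions,
    summary scalars). Any stage failure raises with the stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    log_lines: list[str] = []
    t0 = time.time()

    def log(stage: str, msg: str) -> None:
        line = f"[{time.time() - t0:8.1f}s] {stage}: {msg}"
        logger.info(line)
        log_lines.append(line)

    results: dict = {}
    stage = "simulate"
    try:
        regions = generate_regions(config.n_regions, config.n_modules,
                                   stage_seed(config.seed, "regions"))
        model = default_covariance_model()
        spec = CohortSpec(n_participants=config.n_participants,
                          age_range=config.age_range, n_strata=config.n_strata,
                          seed=stage_seed(config.seed, "cohort"))
        dataset, truth = generate_cohort(spec, regions, model,
                                         mt_depths=config.mt_depths)
        write_dataset(dataset, out / "dataset", ground_truth=truth)
        results["dataset"], results["truth"] = dataset, truth
        log(stage, f"{dataset.n_participants} participants x "
                   f"{dataset.n_regions} regions")

        stage = "build_invariant"
        boot = BootstrapConfig(n_boot=config.n_boot, alpha=config.edge_alpha,
                               seed=stage_seed(config.seed, "boot_invariant"))
        inv_net, inv_corr = build_thresholded_network(dataset, None, boot)
        inv_nodal, inv_glob = nodal_and_global_metrics(inv_net, inv_corr,
                                                       dataset.centroids)
        inv_net.edge_list().to_csv(out / "invariant_edges.csv", index=False)
        results["invariant_network"] = inv_net
        results["invariant_nodal"] = inv_nodal
        results["invariant_global"] = inv_glob
        log(stage, f"density {inv_glob.edge_density_pct:.1f}%")

        stage = "communities"
        partition = consensus_partition(
            inv_net.weights, gamma=config.gamma, n_runs=config.consensus_runs,
            tau=config.tau, seed=stage_seed(config.seed, "consensus"))
        nmi_planted = (nmi(partition.labels, truth.module_labels)
                       if truth.module_labels is not None else np.nan)
        pd.DataFrame({"region_id": dataset.regions.index,
                      "module": partition.labels}).to_csv(
            out / "consensus_partition.csv", index=False)
        results["partition"] = partition
        results["nmi_vs_planted"] = nmi_planted
        log(stage, f"{partition.n_modules} modules, "
                   f"NMI vs planted {nmi_planted:.3f}")

        stage = "slide"
        windows = make_windows(dataset.ages, config.window)
        wtab = pd.DataFrame(
            [(w.window_index, dataset.participants.index[i], dataset.ages[i])
             for w in windows for i in w.indices],
            columns=["window_index", "participant_id", "age"])
        wtab.to_csv(out / "window_membership.csv", index=False)
        results["windows"] = windows
        log(stage, f"{len(windows)} windows")

        stage = "metrics"
        rows = []
        degree = np.empty((len(windows), dataset.n_regions))
        nodal_dist = np.empty_like(degree)
        mean_r_reps = np.empty((config.n_boot, len(windows)))
        window_nets = []
        for w in windows:
            bw = BootstrapConfig(
                n_boot=config.n_boot, alpha=config.edge_alpha,
                seed=stage_seed(config.seed, f"boot_w{w.window_index}"))
            net, corr = build_thresholded_network(dataset, w.indices, bw)
            nodal, glob = nodal_and_global_metrics(net, corr, dataset.centroids)
            window_nets.append(net)
            degree[w.window_index] = nodal.degree
            nodal_dist[w.window_index] = nodal.connection_distance
            mean_r_reps[:, w.window_index] = bootstrap_mean_correlations(
                dataset, w.indices, bw)
            rows.extend(
                (w.window_index, w.median_age, name, value)
                for name, value in [
                    ("mean_correlation", glob.mean_correlation),
                    ("edge_density_pct", glob.edge_density_pct),
                    ("mean_connection_distance", glob.mean_connection_distance),
                ])
        global_tab = pd.DataFrame(
            rows, columns=["window_index", "median_age", "metric", "value"])
        global_tab.to_csv(out / "global_metrics.csv", index=False)
        results["global_metrics"] = global_tab
        results["degree"] = degree
        results["window_networks"] = window_nets
        log(stage, "per-window metrics done")

        stage = "trajectories"
        ages = np.array([w.median_age for w in windows])
        global_fits = {}
        for metric in ("mean_correlation", "edge_density_pct",
                       "mean_connection_distance"):
            y = global_tab.query("metric == @metric").sort_values(
                "window_index")["value"].to_numpy()
            fit = fit_trajectory(ages, y, edf_max=config.edf_max)
            global_fits[metric] = (fit, trajectory_params(fit))
        fit_r, par_r = global_fits["mean_correlation"]
        ci_lo, ci_hi, _ = bootstrap_age_min_ci(ages, mean_r_reps,
                                               model=fit_r.chosen,
                                               edf_max=config.edf_max)
        results["global_fits"] = global_fits
        results["age_min_mean_r_ci"] = (ci_lo, ci_hi)

        nodal_rows = []
        pvals = []
        delta_k = np.empty(dataset.n_regions)
        for j in range(dataset.n_regions):
            fit = fit_trajectory(ages, degree[:, j], edf_max=config.edf_max)
            par = trajectory_params(fit)
            pvals.append(par.pvalue)
            delta_k[j] = par.delta_max * (-1 if par.direction == "decreasing" else 1)
            nodal_rows.append({
                "region_id": dataset.regions.index[j], "metric": "degree",
                "chosen_model": fit.chosen, "delta_max": par.delta_max,
                "age_min": par.age_min, "boundary_min": par.boundary_min,
                "direction": par.direction, "shape": par.shape,
                "p": par.pvalue})
        p_fdr, signif = nodal_significance(pvals, config.trajectory_alpha)
        nodal_tab = pd.DataFrame(nodal_rows)
        nodal_tab["p_fdr"] = p_fdr
        nodal_tab["significant"] = signif
        nodal_tab.to_csv(out / "nodal_trajectories.csv", index=False)
        results["nodal_trajectories"] = nodal_tab
        results["delta_k"] = delta_k
        log(stage, f"{int(signif.sum())} regions with significant change; "
                   f"global r minimum at {par_r.age_min:.2f} y "
                   f"[{ci_lo:.2f}, {ci_hi:.2f}]")

        stage = "community_density"
        labels = partition.labels
        k = partition.n_modules
        D = np.stack([community_density(net, labels) for net in window_nets])
        d_rows = []
        for a in range(k):
            for b in range(a, k):
                series = D[:, a, b]
                if np.any(np.isnan(series)):
                    continue
                fit = fit_trajectory(ages, series, edf_max=config.edf_max)
                par = trajectory_params(fit)
                d_rows.append({"community_a": a + 1, "community_b": b + 1,
                               "delta_D_max": par.delta_max,
                               "age_D_min": par.age_min,
                               "direction": par.direction, "p": par.pvalue})
        dens_tab = pd.DataFrame(d_rows)
        if len(dens_tab):
            dens_tab["p_fdr"] = nodal_significance(
                dens_tab["p"].to_numpy(), config.trajectory_alpha)[0]
        dens_tab.to_csv(out / "community_density_trajectories.csv", index=False)
        results["community_density_trajectories"] = dens_tab
        log(stage, f"{len(dens_tab)} community pairs fitted")

        stage = "morphometry"
        ct_rates = regional_rates(dataset.values, dataset.ages)
        mt_rates = {d: regional_rates(t, dataset.ages)
                    for d, t in dataset.mt.items()}
        rates_tab = pd.DataFrame({"region_id": dataset.regions.index,
                                  "dCT": ct_rates})
        for d, r in mt_rates.items():
            rates_tab[f"dMT_{d}"] = r
        rates_tab.to_csv(out / "morphometric_rates.csv", index=False)
        results["ct_rates"] = ct_rates
        results["mt_rates"] = mt_rates

        stage = "spin"
        spin_cfg = SpinConfig(n_perm=config.n_perm,
                              seed=stage_seed(config.seed, "spin"))
        region_set = dataset.region_set
        degree_vs_dk = spin_pvalue(results["invariant_nodal"].degree.astype(float),
                                   delta_k, region_set, spin_cfg)
        assoc = depth_profile_association(
            mt_rates, delta_k, regions=region_set,
            spin_config=SpinConfig(n_perm=config.n_perm,
                                   seed=stage_seed(config.seed, "spin_depth")))
        assoc.to_csv(out / "depth_profile_association.csv", index=False)
        results["spin_degree_vs_delta_k"] = degree_vs_dk
        results["depth_association"] = assoc
        log(stage, f"invariant degree vs delta_k: rho {degree_vs_dk.rho_emp:.2f} "
                   f"(p_perm {degree_vs_dk.p_perm:.4f})")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return results
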