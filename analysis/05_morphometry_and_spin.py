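"""Network change vs age-invariant architecture and morphometric rates.

Relates nodal degree change (signed delta_k_max) to age-invariant degree, to
cortical thinning and myelination rates (the latter across 12 cortical
depths), and to the consensus communities (within/between edge-density
trajectories). Map-map associations are tested with both the parametric
Spearman p and the spherical spin permutation p (10 000 rotations).
Writes association and community-density tables under results/.
"""

import numpy as np
import pandas as pd

import scnet as s

SEED = 1
COHORT = "results/cohort"


def main() -> None:
    dataset = s.read_dataset(COHORT)
    regions = dataset.region_set
    nodal = pd.read_csv("results/nodal_trajectories.csv")
    invariant = pd.read_csv("results/invariant_degree.csv")
    partition = pd.read_csv("results/consensus_partition.csv")
    glob = pd.read_csv("results/window_global_metrics.csv")
    ages = glob["median_age"].to_numpy()

    signed_dk = np.where(nodal["direction"] == "decreasing",
                         -nodal["delta_max"], nodal["delta_max"]).astype(float)

    spin_cfg = s.SpinConfig(n_perm=10000, seed=s.stage_seed(SEED, "spin"))
    res = s.spin_pvalue(invariant["weighted_degree"].to_numpy(float),
                        signed_dk, regions, spin_cfg)
    print(f"age-invariant weighted degree vs delta_k: rho {res.rho_emp:+.2f} "
          f"(P_Spearman {res.p_spearman:.2g}, P_perm {res.p_perm:.4f})")

    ct_rates = s.regional_rates(dataset.values, dataset.ages)
    mt_rates = {d: s.regional_rates(t, dataset.ages) for d, t in dataset.mt.items()}
    res_ct = s.spin_pvalue(ct_rates, signed_dk, regions,
                           s.SpinConfig(n_perm=10000,
                                        seed=s.stage_seed(SEED, "spin_ct")))
    print(f"thinning rate dCT vs delta_k:           rho {res_ct.rho_emp:+.2f} "
          f"(P_perm {res_ct.p_perm:.4f})")

    profile = s.depth_profile_association(
        mt_rates, signed_dk, regions=regions,
        spin_config=s.SpinConfig(n_perm=2000,
                                 seed=s.stage_seed(SEED, "spin_depth")))
    profile.to_csv("results/depth_profile_association.csv", index=False)
    best = profile.loc[profile["rho"].abs().idxmax()]
    print(f"strongest dMT association at depth {best['depth']} "
          f"(rho {best['rho']:+.2f})")

    # community edge-density trajectories on the consensus partition
    labels = partition["module"].to_numpy()
    windows = s.make_windows(dataset.ages, s.WindowingConfig())
    D = []
    for w in windows:
        net, _ = s.build_thresholded_network(
            dataset, w.indices,
            s.BootstrapConfig(n_boot=200, alpha=0.01,
                              seed=s.stage_seed(SEED, f"dens_w{w.window_index}")))
        D.append(s.community_density(net, labels))
    D = np.stack(D)
    rows = []
    k = D.shape[1]
    for a in range(k):
        for b in range(a, k):
            series = D[:, a, b]
            if np.any(np.isnan(series)):
                continue
            par = s.trajectory_params(s.fit_trajectory(ages, series))
            rows.append({"community_a": a + 1, "community_b": b + 1,
                         "within": a == b, "delta_D_max": par.delta_max,
                         "age_D_min": par.age_min, "p": par.pvalue})
    dens = pd.DataFrame(rows)
    dens["p_fdr"], dens["significant"] = s.nodal_significance(
        dens["p"].to_numpy(), alpha=0.05)
    dens.to_csv("results/community_density_trajectories.csv", index=False)
    print(f"community pairs with significant density change: "
          f"{int(dens.significant.sum())}/{len(dens)}")


if __name__ == "__main__":
    main()
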