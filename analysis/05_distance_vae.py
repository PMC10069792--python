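#!/usr/bin/env python
"""Cluster mutants by MD distance profiles with the attention VAE.

Reads results/distances.csv and results/mechanisms.csv (stage 01),
trains the asymmetric attention VAE (three restarts, best final loss),
projects every mutant to the 2-D latent space, clusters with k-means
(k=3, clusters relabelled by descending mean phenotype), and decodes the
cluster centroids into distance profiles relative to the WT reference.

Writes:
  results/latent_space.csv        mutant, z0, z1, cluster, phenotype
  results/cluster_profiles.csv    decoded centroid distances + Δdistance
Prints the adjusted Rand index against the planted mechanisms and the
per-cluster mean phenotypes.
"""

import argparse
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from polphen.io import read_distance_table
from polphen.pipeline import distance_vae_analysis
from polphen.synth import wt_distance_profile

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=4)
    parser.add_argument("--epochs", type=int, default=1200)
    parser.add_argument("--restarts", type=int, default=4)
    parser.add_argument("--latent-dim", type=int, default=2, choices=(2, 3))
    args = parser.parse_args()

    profiles = read_distance_table(RESULTS / "distances.csv")
    meta = pd.read_csv(RESULTS / "mechanisms.csv", index_col="mutant")
    result = distance_vae_analysis(profiles, meta["phenotype_value"],
                                   wt_distance_profile(), k=3,
                                   latent_dim=args.latent_dim,
                                   epochs=args.epochs,
                                   n_restarts=args.restarts, seed=args.seed)
    result.latent.to_csv(RESULTS / "latent_space.csv", index_label="mutant")
    result.centroid_profiles.to_csv(RESULTS / "cluster_profiles.csv")

    # Free-energy-style density map of phenotype vs mean distance.
    from polphen.landscape import phenotype_distance_density
    mean_dist = profiles.distances.mean(axis=1)
    fe, empty, xe, ye = phenotype_distance_density(
        meta["phenotype_value"].to_numpy(), mean_dist.to_numpy(), bins=20)
    fe_df = pd.DataFrame(fe, index=pd.Index(xe[:-1].round(3), name="phenotype_bin"),
                         columns=ye[:-1].round(3))
    fe_df.to_csv(RESULTS / "phenotype_distance_map.csv")

    ari = adjusted_rand_score(meta["mechanism"].to_numpy(),
                              result.latent["cluster"].to_numpy())
    print(f"best-of-{args.restarts} VAE final loss: {result.final_train_loss:.2f}")
    print(f"adjusted Rand index vs planted mechanisms: {ari:.3f}")
    roman = ("I", "II", "III")
    for i, v in enumerate(result.clusters.cluster_phenotypes):
        n = int((result.latent["cluster"] == i).sum())
        print(f"cluster {roman[i]}: mean phenotype {v:+.2f} ({n} mutants)")


if __name__ == "__main__":
    main()
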