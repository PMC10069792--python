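#!/usr/bin/env python
"""Map fitness profiles to continuum phenotypes with the 256/128/64 net.

Reads results/fitness_scores.csv and results/true_phenotypes.csv (stage
01), trains on a random 100-mutant annotated subset, and writes
results/predicted_phenotypes.csv with a phenotype value and class per
mutant.  Also trains the unsupervised fitness VAE (256/128/64 encoder
and decoder, 2-D Gaussian latent) and writes the latent coordinates to
results/fitness_latent.csv — the unsupervised view of how mutants with
similar phenotypes group by fitness profile alone.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from polphen.io import impute_missing, read_fitness_table, write_phenotype_table
from polphen.metrics import Standardizer
from polphen.pipeline import phenotype_from_fitness
from polphen.vae import (VAE, VAETrainConfig, fitness_vae_spec,
                         project_latent, train_vae_restarts)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=2)
    parser.add_argument("--epochs", type=int, default=1000)
    parser.add_argument("--vae-epochs", type=int, default=1500)
    args = parser.parse_args()

    fitness = read_fitness_table(RESULTS / "fitness_scores.csv")
    truth = pd.read_csv(RESULTS / "true_phenotypes.csv", index_col="mutant")
    rng = np.random.default_rng(args.seed)
    perm = rng.permutation(len(fitness))
    result = phenotype_from_fitness(fitness, truth["phenotype_value"],
                                    fitness.index[perm[:100]],
                                    fitness.index[perm[100:]],
                                    epochs=args.epochs, seed=args.seed + 1)
    write_phenotype_table(result.predictions,
                          RESULTS / "predicted_phenotypes.csv")
    rep = result.heldout_report
    print(f"held-out (n={len(fitness) - 100}): R^2={rep.r2:.3f} "
          f"slope={rep.slope:.3f} MSE={rep.mse:.3f}")

    # Unsupervised latent space of the fitness data.
    X = impute_missing(fitness).to_numpy()
    Xs = Standardizer.fit(X).transform(X)
    vae, loss = train_vae_restarts(fitness_vae_spec(), Xs,
                                   VAETrainConfig(epochs=args.vae_epochs,
                                                  seed=args.seed + 2),
                                   n_restarts=2, base_seed=args.seed + 3)
    z = project_latent(vae, Xs)
    latent = pd.DataFrame({"z0": z[:, 0], "z1": z[:, 1]}, index=fitness.index)
    latent["phenotype"] = result.predictions
    latent.to_csv(RESULTS / "fitness_latent.csv", index_label="mutant")
    print(f"fitness VAE final loss {loss:.2f}; latent coordinates written")


if __name__ == "__main__":
    main()
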