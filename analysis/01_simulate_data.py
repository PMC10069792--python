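#!/usr/bin/env python
"""Generate the synthetic study-condition datasets used by the later stages.

Writes, under results/:
  fitness_scores.csv      135 mutants x (21 conditions x 3 replicates)
  true_phenotypes.csv     ground-truth continuum phenotypes and classes
  distances.csv           62-feature averaged distance profiles
  mechanisms.csv          planted mechanism label per mutant

The fitness phenotypes are planted from additive sequence effects so the
fitness -> phenotype -> sequence chain shares one ground truth; the
distance table plants the three structural mechanisms (TL-GTP inflation,
BH-TL inflation, tight baseline).
"""

import argparse
from pathlib import Path

import numpy as np

from polphen.io import write_distance_table, write_fitness_table
from polphen.synth import (SyntheticSpec, additive_sequence_effects,
                           generate_distance_dataset, generate_fitness_dataset,
                           random_mutant_library)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-mutants", type=int, default=135)
    parser.add_argument("--noise", type=float, default=0.1,
                        help="replicate noise sigma (fitness units)")
    parser.add_argument("--missingness", type=float, default=0.05)
    args = parser.parse_args()

    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(args.seed)
    mutants = random_mutant_library(args.n_mutants, rng)
    effects = additive_sequence_effects(rng)
    phenotypes = effects.phenotypes(mutants)

    spec = SyntheticSpec(n_mutants=args.n_mutants, sigma_rep=args.noise,
                         missingness=args.missingness, seed=args.seed + 1)
    fitness, truth = generate_fitness_dataset(spec, mutants=mutants,
                                              phenotypes=phenotypes)
    write_fitness_table(fitness, RESULTS / "fitness_scores.csv")
    truth.to_csv(RESULTS / "true_phenotypes.csv")

    dist_spec = SyntheticSpec(n_mutants=args.n_mutants, seed=args.seed + 2)
    profiles, mechanisms, dist_truth = generate_distance_dataset(dist_spec,
                                                                 mutants=mutants)
    write_distance_table(profiles, RESULTS / "distances.csv")
    mechanisms.to_frame().join(dist_truth).to_csv(RESULTS / "mechanisms.csv")

    n_missing = int(fitness.isna().sum().sum())
    print(f"wrote {len(mutants)} mutants: fitness {fitness.shape} "
          f"({n_missing} missing cells), distances {profiles.distances.shape}")
    print(f"phenotype range: {phenotypes.min():.2f} .. {phenotypes.max():.2f}")
    print(f"mechanism counts: {mechanisms.value_counts().to_dict()}")


if __name__ == "__main__":
    main()
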