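#!/usr/bin/env python
"""Predict phenotypes from trigger-loop sequence with a net ensemble.

Trains sequence nets over random 100/35 train/test splits on the
fitness-derived phenotypes (stage 02), keeps the best checkpoint per
split by R^2/slope score, ensembles the winners, and compares against
the per-position average baseline.  Writes:

  results/sequence_predictions.csv   ensemble + baseline prediction per mutant
  results/sequence_landscape.csv     31x19 single-mutant landscape + Mean row
"""

import argparse
from pathlib import Path

import pandas as pd

from polphen.io import parse_mutant_id
from polphen.landscape import predict_landscape
from polphen.pipeline import (position_baseline_analysis,
                              save_sequence_ensemble,
                              sequence_ensemble_analysis)
from polphen.synth import DEFAULT_WT_SEQ

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=3)
    parser.add_argument("--n-sets", type=int, default=3)
    parser.add_argument("--models-per-set", type=int, default=1)
    parser.add_argument("--epochs", type=int, default=2000)
    args = parser.parse_args()

    phen = pd.read_csv(RESULTS / "predicted_phenotypes.csv",
                       index_col="mutant")["phenotype_value"]
    mutants = [parse_mutant_id(str(l)) for l in phen.index]
    seq = sequence_ensemble_analysis(mutants, phen, DEFAULT_WT_SEQ,
                                     n_sets=args.n_sets,
                                     models_per_set=args.models_per_set,
                                     epochs=args.epochs,
                                     checkpoint_interval=100,
                                     learning_rate=1e-5, seed=args.seed)
    baseline = position_baseline_analysis(mutants, phen, seq.splits)

    out = pd.DataFrame({
        "phenotype_from_fitness": phen,
        "ensemble_prediction": seq.predictions,
        "baseline_prediction": baseline.predictions,
    })
    out.to_csv(RESULTS / "sequence_predictions.csv", index_label="mutant")
    predict_landscape(seq.ensemble.predict, DEFAULT_WT_SEQ).to_csv(
        RESULTS / "sequence_landscape.csv")
    SCRATCH.mkdir(exist_ok=True)
    save_sequence_ensemble(seq.ensemble, SCRATCH / "sequence_ensemble.npz")

    r = seq.overall_report
    b = baseline.overall_report
    print(f"sequence ensemble: R^2={r.r2:.3f} slope={r.slope:.3f} "
          f"intercept={r.intercept:.3f} MSE={r.mse:.3f}")
    print(f"mean held-out R^2 over {args.n_sets} splits: {seq.mean_test_r2:.3f}")
    print(f"per-position baseline: R^2={b.r2:.3f} slope={b.slope:.3f}")


if __name__ == "__main__":
    main()
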