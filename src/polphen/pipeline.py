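"""End-to-end analysis stages chaining the library modules.

The full pipeline mirrors the study design:

1. a supervised net maps the 63 fitness features of an annotated mutant
   subset to continuum phenotypes, then predicts phenotypes for the whole
   library;
2. an ensemble of sequence nets (ten random 100/35 splits in the full
   protocol) learns those phenotypes from one-hot sequence alone and is
   compared against a per-position average baseline;
3. the single-mutant ensemble predicts double-mutant landscapes, checked
   against the additive null;
4. an attention VAE on averaged MD distances organises mutants into
   k-means clusters whose decoded centroids expose mechanism.

Each stage is a plain function returning a result object so drivers and
tests can run stages independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import encode_mutants
from .io import DistanceProfileSet, MutantID, impute_missing, parse_mutant_id
from .landscape import (PhenotypeLandscape, PositionAverageBaseline,
                        additive_phenotype, predict_landscape)
from .metrics import RegressionReport, Standardizer, regression_metrics
from .nn import (DenseNet, Ensemble, EnsembleProtocol, SequenceNet,
                 TrainConfig, select_best_checkpoint, train_ensemble,
                 train_with_checkpoints)
from .vae import (ClusterModel, VAE, VAETrainConfig, cluster_latent,
                  decode_profiles, md_vae_spec, project_latent,
                  train_vae_restarts)

#: Double-mutant backgrounds studied on top of the single-mutant ensemble:
#: three GOF (E1103G, G1097D, F1084I) and one LOF (Q1078S).
DOUBLE_MUTANT_BACKGROUNDS = ("E1103G", "G1097D", "F1084I", "Q1078S")


# ---------------------------------------------------------------------------
# Stage 1: fitness -> phenotype
# ---------------------------------------------------------------------------

@dataclass
class FitnessModelResult:
    model: DenseNet
    standardizer: Standardizer
    predictions: pd.Series           # all mutants
    heldout_report: RegressionReport


def phenotype_from_fitness(fitness: pd.DataFrame, phenotypes: pd.Series,
                           train_index, test_index,
                           epochs: int = 1000, learning_rate: float = 1e-4,
                           checkpoint_interval: int = 100,
                           seed: int = 0) -> FitnessModelResult:
    """Train the 256/128/64 fitness net and predict the whole library.

    Missing fitness entries are mean-imputed; features are z-scored on
    the training rows.  The best checkpoint by R^2/slope score on the
    held-out rows is kept.
    """
    X = impute_missing(fitness).to_numpy()
    y = phenotypes.loc[fitness.index].to_numpy()
    train_pos = fitness.index.get_indexer(train_index)
    test_pos = fitness.index.get_indexer(test_index)
    std = Standardizer.fit(X[train_pos])
    Xs = std.transform(X)
    model = DenseNet(X.shape[1], (256, 128, 64), np.random.default_rng(seed))
    cfg = TrainConfig(learning_rate=learning_rate, max_epochs=epochs,
                      checkpoint_interval=checkpoint_interval,
                      batch_size=4, seed=seed + 1)
    result = train_with_checkpoints(model, Xs[train_pos], y[train_pos], cfg)
    best = select_best_checkpoint(model, result.checkpoints,
                                  Xs[test_pos], y[test_pos])
    preds = pd.Series(model.predict(Xs), index=fitness.index,
                      name="phenotype_value")
    return FitnessModelResult(model=model, standardizer=std,
                              predictions=preds,
                              heldout_report=best.test_report)


# ---------------------------------------------------------------------------
# Stage 2: sequence -> phenotype ensemble + baseline
# ---------------------------------------------------------------------------

@dataclass
class SequenceEnsembleResult:
    ensemble: Ensemble
    overall_report: RegressionReport     # ensemble predictions vs labels, all mutants
    mean_test_r2: float                  # mean held-out R^2 over the splits
    per_set_reports: list[RegressionReport]
    splits: list[tuple[np.ndarray, np.ndarray]]
    predictions: pd.Series


def sequence_ensemble_analysis(mutants: list[MutantID], phenotypes: pd.Series,
                               wt_seq: str, n_sets: int = 10,
                               models_per_set: int = 10,
                               epochs: int = 20_000,
                               checkpoint_interval: int = 500,
                               learning_rate: float = 1e-5,
                               seed: int = 0) -> SequenceEnsembleResult:
    """Train the sequence-net ensemble over random train/test splits.

    Labels are the continuum phenotypes (fitness-derived in the full
    pipeline).  The returned overall report regresses the ensemble
    predictions for the complete mutant set on the labels.
    """
    labels = [m.label for m in mutants]
    y = phenotypes.loc[labels].to_numpy()
    X = encode_mutants(wt_seq, mutants)
    n = len(mutants)
    protocol = EnsembleProtocol(n_sets=n_sets,
                                train_size=round(n * 100 / 135),
                                test_size=n - round(n * 100 / 135),
                                models_per_set=models_per_set)
    cfg = TrainConfig(learning_rate=learning_rate, max_epochs=epochs,
                      checkpoint_interval=checkpoint_interval,
                      batch_size=4, seed=seed)
    result = train_ensemble(lambda rng: SequenceNet(rng=rng), X, y, cfg,
                            protocol, seed=seed)
    preds = pd.Series(result.ensemble.predict(X), index=labels,
                      name="phenotype_pred")
    return SequenceEnsembleResult(
        ensemble=result.ensemble,
        overall_report=regression_metrics(y, preds.to_numpy()),
        mean_test_r2=result.mean_test_r2,
        per_set_reports=result.per_set_test_report,
        splits=result.splits,
        predictions=preds,
    )


@dataclass
class BaselineResult:
    overall_report: RegressionReport
    predictions: pd.Series


def position_baseline_analysis(mutants: list[MutantID], phenotypes: pd.Series,
                               splits: list[tuple[np.ndarray, np.ndarray]]
                               ) -> BaselineResult:
    """Per-position average baseline over the same training splits.

    For each split, position means are fitted on the training mutants and
    used to predict the whole library; predictions are averaged over the
    splits, mirroring the ensemble protocol.
    """
    labels = [m.label for m in mutants]
    y = phenotypes.loc[labels].to_numpy()
    all_preds = []
    for train_idx, _ in splits:
        model = PositionAverageBaseline([mutants[i] for i in train_idx],
                                        y[train_idx])
        all_preds.append(model.predict(mutants))
    preds = pd.Series(np.mean(all_preds, axis=0), index=labels)
    return BaselineResult(overall_report=regression_metrics(y, preds.to_numpy()),
                          predictions=preds)


def save_sequence_ensemble(ensemble: Ensemble, path) -> None:
    """Serialise sequence-net ensemble weights to one ``.npz`` archive."""
    arrays = {}
    for i, member in enumerate(ensemble.members):
        for j, w in enumerate(member.get_weights()):
            arrays[f"m{i}_w{j}"] = w
    arrays["n_members"] = np.array(len(ensemble.members))
    np.savez(path, **arrays)


def load_sequence_ensemble(path) -> Ensemble:
    """Rebuild a default-geometry sequence-net ensemble from ``.npz``."""
    data = np.load(path)
    n = int(data["n_members"])
    members = []
    for i in range(n):
        net = SequenceNet(rng=np.random.default_rng(0))
        weights = []
        j = 0
        while f"m{i}_w{j}" in data:
            weights.append(data[f"m{i}_w{j}"])
            j += 1
        net.set_weights(weights)
        members.append(net)
    return Ensemble(members)


# ---------------------------------------------------------------------------
# Stage 3: double mutants vs additivity
# ---------------------------------------------------------------------------

@dataclass
class DoubleMutantResult:
    report: RegressionReport             # predicted vs additive phenotypes
    landscapes: dict[str, PhenotypeLandscape]
    predicted: pd.Series
    additive: pd.Series


def double_mutant_analysis(ensemble, wt_seq: str,
                           backgrounds=DOUBLE_MUTANT_BACKGROUNDS
                           ) -> DoubleMutantResult:
    """Double-mutant landscapes on fixed backgrounds vs the additive null.

    The single-mutant landscape is predicted once; the additive phenotype
    of a double mutant is the sum of the two single-mutant predictions.
    The comparison regresses the directly predicted double-mutant
    phenotypes on the additive ones over all scanned cells of all
    backgrounds.
    """
    singles = predict_landscape(ensemble.predict, wt_seq)
    first_pos = singles.grid.index[0]
    landscapes: dict[str, PhenotypeLandscape] = {}
    predicted: dict[str, float] = {}
    additive: dict[str, float] = {}
    for background in backgrounds:
        bg = parse_mutant_id(background)
        bg_sub = bg.substitutions[0]
        bg_single = float(singles.grid.loc[bg_sub.position, bg_sub.sub_aa])
        ls = predict_landscape(ensemble.predict, wt_seq, second_site=bg)
        landscapes[background] = ls
        for pos in ls.grid.index:
            for aa in ls.grid.columns:
                value = ls.grid.loc[pos, aa]
                if np.isnan(value):
                    continue
                wt_aa = wt_seq[pos - first_pos]
                double_label = f"{wt_aa}{pos}{aa}-{background}"
                predicted[double_label] = float(value)
                additive[double_label] = additive_phenotype(
                    float(singles.grid.loc[pos, aa]), bg_single)
    pred = pd.Series(predicted)
    add = pd.Series(additive)
    return DoubleMutantResult(
        report=regression_metrics(add.to_numpy(), pred.to_numpy()),
        landscapes=landscapes, predicted=pred, additive=add,
    )


# ---------------------------------------------------------------------------
# Stage 4: distance VAE, clustering, centroid decoding
# ---------------------------------------------------------------------------

@dataclass
class DistanceVAEResult:
    model: VAE
    standardizer: Standardizer
    latent: pd.DataFrame                 # mutant, z0, z1, cluster, phenotype
    clusters: ClusterModel
    centroid_profiles: pd.DataFrame      # decoded_A / delta_A per cluster
    final_train_loss: float


def distance_vae_analysis(profiles: DistanceProfileSet, phenotypes: pd.Series,
                          wt_profile: pd.Series, k: int = 3,
                          latent_dim: int = 2, attention: bool = True,
                          epochs: int = 1200, kl_warmup_epochs: int = 1000,
                          learning_rate: float = 1e-4,
                          n_restarts: int = 4, seed: int = 0
                          ) -> DistanceVAEResult:
    """Attention VAE on averaged distances, k-means clusters, centroid decode.

    The schedule spends most of its budget with the prior-KL weight
    ramping up (a near-autoencoder phase in which the encoder learns all
    structured feature directions) and stops shortly after the full
    objective engages: training far past that point lets the latent
    space absorb within-group noise (one group elongates), which
    degrades the k-means partition without improving the decoded
    profiles.  Restart selection keeps the lowest final-training-loss
    model, which favours runs whose decoder reproduces every structured
    feature group.
    """
    X = profiles.distances.to_numpy()
    std = Standardizer.fit(X)
    Xs = std.transform(X)
    cfg = VAETrainConfig(learning_rate=learning_rate, epochs=epochs, seed=seed,
                         kl_warmup_epochs=kl_warmup_epochs)
    model, final_loss = train_vae_restarts(
        md_vae_spec(latent_dim=latent_dim, attention=attention), Xs, cfg,
        n_restarts=n_restarts, base_seed=seed)
    z = project_latent(model, Xs)
    ph = phenotypes.loc[profiles.distances.index].to_numpy()
    clusters = cluster_latent(z, k=k, phenotypes=ph, seed=seed)
    latent = pd.DataFrame(
        {f"z{i}": z[:, i] for i in range(z.shape[1])},
        index=profiles.distances.index,
    )
    latent["cluster"] = clusters.labels
    latent["phenotype"] = ph
    centroid_profiles = decode_profiles(model, clusters.centroids, std, wt_profile)
    return DistanceVAEResult(model=model, standardizer=std, latent=latent,
                             clusters=clusters,
                             centroid_profiles=centroid_profiles,
                             final_train_loss=final_loss)
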