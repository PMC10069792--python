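"""Synthetic study-condition datasets with known ground truth.

Every downstream stage of the pipeline (phenotype nets, sequence
ensembles, distance VAEs) is exercised on data generated here, so the
generators emit the ground truth alongside the observations and are
seed-deterministic.

The generators emulate the statistical structure of the real study:

* fitness matrices — 135 single mutants x 21 conditions x 3 replicates;
  each mutant carries a true continuum phenotype near its class anchor
  (GOF +1, LOF -1, lethal -2, WT 0, spread 0.2); each condition responds
  linearly with its own sensitivity (slope/offset, sign-discordant across
  conditions so hyper- and hypoactive mutants separate); replicate noise
  and missing entries are added on top;
* mutant sequence libraries — single/double substitutions applied to a
  fixed 31-mer WT trigger-loop sequence (arbitrary default; supply the
  real Rpb1 1076-1106 sequence for real-data runs);
* distance tables — 62-feature profiles with three planted mechanisms:
  lethal/LOF-A inflate the TL-GTP category, LOF-B inflate the TL-BH
  category, GOF/WT stay at the pocket-tight baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (DistanceProfileSet, MutantID, Substitution, TL_START,
                 fitness_columns, validate_fitness_matrix)
from .pairs import DEFAULT_PAIR_CATEGORIES, DEFAULT_PAIR_NAMES, TL_RESIDUES

#: Default WT 31-mer (positions 1076-1106).  An arbitrary fixed sequence
#: whose residue identities match the mutants discussed in the text
#: (A1076, Q1078, L1081, H1085, G1097, E1103, ...); the true Rpb1 sequence
#: must be user-supplied for real-data runs.
DEFAULT_WT_SEQ = "".join(TL_RESIDUES[p] for p in sorted(TL_RESIDUES))

#: Condition labels for the synthetic fitness assay (21 conditions).
DEFAULT_CONDITIONS = (
    "MPA", "Mn", "Raff", "RaffGal", "Lys", "Form",
    *(f"cond{i:02d}" for i in range(7, 22)),
)

#: Per-condition sensitivity slopes.  Sign-discordant by design: some
#: conditions reward hyperactivity (positive slope), others punish it, so
#: GOF and LOF mutants are separable from the fitness profile alone.
DEFAULT_SLOPES = (
    1.00, -0.80, 0.60, -1.10, 0.90, -0.50, 0.75, 0.40, -0.65, 1.20,
    -0.30, 0.55, 0.85, -0.95, 0.25, 0.70, -0.45, 1.05, -0.70, 0.35, 0.50,
)

#: Per-condition offsets (condition-specific baseline growth).
DEFAULT_OFFSETS = (
    0.00, 0.10, -0.05, 0.15, -0.10, 0.05, 0.00, -0.15, 0.10, 0.05,
    -0.05, 0.00, 0.10, -0.10, 0.05, 0.00, 0.15, -0.05, 0.00, 0.10, -0.10,
)

_CLASS_ANCHORS = {"GOF": 1.0, "LOF": -1.0, "lethal": -2.0, "WT": 0.0}

#: Baseline WT distance per category (Å), kept within the 2-12 Å range
#: typical of close active-site contacts.
_CATEGORY_BASELINE = {
    "GTP-other": 3.0, "TL-GTP": 4.0, "TL-BH": 5.0, "BH-BH": 4.5, "TL-TL": 6.0,
}

MECHANISM_TL_GTP = "TL-GTP-inflated"
MECHANISM_BH_TL = "BH-TL-inflated"
MECHANISM_BASELINE = "baseline"


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic generators."""

    n_mutants: int = 135
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {"GOF": 0.20, "LOF": 0.35, "lethal": 0.25, "WT": 0.20}
    )
    slopes: tuple[float, ...] = DEFAULT_SLOPES
    offsets: tuple[float, ...] = DEFAULT_OFFSETS
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_replicates: int = 3
    sigma_rep: float = 0.1
    missingness: float = 0.05
    phenotype_spread: float = 0.2
    delta_tl_gtp: float = 2.0
    delta_bh_tl: float = 2.0
    sigma_d: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValueError("class proportions must be non-negative")
        if self.sigma_rep < 0 or self.sigma_d < 0:
            raise ValueError("noise levels must be >= 0")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0, 1)")
        if self.delta_tl_gtp < 0 or self.delta_bh_tl < 0:
            raise ValueError("mechanism effect sizes must be >= 0")
        if len(self.slopes) != len(self.conditions) or len(self.offsets) != len(self.conditions):
            raise ValueError("slopes/offsets must match the number of conditions")


# ---------------------------------------------------------------------------
# Mutant libraries and sequences
# ---------------------------------------------------------------------------

def random_mutant_library(n: int, rng: np.random.Generator,
                          wt_seq: str = DEFAULT_WT_SEQ) -> list[MutantID]:
    """Draw ``n`` distinct single-substitution mutants of the WT sequence."""
    n_positions = len(wt_seq)
    if n > n_positions * 19:
        raise ValueError(f"at most {n_positions * 19} distinct single mutants exist")
    standard = [a for a in "ACDEFGHIKLMNPQRSTVWY"]
    seen: set[str] = set()
    mutants: list[MutantID] = []
    while len(mutants) < n:
        idx = int(rng.integers(n_positions))
        wt_aa = wt_seq[idx]
        sub_aa = standard[int(rng.integers(20))]
        if sub_aa == wt_aa:
            continue
        m = MutantID((Substitution(wt_aa, TL_START + idx, sub_aa),))
        if m.label in seen:
            continue
        seen.add(m.label)
        mutants.append(m)
    return mutants


def generate_sequence_library(wt_seq: str, mutants: list[MutantID],
                              protonated_positions=None) -> list[list[str]]:
    """Token sequences for a mutant list; Hamming distance from WT equals
    the substitution count of each mutant."""
    from .io import DEFAULT_PROTONATED_POSITIONS, apply_substitutions
    if protonated_positions is None:
        protonated_positions = DEFAULT_PROTONATED_POSITIONS
    return [apply_substitutions(wt_seq, m, protonated_positions) for m in mutants]


@dataclass
class AdditiveSequenceEffects:
    """Ground-truth additive sequence-phenotype map.

    A mutant's phenotype is the sum, over its substitutions, of a
    position effect and a substituted-residue effect.  Both components
    are shared across mutants (the residue effect across positions), so
    the map generalises to held-out substitutions — the synthetic
    analogue of sequence determinants that a model can learn.
    """

    position_effect: np.ndarray            # (31,)
    residue_effect: dict[str, float]       # per substituted amino acid

    def phenotype(self, mutant: MutantID) -> float:
        total = 0.0
        for sub in mutant.substitutions:
            total += self.position_effect[sub.position - TL_START]
            total += self.residue_effect[sub.sub_aa]
        return float(total)

    def phenotypes(self, mutants: list[MutantID]) -> np.ndarray:
        return np.array([self.phenotype(m) for m in mutants])


def additive_sequence_effects(rng: np.random.Generator,
                              position_sd: float = 0.6,
                              residue_sd: float = 0.5) -> AdditiveSequenceEffects:
    """Draw an additive ground-truth map with the default effect scales."""
    pos = rng.normal(0.0, position_sd, size=31)
    res = dict(zip("ACDEFGHIKLMNPQRSTVWY", rng.normal(0.0, residue_sd, size=20)))
    return AdditiveSequenceEffects(position_effect=pos, residue_effect=res)


def _draw_phenotypes(spec: SyntheticSpec, rng: np.random.Generator,
                     mutants: list[MutantID]) -> pd.DataFrame:
    classes = list(spec.class_proportions)
    probs = np.array([spec.class_proportions[c] for c in classes])
    drawn = rng.choice(classes, size=len(mutants), p=probs)
    values = np.array([_CLASS_ANCHORS[c] for c in drawn])
    values = values + rng.normal(0.0, spec.phenotype_spread, size=len(mutants))
    return pd.DataFrame(
        {"phenotype_value": values, "phenotype_class": drawn},
        index=pd.Index([m.label for m in mutants], name="mutant"),
    )


# ---------------------------------------------------------------------------
# Fitness matrices
# ---------------------------------------------------------------------------

def generate_fitness_dataset(spec: SyntheticSpec,
                             mutants: list[MutantID] | None = None,
                             phenotypes: np.ndarray | None = None
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fitness matrix plus ground-truth phenotypes.

    Each entry is ``a_c * p + b_c + Normal(0, sigma_rep)`` for the
    mutant's true phenotype ``p`` and its condition's sensitivity; entries
    are masked missing (NaN) independently with the spec's missingness
    probability.  Returns ``(fitness, truth)`` where ``truth`` has columns
    phenotype_value and phenotype_class.

    By default phenotypes are drawn near the class anchors; passing
    ``phenotypes`` (aligned with ``mutants``) instead plants externally
    determined values, e.g. additive sequence effects, so that the whole
    fitness -> phenotype -> sequence chain shares one ground truth.
    """
    from .io import classify_phenotype_value

    rng = np.random.default_rng(spec.seed)
    if mutants is None:
        mutants = random_mutant_library(spec.n_mutants, rng)
    if phenotypes is None:
        truth = _draw_phenotypes(spec, rng, mutants)
    else:
        values = np.asarray(phenotypes, dtype=float)
        if values.size != len(mutants):
            raise ValueError("phenotypes must align with mutants")
        truth = pd.DataFrame(
            {"phenotype_value": values,
             "phenotype_class": [classify_phenotype_value(v) for v in values]},
            index=pd.Index([m.label for m in mutants], name="mutant"),
        )
    p = truth["phenotype_value"].to_numpy()

    columns = fitness_columns(spec.conditions, spec.n_replicates)
    slopes = np.repeat(spec.slopes, spec.n_replicates)
    offsets = np.repeat(spec.offsets, spec.n_replicates)
    clean = p[:, None] * slopes[None, :] + offsets[None, :]
    noisy = clean + rng.normal(0.0, spec.sigma_rep, size=clean.shape)
    if spec.missingness > 0:
        mask = rng.random(noisy.shape) < spec.missingness
        noisy = np.where(mask, np.nan, noisy)
    fitness = pd.DataFrame(noisy, index=truth.index, columns=columns)
    validate_fitness_matrix(fitness)
    return fitness, truth


# ---------------------------------------------------------------------------
# Distance tables with planted mechanisms
# ---------------------------------------------------------------------------

def wt_distance_profile() -> pd.Series:
    """Deterministic WT baseline profile over the default 62-pair catalog."""
    values = []
    for i, name in enumerate(DEFAULT_PAIR_NAMES):
        base = _CATEGORY_BASELINE[DEFAULT_PAIR_CATEGORIES[name]]
        values.append(base + ((i * 37) % 10) * 0.15)   # 0.0 .. 1.35 Å spread
    return pd.Series(values, index=DEFAULT_PAIR_NAMES, name="WT")


def generate_distance_dataset(spec: SyntheticSpec,
                              mutants: list[MutantID] | None = None
                              ) -> tuple[DistanceProfileSet, pd.Series, pd.DataFrame]:
    """Distance profiles with three planted mechanisms.

    * lethal and half of the LOF mutants inflate every TL-GTP distance by
      ``delta_tl_gtp`` (direct active-site distortion);
    * the other half of the LOF mutants inflate every TL-BH distance by
      ``delta_bh_tl`` (bridge-helix decoupling);
    * GOF and WT-like mutants keep the tight baseline profile.

    Gaussian noise ``sigma_d`` is added per feature.  Returns
    ``(profiles, mechanism_labels, truth)``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    if mutants is None:
        mutants = random_mutant_library(spec.n_mutants, rng)
    truth = _draw_phenotypes(spec, rng, mutants)

    wt = wt_distance_profile()
    tl_gtp_cols = [n for n in DEFAULT_PAIR_NAMES if DEFAULT_PAIR_CATEGORIES[n] == "TL-GTP"]
    tl_bh_cols = [n for n in DEFAULT_PAIR_NAMES if DEFAULT_PAIR_CATEGORIES[n] == "TL-BH"]

    mechanisms = []
    rows = []
    for label, cls in truth["phenotype_class"].items():
        profile = wt.copy()
        if cls == "lethal" or (cls == "LOF" and rng.random() < 0.5):
            profile[tl_gtp_cols] += spec.delta_tl_gtp
            mech = MECHANISM_TL_GTP
        elif cls == "LOF":
            profile[tl_bh_cols] += spec.delta_bh_tl
            mech = MECHANISM_BH_TL
        else:
            mech = MECHANISM_BASELINE
        mechanisms.append(mech)
        rows.append(profile.to_numpy())

    data = np.array(rows)
    if spec.sigma_d > 0:
        data = data + rng.normal(0.0, spec.sigma_d, size=data.shape)
        data = np.maximum(data, 0.05)   # distances stay strictly positive
    distances = pd.DataFrame(data, index=truth.index, columns=DEFAULT_PAIR_NAMES)
    profiles = DistanceProfileSet(distances, dict(DEFAULT_PAIR_CATEGORIES))
    mech_series = pd.Series(mechanisms, index=truth.index, name="mechanism")
    return profiles, mech_series, truth
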