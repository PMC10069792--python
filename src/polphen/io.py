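"""Data model and I/O for trigger-loop mutant datasets.

The package works with three tabular inputs:

* fitness matrices — mutants x (condition, replicate) log2 allele-frequency
  fitness scores from pooled growth assays, with missing entries;
* 31-residue trigger-loop (TL) sequences for single/double mutants, Rpb1
  numbering 1076-1106;
* per-mutant averaged inter-residue distance profiles (62 distances, Å)
  derived from MD trajectories.

Phenotypes live on a real continuum anchored at the classical discrete
classes: gain-of-function (GOF) at +1, loss-of-function (LOF) at -1, lethal
at -2 and wild type / indeterminate at 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# Rpb1 trigger-loop span (author numbering).
TL_START = 1076
TL_END = 1106
TL_LENGTH = TL_END - TL_START + 1  # 31

#: 20 standard amino acids plus the protonated-histidine token.  The order
#: fixes the one-hot channel layout used by the sequence models: channel 21
#: (index 20) is protonated His.
PROTONATED_HIS = "HSP"
AA_ALPHABET: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY") + (PROTONATED_HIS,)
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

#: Position whose histidine is modelled protonated by default.
DEFAULT_PROTONATED_POSITIONS = frozenset({1085})

#: Distance-profile categories (fixed set).
DISTANCE_CATEGORIES = ("TL-TL", "TL-BH", "BH-BH", "TL-GTP", "GTP-other")

PHENOTYPE_CLASSES = ("GOF", "LOF", "lethal", "WT")

_CLASS_VALUES = {"GOF": 1.0, "LOF": -1.0, "lethal": -2.0, "WT": 0.0}

_SUB_RE = re.compile(r"^([A-Z])(\d{3,4})([A-Z]|HSP)$")


class MutantParseError(ValueError):
    """Raised for malformed or out-of-range mutant labels."""


@dataclass(frozen=True)
class Substitution:
    wt_aa: str
    position: int
    sub_aa: str

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.sub_aa}"


@dataclass(frozen=True)
class MutantID:
    """One or two amino-acid substitutions in the trigger loop, or WT.

    The canonical label joins substitutions with ``-`` (e.g. ``E1103G``,
    ``H1085Q-Q1078S``); the empty substitution list is labelled ``WT``.
    """

    substitutions: tuple[Substitution, ...] = ()

    @property
    def label(self) -> str:
        if not self.substitutions:
            return "WT"
        return "-".join(str(s) for s in self.substitutions)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.position for s in self.substitutions)

    def __str__(self) -> str:
        return self.label


def parse_mutant_id(label: str) -> MutantID:
    """Parse a mutant label such as ``"E1103G"`` or ``"H1085Q-Q1078S"``.

    ``"WT"`` yields an empty substitution list.  Positions must fall within
    the trigger loop (1076-1106); at most two substitutions are accepted.
    The protonated-His token ``HSP`` is allowed as a substitution target.
    """
    if not isinstance(label, str):
        raise MutantParseError(f"mutant label must be a string, got {type(label)!r}")
    text = label.strip()
    if text == "WT":
        return MutantID()
    parts = text.split("-")
    if len(parts) > 2:
        raise MutantParseError(
            f"{label!r}: at most two substitutions are supported, got {len(parts)}"
        )
    subs = []
    for part in parts:
        m = _SUB_RE.match(part)
        if m is None:
            raise MutantParseError(f"{label!r}: malformed substitution {part!r}")
        wt_aa, pos_s, sub_aa = m.groups()
        pos = int(pos_s)
        if not TL_START <= pos <= TL_END:
            raise MutantParseError(
                f"{label!r}: position {pos} outside trigger loop "
                f"{TL_START}-{TL_END}"
            )
        if wt_aa == sub_aa:
            raise MutantParseError(f"{label!r}: substitution {part!r} is silent")
        if wt_aa not in AA_INDEX or wt_aa == PROTONATED_HIS:
            raise MutantParseError(f"{label!r}: unknown wild-type residue {wt_aa!r}")
        if sub_aa not in AA_INDEX:
            raise MutantParseError(f"{label!r}: unknown substitution {sub_aa!r}")
        subs.append(Substitution(wt_aa, pos, sub_aa))
    if len(subs) == 2 and subs[0].position == subs[1].position:
        raise MutantParseError(f"{label!r}: both substitutions at one position")
    return MutantID(tuple(subs))


def encode_phenotype_class(phenotype_class: str) -> float:
    """Map a discrete phenotype class to its continuum anchor value.

    GOF -> +1.0, LOF -> -1.0, lethal -> -2.0, WT/indeterminate -> 0.0.
    """
    try:
        return _CLASS_VALUES[phenotype_class]
    except KeyError:
        raise ValueError(
            f"unknown phenotype class {phenotype_class!r}; "
            f"expected one of {PHENOTYPE_CLASSES}"
        ) from None


@dataclass(frozen=True)
class PhenotypeBands:
    """Band edges mapping continuum values back to discrete classes.

    Only the lethal cutoff (-1.5) is anchored by convention; the LOF/WT and
    WT/GOF edges default to +-0.5, symmetric around the class anchors.
    """

    lethal_max: float = -1.5   # value <= lethal_max  -> lethal
    lof_max: float = -0.5      # value <= lof_max     -> LOF
    gof_min: float = 0.5       # value >= gof_min     -> GOF


def classify_phenotype_value(value: float, bands: PhenotypeBands = PhenotypeBands()) -> str:
    """Classify a continuum phenotype value into lethal/LOF/WT/GOF bands."""
    if not np.isfinite(value):
        raise ValueError(f"phenotype value must be finite, got {value!r}")
    if value <= bands.lethal_max:
        return "lethal"
    if value <= bands.lof_max:
        return "LOF"
    if value >= bands.gof_min:
        return "GOF"
    return "WT"


# ---------------------------------------------------------------------------
# Fitness matrices
# ---------------------------------------------------------------------------

N_CONDITIONS = 21
N_REPLICATES = 3

_COLUMN_RE = re.compile(r"^(?P<condition>.+)_rep(?P<replicate>[123])$")


def fitness_columns(conditions: Sequence[str], n_replicates: int = N_REPLICATES) -> list[str]:
    """Column labels ``<condition>_rep<r>`` in condition-major order."""
    return [f"{c}_rep{r}" for c in conditions for r in range(1, n_replicates + 1)]


def validate_fitness_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Check a mutants x (condition, replicate) fitness table.

    Requires 63 data columns matching ``<condition>_rep<1..3>`` and
    parseable mutant labels in the index.  Missing values are NaN.
    """
    bad = [c for c in df.columns if _COLUMN_RE.match(str(c)) is None]
    if bad:
        raise ValueError(f"fitness columns not matching '<condition>_rep<r>': {bad}")
    conditions = {_COLUMN_RE.match(str(c))["condition"] for c in df.columns}
    expected = len(conditions) * N_REPLICATES
    if len(df.columns) != expected:
        raise ValueError(
            f"expected {expected} columns ({len(conditions)} conditions x "
            f"{N_REPLICATES} replicates), got {len(df.columns)}"
        )
    for label in df.index:
        parse_mutant_id(str(label))
    return df


def read_fitness_table(path) -> pd.DataFrame:
    """Read a CSV/TSV fitness table into a validated DataFrame.

    The mutant column is named ``mutant``; empty cells and ``NA`` are read
    as missing (NaN), never as numeric sentinels.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, na_values=["NA"], index_col="mutant")
    df = df.astype(float)
    return validate_fitness_matrix(df)


def write_fitness_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="mutant", na_rep="")


def impute_missing(df: pd.DataFrame) -> pd.DataFrame:
    """Replace missing entries by the column (feature) mean of observed values.

    Observed entries are unchanged and each column mean is preserved.  A
    fully-missing column cannot be imputed and raises, naming the column.
    """
    empty = [c for c in df.columns if df[c].notna().sum() == 0]
    if empty:
        raise ValueError(f"cannot impute fully-missing column(s): {empty}")
    return df.fillna(df.mean())


# ---------------------------------------------------------------------------
# Phenotype tables and distance profiles
# ---------------------------------------------------------------------------

def read_phenotype_table(path) -> pd.DataFrame:
    """CSV with columns mutant, phenotype_value[, phenotype_class]."""
    df = pd.read_csv(path, index_col="mutant")
    if "phenotype_value" not in df.columns:
        raise ValueError("phenotype table must have a 'phenotype_value' column")
    return df


def write_phenotype_table(values: pd.Series, path, bands: PhenotypeBands = PhenotypeBands()) -> None:
    out = pd.DataFrame(
        {
            "phenotype_value": values,
            "phenotype_class": [classify_phenotype_value(v, bands) for v in values],
        }
    )
    out.to_csv(path, index_label="mutant")


@dataclass
class DistanceProfileSet:
    """Per-mutant averaged minimum inter-residue distances (Å).

    ``distances`` is a mutants x features DataFrame; ``categories`` maps
    each feature name to one of the five structural categories.
    """

    distances: pd.DataFrame
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.distances.columns.duplicated().any():
            raise ValueError("distance feature names must be unique")
        if (self.distances.to_numpy() <= 0).any():
            raise ValueError("all distances must be strictly positive")
        for name, cat in self.categories.items():
            if cat not in DISTANCE_CATEGORIES:
                raise ValueError(f"unknown distance category {cat!r} for {name!r}")

    @property
    def n_features(self) -> int:
        return self.distances.shape[1]

    def features_in_category(self, category: str) -> list[str]:
        return [n for n, c in self.categories.items() if c == category]


def read_distance_table(path) -> DistanceProfileSet:
    """Read a distance CSV whose second header row carries categories.

    Layout: first line ``mutant,<name1>,...``; second line
    ``category,<cat1>,...``; then one row per mutant.
    """
    raw = pd.read_csv(path, index_col=0)
    if len(raw) == 0 or raw.index[0] != "category":
        raise ValueError("distance table must carry a 'category' row after the header")
    categories = {c: str(raw.loc["category", c]) for c in raw.columns}
    body = raw.drop(index="category").astype(float)
    body.index.name = "mutant"
    return DistanceProfileSet(body, categories)


def write_distance_table(profiles: DistanceProfileSet, path) -> None:
    cat_row = pd.DataFrame(
        [ [profiles.categories.get(c, "") for c in profiles.distances.columns] ],
        index=pd.Index(["category"], name="mutant"),
        columns=profiles.distances.columns,
    )
    pd.concat([cat_row, profiles.distances]).to_csv(path, index_label="mutant")


def apply_substitutions(wt_seq: str, mutant: MutantID,
                        protonated_positions: Iterable[int] = DEFAULT_PROTONATED_POSITIONS) -> list[str]:
    """Apply a mutant's substitutions to the 31-mer WT trigger-loop sequence.

    Returns a per-position token list (tokens from :data:`AA_ALPHABET`).
    Histidines at ``protonated_positions`` are emitted as the protonated
    token unless substituted away.  The label's wild-type residues must
    agree with ``wt_seq``.
    """
    if len(wt_seq) != TL_LENGTH:
        raise ValueError(f"WT sequence must have length {TL_LENGTH}, got {len(wt_seq)}")
    tokens = list(wt_seq)
    for sub in mutant.substitutions:
        idx = sub.position - TL_START
        if tokens[idx] != sub.wt_aa:
            raise ValueError(
                f"{mutant.label}: wild-type residue mismatch at {sub.position} "
                f"(sequence has {tokens[idx]}, label says {sub.wt_aa})"
            )
        tokens[idx] = sub.sub_aa
    protonated = set(protonated_positions)
    for i, tok in enumerate(tokens):
        if tok == "H" and (TL_START + i) in protonated:
            tokens[i] = PROTONATED_HIS
    return tokens
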