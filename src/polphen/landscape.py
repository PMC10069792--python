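"""Phenotype landscapes, additivity analysis, and the per-position baseline.

A phenotype landscape is the grid of predicted continuum phenotypes for
every single substitution at trigger-loop positions 1076-1106 (19 non-WT
substitutions per position), optionally on a fixed second-site background
for double-mutant maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import encode_mutants
from .io import (DEFAULT_PROTONATED_POSITIONS, MutantID, Substitution,
                 TL_START, parse_mutant_id)
from .metrics import RegressionReport, regression_metrics  # noqa: F401  (re-export)

STANDARD_AAS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class PhenotypeLandscape:
    """Grid of predictions: rows are positions 1076-1106, columns the 20
    standard amino acids; WT cells (and second-site collisions) are NaN,
    leaving 31 x 19 predicted entries for single-mutant maps."""

    grid: pd.DataFrame
    second_site: MutantID | None = None

    @property
    def position_mean(self) -> pd.Series:
        """Mean predicted phenotype per position (all predicted cells)."""
        return self.grid.mean(axis=1)

    @property
    def substitution_mean(self) -> pd.Series:
        """Mean predicted phenotype per substitution across positions."""
        return self.grid.mean(axis=0)

    def to_csv(self, path) -> None:
        out = self.grid.copy()
        out.loc["Mean"] = self.substitution_mean
        out.to_csv(path, index_label="position")


def scan_mutants(wt_seq: str, second_site: MutantID | None = None
                 ) -> list[tuple[int, str, MutantID | None]]:
    """Enumerate (position, substitution, mutant) for a landscape scan.

    A ``None`` mutant marks cells that are not predicted: the WT residue
    itself, or a position colliding with the second-site substitution.
    """
    cells: list[tuple[int, str, MutantID | None]] = []
    blocked = set(second_site.positions) if second_site is not None else set()
    for i, wt_aa in enumerate(wt_seq):
        pos = TL_START + i
        for aa in STANDARD_AAS:
            if aa == wt_aa or pos in blocked:
                cells.append((pos, aa, None))
                continue
            subs = (Substitution(wt_aa, pos, aa),)
            if second_site is not None:
                subs = subs + second_site.substitutions
            cells.append((pos, aa, MutantID(subs)))
    return cells


def predict_landscape(predict_fn, wt_seq: str,
                      second_site: MutantID | str | None = None,
                      protonated_positions=DEFAULT_PROTONATED_POSITIONS
                      ) -> PhenotypeLandscape:
    """Predict the full single-substitution landscape with an ensemble.

    ``predict_fn`` maps a one-hot stack (n, 31, 21) to n predictions (an
    :class:`polphen.nn.train.Ensemble`'s ``predict`` fits).  With a
    ``second_site`` mutant every scanned substitution is combined with
    that background; cells whose position collides with the background
    are flagged (NaN), not predicted.
    """
    if isinstance(second_site, str):
        second_site = parse_mutant_id(second_site)
    cells = scan_mutants(wt_seq, second_site)
    predictable = [m for _, _, m in cells if m is not None]
    encoded = encode_mutants(wt_seq, predictable, protonated_positions)
    values = np.asarray(predict_fn(encoded), dtype=float).ravel()
    if values.size != len(predictable):
        raise ValueError("predict_fn returned a wrong number of predictions")

    positions = [TL_START + i for i in range(len(wt_seq))]
    grid = pd.DataFrame(np.nan, index=pd.Index(positions, name="position"),
                        columns=list(STANDARD_AAS))
    it = iter(values)
    for pos, aa, m in cells:
        if m is not None:
            grid.loc[pos, aa] = next(it)
    return PhenotypeLandscape(grid=grid, second_site=second_site)


def additive_phenotype(p1: float, p2: float) -> float:
    """Null model for a double mutant: the sum of the single phenotypes."""
    return p1 + p2


class PositionAverageBaseline:
    """Predicts the mean training phenotype of the query's position.

    Positions unseen in training fall back to the global training mean.
    """

    def __init__(self, mutants: list[MutantID | str], phenotypes) -> None:
        values = np.asarray(phenotypes, dtype=float).ravel()
        if len(mutants) == 0:
            raise ValueError("baseline needs at least one training mutant")
        if len(mutants) != values.size:
            raise ValueError("mutant and phenotype counts differ")
        sums: dict[int, float] = {}
        counts: dict[int, int] = {}
        for m, v in zip(mutants, values):
            mid = parse_mutant_id(m) if isinstance(m, str) else m
            for pos in mid.positions:
                sums[pos] = sums.get(pos, 0.0) + v
                counts[pos] = counts.get(pos, 0) + 1
        self.position_mean = {p: sums[p] / counts[p] for p in sums}
        self.global_mean = float(values.mean())

    def predict_one(self, mutant: MutantID | str) -> float:
        mid = parse_mutant_id(mutant) if isinstance(mutant, str) else mutant
        if not mid.positions:
            return self.global_mean
        vals = [self.position_mean.get(p, self.global_mean) for p in mid.positions]
        return float(np.mean(vals))

    def predict(self, mutants) -> np.ndarray:
        return np.array([self.predict_one(m) for m in mutants])


def phenotype_distance_density(phenotypes, distances, bins: int | tuple[int, int] = 20
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Negative-log density map of phenotype vs average distance.

    Returns ``(free_energy, empty_mask, x_edges, y_edges)`` where
    ``free_energy = -ln(density)`` over a 2-D histogram normalised to a
    probability density; empty bins are flagged in ``empty_mask`` and set
    to the map maximum + 1 rather than infinity.
    """
    x = np.asarray(phenotypes, dtype=float).ravel()
    y = np.asarray(distances, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if x.size != y.size:
        raise ValueError("phenotype and distance samples must pair up")
    if isinstance(bins, int):
        bins = (bins, bins)
    if bins[0] < 2 or bins[1] < 2:
        raise ValueError("need at least 2 bins per axis")
    hist, x_edges, y_edges = np.histogram2d(x, y, bins=bins, density=True)
    empty = hist == 0
    fe = np.full_like(hist, np.nan)
    fe[~empty] = -np.log(hist[~empty])
    fe[empty] = (np.nanmax(fe) if (~empty).any() else 0.0) + 1.0
    return fe, empty, x_edges, y_edges
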