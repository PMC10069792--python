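"""One-hot encoding of trigger-loop sequences.

Each 31-residue sequence becomes a 31x21 binary matrix: 20 standard
amino-acid channels plus a dedicated channel for protonated histidine,
so the models can distinguish the protonated H1085 of the wild type from
an ordinary histidine.  Rows sum to one.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .io import (AA_ALPHABET, AA_INDEX, DEFAULT_PROTONATED_POSITIONS, MutantID,
                 TL_LENGTH, apply_substitutions)

N_CHANNELS = len(AA_ALPHABET)  # 21


def one_hot_encode(tokens: Sequence[str]) -> np.ndarray:
    """Encode a token sequence (see :data:`polphen.io.AA_ALPHABET`) as 31x21.

    Tokens may be single-letter amino acids or the protonated-His token.
    A plain string is accepted for sequences without protonation flags.
    """
    if len(tokens) != TL_LENGTH:
        raise ValueError(f"sequence must have length {TL_LENGTH}, got {len(tokens)}")
    out = np.zeros((TL_LENGTH, N_CHANNELS))
    for i, tok in enumerate(tokens):
        try:
            out[i, AA_INDEX[tok]] = 1.0
        except KeyError:
            raise ValueError(f"unknown residue token {tok!r} at position {i}") from None
    return out


def encode_mutants(wt_seq: str, mutants: Iterable[MutantID],
                   protonated_positions=DEFAULT_PROTONATED_POSITIONS) -> np.ndarray:
    """Stack one-hot matrices for a mutant library: (n, 31, 21)."""
    return np.stack([
        one_hot_encode(apply_substitutions(wt_seq, m, protonated_positions))
        for m in mutants
    ])
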