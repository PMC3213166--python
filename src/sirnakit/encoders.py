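"""Sequence and design-rule encodings of 19-nt siRNAs.

Four fixed-width representations feed the layer-1 regressors:

* numeric (width 19): A, U, C, G mapped to 1, 2, 3, 4 per position;
* binary (width 76): one-hot quartets, bit order (G, C, U, A), i.e.
  A = 0 0 0 1, U = 0 0 1 0, C = 0 1 0 0, G = 1 0 0 0;
* hybrid (width 95): each binary quartet followed by the position weight
  of the observed nucleotide — the Pearson correlation, learned from
  training data, between that (nucleotide, position) indicator and
  observed efficacy;
* rules (width 228 = 19 positions x 12 rule sets): +1 where a published
  design-rule set marks the nucleotide at that position as favoring high
  efficacy, -1 where it marks low efficacy, 0 where the set is silent.

All encoders are scikit-learn transformers operating on sequences of
19-character RNA strings.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ValidationError, normalize_sequence

NUCLEOTIDES = ("A", "U", "C", "G")
_NUMERIC_CODE = {"A": 1.0, "U": 2.0, "C": 3.0, "G": 4.0}
# quartet bit order is (G, C, U, A) left to right
_BINARY_CODE = {
    "A": (0.0, 0.0, 0.0, 1.0),
    "U": (0.0, 0.0, 1.0, 0.0),
    "C": (0.0, 1.0, 0.0, 0.0),
    "G": (1.0, 0.0, 0.0, 0.0),
}
SEQ_LEN = 19


def _check_seq(seq: str) -> str:
    seq = normalize_sequence(seq)
    if len(seq) != SEQ_LEN:
        raise ValidationError(f"encoders need 19-nt sequences, got length {len(seq)}")
    return seq


def encode_numeric(seq: str) -> np.ndarray:
    """Width-19 numeric encoding: A->1, U->2, C->3, G->4 per position."""
    seq = _check_seq(seq)
    return np.array([_NUMERIC_CODE[b] for b in seq])


def encode_binary(seq: str) -> np.ndarray:
    """Width-76 one-hot encoding: 19 quartets in (G, C, U, A) bit order."""
    seq = _check_seq(seq)
    return np.concatenate([_BINARY_CODE[b] for b in seq])


@dataclass(frozen=True)
class PositionWeightTable:
    """Per-(nucleotide, position) correlation weights.

    ``p[(b, n)]`` is the Pearson correlation between the 0/1 indicator
    "nucleotide at position n equals b" and observed efficacy; positions
    are 1-based, 5'->3' on the sense strand.  76 entries, each in [-1, 1].
    """

    p: dict[tuple[str, int], float]

    def __post_init__(self) -> None:
        if len(self.p) != 4 * SEQ_LEN:
            raise ValidationError(
                f"position weight table has {len(self.p)} entries, expected 76"
            )
        for (b, n), v in self.p.items():
            if b not in NUCLEOTIDES or not 1 <= n <= SEQ_LEN:
                raise ValidationError(f"bad position-weight key ({b!r}, {n})")
            if not -1.0 - 1e-9 <= v <= 1.0 + 1e-9:
                raise ValidationError(f"weight p[{b},{n}]={v} outside [-1, 1]")

    @classmethod
    def zeros(cls) -> "PositionWeightTable":
        return cls({(b, n): 0.0 for b in NUCLEOTIDES for n in range(1, SEQ_LEN + 1)})


def fit_position_weights(
    sequences: Sequence[str], efficacies: Iterable[float]
) -> PositionWeightTable:
    """Correlate each (nucleotide, position) indicator with efficacy.

    Cells whose indicator has zero variance across the training set (the
    nucleotide is always or never present at that position), or a constant
    efficacy vector, yield weight 0 with a warning rather than NaN.
    """
    y = np.asarray(list(efficacies), dtype=float)
    if len(sequences) != len(y) or len(y) < 3:
        raise ValidationError("position weights need >= 3 labeled records")
    seqs = [_check_seq(s) for s in sequences]
    yc = y - y.mean()
    y_ss = float(yc @ yc)
    p: dict[tuple[str, int], float] = {}
    degenerate = []
    for n in range(1, SEQ_LEN + 1):
        col = np.array([s[n - 1] for s in seqs])
        for b in NUCLEOTIDES:
            x = (col == b).astype(float)
            xc = x - x.mean()
            x_ss = float(xc @ xc)
            if x_ss == 0.0 or y_ss == 0.0:
                p[(b, n)] = 0.0
                degenerate.append((b, n))
            else:
                p[(b, n)] = float(xc @ yc / np.sqrt(x_ss * y_ss))
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} zero-variance (nucleotide, position) cells "
            f"set to weight 0, e.g. {degenerate[:3]}",
            stacklevel=2,
        )
    return PositionWeightTable(p)


def encode_hybrid(seq: str, weights: PositionWeightTable) -> np.ndarray:
    """Width-95 hybrid encoding: each one-hot quartet plus its position weight."""
    seq = _check_seq(seq)
    out = np.empty(5 * SEQ_LEN)
    for i, b in enumerate(seq):
        out[5 * i : 5 * i + 4] = _BINARY_CODE[b]
        out[5 * i + 4] = weights.p[(b, i + 1)]
    return out


@dataclass(frozen=True)
class RuleTable:
    """A collection of named design-rule sets with per-position verdicts.

    ``verdict[(rule_set, position, nucleotide)]`` is +1 (preferred for
    high efficacy), -1 (disfavored); absent keys mean the set is silent
    there.  ``sets`` fixes the encoding order of the rule sets.
    """

    sets: tuple[str, ...]
    verdict: dict[tuple[str, int, str], int]

    def __post_init__(self) -> None:
        for (rs, pos, b), v in self.verdict.items():
            if rs not in self.sets:
                raise ValidationError(f"verdict references unknown rule set {rs!r}")
            if not 1 <= pos <= SEQ_LEN or b not in NUCLEOTIDES:
                raise ValidationError(f"bad rule key ({rs!r}, {pos}, {b!r})")
            if v not in (-1, 1):
                raise ValidationError(f"rule verdict must be +1 or -1, got {v}")


def load_rule_table(
    path: str | os.PathLike | None = None, require_12_sets: bool = True
) -> RuleTable:
    """Load a rule table from TSV columns rule_set, position, nucleotide, verdict.

    Lines starting with '#' are comments.  By default the standard 12-set
    count is enforced; pass ``require_12_sets=False`` for custom
    collections.  Conflicting verdicts within one set at one
    (position, nucleotide) are rejected at load time.
    """
    if path is None:
        src = resources.files("sirnakit.data").joinpath("rule_sets.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    need = {"rule_set", "position", "nucleotide", "verdict"}
    if not need <= set(df.columns):
        raise ValidationError(f"rule table needs columns {sorted(need)}")
    sets: list[str] = []
    verdict: dict[tuple[str, int, str], int] = {}
    for row in df.itertuples(index=False):
        rs = str(row.rule_set)
        if rs not in sets:
            sets.append(rs)
        key = (rs, int(row.position), normalize_sequence(str(row.nucleotide)))
        v = int(row.verdict)
        if key in verdict and verdict[key] != v:
            raise ValidationError(
                f"conflicting verdicts within rule set {rs!r} at "
                f"position {key[1]} nucleotide {key[2]}"
            )
        verdict[key] = v
    if require_12_sets and len(sets) != 12:
        raise ValidationError(
            f"rule table has {len(sets)} rule sets, expected 12 "
            "(pass require_12_sets=False for custom collections)"
        )
    return RuleTable(tuple(sets), verdict)


def encode_rules(seq: str, rules: RuleTable) -> np.ndarray:
    """Width 19 x n_sets rule encoding in {-1, 0, +1}, position-major."""
    seq = _check_seq(seq)
    out = np.zeros(SEQ_LEN * len(rules.sets))
    for i, b in enumerate(seq):
        for j, rs in enumerate(rules.sets):
            out[i * len(rules.sets) + j] = rules.verdict.get((rs, i + 1, b), 0)
    return out


class _SequenceEncoderBase(BaseEstimator, TransformerMixin):
    """Shared plumbing: transform a sequence collection to a 2-D array."""

    def _encode_one(self, seq: str) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        return np.vstack([self._encode_one(seq) for seq in _as_sequences(X)])


def _as_sequences(X) -> list[str]:
    if hasattr(X, "sequences"):  # Dataset
        return list(X.sequences)
    arr = np.asarray(X, dtype=object).ravel()
    return [str(s) for s in arr]


class NumericEncoder(_SequenceEncoderBase):
    """Stateless transformer for the width-19 numeric encoding."""

    def _encode_one(self, seq: str) -> np.ndarray:
        return encode_numeric(seq)


class BinaryEncoder(_SequenceEncoderBase):
    """Stateless transformer for the width-76 one-hot encoding."""

    def _encode_one(self, seq: str) -> np.ndarray:
        return encode_binary(seq)


class HybridEncoder(_SequenceEncoderBase):
    """One-hot quartets augmented with learned position-correlation weights.

    ``fit`` requires labeled data: it computes the 76-entry
    :class:`PositionWeightTable` from the training sequences and
    efficacies; ``transform`` emits width-95 vectors.
    """

    def fit(self, X, y):
        if y is None:
            raise ValidationError("HybridEncoder.fit requires efficacies (y)")
        self.weights_ = fit_position_weights(_as_sequences(X), np.asarray(y, float))
        self.n_features_in_ = 1
        return self

    def _encode_one(self, seq: str) -> np.ndarray:
        return encode_hybrid(seq, self.weights_)


class RuleEncoder(_SequenceEncoderBase):
    """Transformer for the 228-wide (12 rule sets) design-rule encoding."""

    def __init__(self, rule_table: RuleTable | None = None):
        self.rule_table = rule_table

    def fit(self, X, y=None):
        self.rule_table_ = (
            self.rule_table if self.rule_table is not None else load_rule_table()
        )
        self.n_features_in_ = 1
        return self

    def _encode_one(self, seq: str) -> np.ndarray:
        return encode_rules(seq, self.rule_table_)
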