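"""Correlation-selected feature sets for siRNA efficacy regression.

Three families of candidate features are screened against training
efficacy with Pearson correlation:

* ``single`` — 76 indicator features "nucleotide b at position n"
  (value 1 when the input sequence matches, else 0);
* ``ngram``  — overlapping occurrence counts of every subword of length
  2..5 observed in the training sequences (frequency, not mere presence);
* ``thermo`` — 21 nearest-neighbor duplex-stability values: the 18
  antisense stacking dG37 terms, their sum (whole_dG), and whole-duplex
  dH and dS.

Selection keeps single/ngram features that are significant (p < 0.001 by
the exact t-test of a Pearson correlation) and, when a threshold is set,
have |r| strictly above it; thermodynamic features are always retained.
The named method family differs only in its |r| thresholds
(single/ngram): F162 none/none, F85 0.10/0.09, F65 0.12/0.10,
F47 0.13/0.12.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ValidationError, normalize_sequence
from .thermo import ThermoParams, compute_thermo, default_params

NGRAM_LENGTHS = (2, 3, 4, 5)
KIND_ORDER = {"single": 0, "ngram": 1, "thermo": 2}

#: |r| thresholds (single, ngram) of the standard method family; None means
#: no correlation filter (significance filter still applies).
METHOD_THRESHOLDS: dict[str, tuple[float | None, float | None]] = {
    "F162": (None, None),
    "F85": (0.10, 0.09),
    "F65": (0.12, 0.10),
    "F47": (0.13, 0.12),
}


@dataclass(frozen=True)
class FeatureElement:
    """One candidate or selected feature with its training-set statistics."""

    kind: str  # single | ngram | thermo
    key: str  # e.g. "pos7:A", "ngram:AG", "stack:12-13", "wholeG"
    r_train: float
    p_value: float

    def __post_init__(self) -> None:
        if self.kind not in KIND_ORDER:
            raise ValidationError(f"unknown feature kind {self.kind!r}")


@dataclass(frozen=True)
class FeatureSetSpec:
    """A frozen, ordered feature list plus the thresholds that produced it."""

    name: str
    elements: tuple[FeatureElement, ...]
    threshold_single: float | None = None
    threshold_ngram: float | None = None

    def __len__(self) -> int:
        return len(self.elements)

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "threshold_single": self.threshold_single,
                "threshold_ngram": self.threshold_ngram,
                "elements": [
                    {"kind": e.kind, "key": e.key, "r": e.r_train, "p": e.p_value}
                    for e in self.elements
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureSetSpec":
        d = json.loads(text)
        return cls(
            name=d["name"],
            threshold_single=d["threshold_single"],
            threshold_ngram=d["threshold_ngram"],
            elements=tuple(
                FeatureElement(e["kind"], e["key"], e["r"], e["p"])
                for e in d["elements"]
            ),
        )

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path: str | os.PathLike) -> "FeatureSetSpec":
        with open(path) as fh:
            return cls.from_json(fh.read())


def count_ngram(seq: str, subword: str) -> int:
    """Count (possibly overlapping) occurrences of a 2..5-nt subword."""
    subword = normalize_sequence(subword)
    if not 2 <= len(subword) <= 5:
        raise ValidationError(f"subword length must be 2..5, got {len(subword)}")
    seq = normalize_sequence(seq)
    n, m = len(seq), len(subword)
    return sum(1 for i in range(n - m + 1) if seq[i : i + m] == subword)


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """(r, p) of a candidate feature column vs efficacy; None if degenerate."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _bulk_pearson(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise Pearson r of X vs y with two-sided t-test p-values.

    Returns (r, p, valid); columns with zero variance (or a constant y)
    are flagged invalid.  Equivalent to scipy.stats.pearsonr per column.
    """
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    ssx = (Xc**2).sum(axis=0)
    ssy = float(yc @ yc)
    valid = (ssx > 0) & (ssy > 0)
    denom = np.sqrt(np.where(valid, ssx * ssy, 1.0))
    r = np.where(valid, Xc.T @ yc / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return r, p, valid


def _check_training(sequences: Sequence[str], efficacies) -> tuple[list[str], np.ndarray]:
    y = np.asarray(list(efficacies), dtype=float)
    if len(sequences) != len(y) or len(y) < 3:
        raise ValidationError("feature screening needs >= 3 labeled records")
    return [normalize_sequence(s) for s in sequences], y


def enumerate_single_features(
    sequences: Sequence[str], efficacies: Iterable[float]
) -> list[FeatureElement]:
    """Screen the 76 (position, nucleotide) indicators against efficacy."""
    seqs, y = _check_training(sequences, efficacies)
    keys = [f"pos{pos}:{b}" for pos in range(1, 20) for b in "ACGU"]
    mat = np.empty((len(seqs), len(keys)))
    for j, key in enumerate(keys):
        pos, b = key[3:].split(":")
        mat[:, j] = [1.0 if s[int(pos) - 1] == b else 0.0 for s in seqs]
    r, p, valid = _bulk_pearson(mat, y)
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} zero-variance single-nucleotide "
            "indicators dropped",
            stacklevel=2,
        )
    return [
        FeatureElement("single", keys[j], float(r[j]), float(p[j]))
        for j in range(len(keys))
        if valid[j]
    ]


def enumerate_ngram_features(
    sequences: Sequence[str], efficacies: Iterable[float]
) -> list[FeatureElement]:
    """Screen every subword of length 2..5 observed in the training data.

    The feature value is the per-sequence overlapping occurrence count;
    subwords with identical counts in every record are dropped (their
    correlation is undefined).
    """
    seqs, y = _check_training(sequences, efficacies)
    # one pass per sequence tallies all its subwords (overlapping counts)
    tallies: list[dict[str, int]] = []
    observed: set[str] = set()
    for s in seqs:
        d: dict[str, int] = {}
        for m in NGRAM_LENGTHS:
            for i in range(len(s) - m + 1):
                sub = s[i : i + m]
                d[sub] = d.get(sub, 0) + 1
        tallies.append(d)
        observed.update(d)
    subs = sorted(observed)
    col = {sub: j for j, sub in enumerate(subs)}
    mat = np.zeros((len(seqs), len(subs)))
    for i, d in enumerate(tallies):
        for sub, c in d.items():
            mat[i, col[sub]] = c
    r, p, valid = _bulk_pearson(mat, y)
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} constant-frequency subwords dropped",
            stacklevel=2,
        )
    return [
        FeatureElement("ngram", f"ngram:{subs[j]}", float(r[j]), float(p[j]))
        for j in range(len(subs))
        if valid[j]
    ]


THERMO_KEYS = tuple(
    [f"stack:{k}-{k + 1}" for k in range(1, 19)] + ["wholeG", "dH", "dS"]
)


def thermo_values(seq: str, params: ThermoParams | None = None) -> dict[str, float]:
    """The 21 duplex-stability feature values of one 19-nt sequence."""
    tf = compute_thermo(seq, params)
    vals = {f"stack:{k}-{k + 1}": tf.stacks[k - 1] for k in range(1, 19)}
    vals["wholeG"] = tf.whole_dG
    vals["dH"] = tf.dH
    vals["dS"] = tf.dS
    return vals


def enumerate_thermo_features(
    sequences: Sequence[str],
    efficacies: Iterable[float],
    params: ThermoParams | None = None,
) -> list[FeatureElement]:
    """Correlate the 21 stability values with efficacy (all are retained
    by selection regardless of the outcome; statistics are informational)."""
    seqs, y = _check_training(sequences, efficacies)
    table = np.array([[thermo_values(s, params)[k] for k in THERMO_KEYS] for s in seqs])
    out = []
    for j, key in enumerate(THERMO_KEYS):
        rp = _pearson_with_p(table[:, j], y)
        r, p = rp if rp is not None else (0.0, 1.0)
        out.append(FeatureElement("thermo", key, r, p))
    return out


def select_features(
    candidates: Iterable[FeatureElement],
    threshold_single: float | None = None,
    threshold_ngram: float | None = None,
    name: str = "custom",
    p_cutoff: float = 1e-3,
) -> FeatureSetSpec:
    """Filter candidates into a frozen feature set.

    single/ngram elements must satisfy ``p < p_cutoff`` and, when the
    matching threshold is set, ``|r| > threshold`` (strict); thermo
    elements are kept unconditionally.  Output order is deterministic:
    kind (single, ngram, thermo), then key lexicographic.
    """
    kept: list[FeatureElement] = []
    for el in candidates:
        if el.kind == "thermo":
            kept.append(el)
            continue
        if el.p_value >= p_cutoff:
            continue
        thr = threshold_single if el.kind == "single" else threshold_ngram
        if thr is not None and abs(el.r_train) <= thr:
            continue
        kept.append(el)
    if not kept:
        raise ValidationError(
            "feature selection left no elements; relax the |r| thresholds "
            "or the significance cutoff"
        )
    kept.sort(key=lambda e: (KIND_ORDER[e.kind], e.key))
    keys = [e.key for e in kept]
    if len(set(keys)) != len(keys):
        raise ValidationError("duplicate feature keys in candidate pool")
    return FeatureSetSpec(name, tuple(kept), threshold_single, threshold_ngram)


def build_feature_vector(
    seq: str, spec: FeatureSetSpec, params: ThermoParams | None = None
) -> np.ndarray:
    """Evaluate a frozen feature set on one sequence, in spec order."""
    seq = normalize_sequence(seq)
    thermo = None
    out = np.empty(len(spec.elements))
    for j, el in enumerate(spec.elements):
        if el.kind == "single":
            pos, b = el.key[3:].split(":")
            out[j] = 1.0 if seq[int(pos) - 1] == b else 0.0
        elif el.kind == "ngram":
            out[j] = count_ngram(seq, el.key.split(":", 1)[1])
        else:
            if thermo is None:
                thermo = thermo_values(seq, params)
            out[j] = thermo[el.key]
    return out


class FeatureVectorizer(BaseEstimator, TransformerMixin):
    """Transformer wrapping screening + selection + vector construction.

    Parameters
    ----------
    threshold_single, threshold_ngram : float or None
        Strict |r| cutoffs for the two screened families; None disables
        the correlation filter (significance filter still applies).
    p_cutoff : float
        Significance level for the correlation t-test (default 0.001).
    name : str
        Label for the resulting :class:`FeatureSetSpec`.
    thermo_params : ThermoParams or None
        Nearest-neighbor table; None uses the shipped default.
    """

    def __init__(
        self,
        threshold_single: float | None = None,
        threshold_ngram: float | None = None,
        p_cutoff: float = 1e-3,
        name: str = "custom",
        thermo_params: ThermoParams | None = None,
    ):
        self.threshold_single = threshold_single
        self.threshold_ngram = threshold_ngram
        self.p_cutoff = p_cutoff
        self.name = name
        self.thermo_params = thermo_params

    @classmethod
    def standard(cls, name: str, **kwargs) -> "FeatureVectorizer":
        """A vectorizer with the named method family's thresholds
        (F162, F85, F65 or F47)."""
        try:
            ts, tn = METHOD_THRESHOLDS[name]
        except KeyError:
            raise ValidationError(
                f"unknown method {name!r}; choose from {sorted(METHOD_THRESHOLDS)}"
            )
        return cls(threshold_single=ts, threshold_ngram=tn, name=name, **kwargs)

    def fit(self, X, y):
        from .encoders import _as_sequences

        if y is None:
            raise ValidationError("FeatureVectorizer.fit requires efficacies (y)")
        seqs = _as_sequences(X)
        y = np.asarray(y, dtype=float)
        params = self.thermo_params if self.thermo_params is not None else default_params()
        candidates = (
            enumerate_single_features(seqs, y)
            + enumerate_ngram_features(seqs, y)
            + enumerate_thermo_features(seqs, y, params)
        )
        self.spec_ = select_features(
            candidates,
            self.threshold_single,
            self.threshold_ngram,
            name=self.name,
            p_cutoff=self.p_cutoff,
        )
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        from .encoders import _as_sequences

        check_is_fitted(self)
        params = self.thermo_params if self.thermo_params is not None else default_params()
        return np.vstack(
            [build_feature_vector(s, self.spec_, params) for s in _as_sequences(X)]
        )
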