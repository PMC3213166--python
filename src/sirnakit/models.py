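"""Two-layer stacked regression for siRNA efficacy.

Layer 1 trains an epsilon-SVR on one input representation per "method"
(Numeric/Binary/Hybrid sequence encodings, the F162/F85/F65/F47
correlation-selected feature sets, or the R12 rule encoding) and records
its 10-fold cross-validated Pearson r.  Methods with cv r >= 0.6 are
admitted, and layer 2 fuses one sequence-type with one feature-type
method, trained on OUT-OF-FOLD layer-1 predictions (stacked
generalization) by one of three mechanisms:

* another epsilon-SVR on the two predictions;
* a 2-6-1 feed-forward network (sigmoid hidden and output units,
  full-batch gradient descent with momentum, targets scaled to [0,1]);
* a weighted sum R_pred = W1*R1 + W2*R2 with W1, W2 in [0,1] evolved by a
  generational genetic algorithm (binary chromosomes, one-point
  crossover, per-bit mutation, roulette selection with elitism of 1)
  minimizing mean squared error.

All estimators follow the scikit-learn fit/predict contract and are
deterministic given ``random_state``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted

from .encoders import (
    BinaryEncoder,
    HybridEncoder,
    NumericEncoder,
    RuleEncoder,
    _as_sequences,
)
from .features import METHOD_THRESHOLDS, FeatureVectorizer
from .io import ValidationError

#: default epsilon-SVR search grid (RBF kernel), deliberately small; pass a
#: larger grid for exhaustive searches.
DEFAULT_SVR_GRID: dict = {"C": [1.0, 10.0, 100.0], "gamma": ["scale"], "epsilon": [0.1]}

SEQUENCE_METHODS = ("Numeric", "Binary", "Hybrid")
RULE_METHODS = ("R12",)


def make_encoder(method_name: str, **kwargs):
    """Instantiate the encoder/vectorizer behind a named layer-1 method."""
    if method_name == "Numeric":
        return NumericEncoder()
    if method_name == "Binary":
        return BinaryEncoder()
    if method_name == "Hybrid":
        return HybridEncoder()
    if method_name == "R12":
        return RuleEncoder(**kwargs)
    if method_name in METHOD_THRESHOLDS:
        return FeatureVectorizer.standard(method_name, **kwargs)
    raise ValidationError(f"unknown method name {method_name!r}")


def method_category(method_name: str) -> str:
    if method_name in SEQUENCE_METHODS:
        return "sequence"
    if method_name in RULE_METHODS:
        return "rule"
    if method_name in METHOD_THRESHOLDS:
        return "feature"
    return "custom"


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _make_folds(n: int, n_folds: int, seed: int, y: np.ndarray) -> list[np.ndarray]:
    """Deterministic shuffled near-equal folds; folds whose labels are
    constant are merged with a neighbor (with a warning)."""
    order = np.random.default_rng(seed).permutation(n)
    folds = [f for f in np.array_split(order, n_folds) if len(f)]
    merged = True
    while merged and len(folds) > 1:
        merged = False
        for i, f in enumerate(folds):
            if np.ptp(y[f]) == 0:
                j = i - 1 if i > 0 else i + 1
                folds[j] = np.concatenate([folds[j], f])
                del folds[i]
                warnings.warn(
                    "fold with zero label variance merged with neighbor",
                    stacklevel=3,
                )
                merged = True
                break
    return folds


class Layer1Regressor(BaseEstimator, RegressorMixin):
    """One characteristic method: an encoder plus an epsilon-SVR.

    ``fit`` selects RBF-SVR hyperparameters by inner 5-fold grid search
    (Pearson-r scoring), records ``cv_r_`` as the correlation between
    pooled 10-fold out-of-fold predictions and the observed efficacies
    (encoder refit inside each fold), then refits encoder and SVR on the
    full training set.

    Parameters
    ----------
    method_name : str
        Numeric | Binary | Hybrid | F162 | F85 | F65 | F47 | R12, or any
        label when ``encoder`` is supplied explicitly.
    encoder : transformer, optional
        Overrides the encoder implied by ``method_name``.
    param_grid : dict, optional
        SVR search grid (default :data:`DEFAULT_SVR_GRID`).
    n_folds : int
        Folds for the out-of-fold cv_r estimate (default 10).
    random_state : int
        Seeds fold shuffling and the inner grid-search folds.
    """

    def __init__(
        self,
        method_name: str = "Binary",
        encoder=None,
        param_grid: dict | None = None,
        n_folds: int = 10,
        random_state: int = 0,
    ):
        self.method_name = method_name
        self.encoder = encoder
        self.param_grid = param_grid
        self.n_folds = n_folds
        self.random_state = random_state

    @property
    def category(self) -> str:
        return method_category(self.method_name)

    def _proto_encoder(self):
        return (
            clone(self.encoder)
            if self.encoder is not None
            else make_encoder(self.method_name)
        )

    def fit(self, X, y):
        seqs = _as_sequences(X)
        y = np.asarray(y, dtype=float)
        if len(seqs) != len(y):
            raise ValidationError("X and y length mismatch")
        if len(y) < 20:
            raise ValidationError("layer-1 training needs n >= 20")
        if np.ptp(y) == 0:
            raise ValidationError("degenerate labels: efficacy has zero variance")

        # hyperparameter selection on the full encoded training set
        enc = self._proto_encoder().fit(seqs, y)
        Xe = enc.transform(seqs)
        grid = self.param_grid if self.param_grid is not None else DEFAULT_SVR_GRID
        inner = KFold(n_splits=5, shuffle=True, random_state=self.random_state)
        search = GridSearchCV(
            SVR(kernel="rbf"), grid, cv=inner, scoring=_pearson_scorer, n_jobs=None
        )
        search.fit(Xe, y)
        self.best_params_ = dict(search.best_params_)

        # out-of-fold cv_r with per-fold encoder refits (no leakage)
        oof = self._oof_predictions(seqs, y)
        self.cv_r_ = _pearson(oof, y)
        # cache so a stacking frame on the same data can reuse these
        self._train_seqs_ = list(seqs)
        self._train_y_ = y.copy()
        self.oof_predictions_ = oof

        # final model on the full training set
        self.encoder_ = enc
        self.svr_ = SVR(kernel="rbf", **self.best_params_).fit(Xe, y)
        self.n_features_in_ = 1
        return self

    def _oof_predictions(
        self, seqs: list[str], y: np.ndarray, seed: int | None = None
    ) -> np.ndarray:
        """Pooled out-of-fold predictions using the selected hyperparameters."""
        seed = self.random_state if seed is None else seed
        folds = _make_folds(len(seqs), self.n_folds, seed, y)
        oof = np.empty(len(seqs))
        for held in folds:
            train = np.setdiff1d(np.arange(len(seqs)), held)
            enc = self._proto_encoder().fit([seqs[i] for i in train], y[train])
            Xtr = enc.transform([seqs[i] for i in train])
            Xte = enc.transform([seqs[i] for i in held])
            svr = SVR(kernel="rbf", **self.best_params_).fit(Xtr, y[train])
            oof[held] = svr.predict(Xte)
        return oof

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "svr_")
        seqs = _as_sequences(X)
        return self.svr_.predict(self.encoder_.transform(seqs))


def _pearson_scorer(estimator, X, y) -> float:
    return _pearson(estimator.predict(X), y)


def admit_methods(
    models: list[Layer1Regressor], threshold: float = 0.6
) -> dict[str, list[Layer1Regressor]]:
    """Keep layer-1 models with cv_r >= threshold (inclusive), grouped by
    category for layer-2 pairing.

    Raises if no sequence-type or no feature-type method survives: the
    fusion layer pairs exactly one of each.
    """
    admitted = [m for m in models if m.cv_r_ >= threshold]
    groups: dict[str, list[Layer1Regressor]] = {"sequence": [], "feature": [], "rule": []}
    for m in admitted:
        groups.setdefault(m.category, []).append(m)
    if not groups["sequence"] or not groups["feature"]:
        have = sorted(f"{m.method_name}({m.cv_r_:.3f})" for m in admitted)
        raise ValidationError(
            "layer-2 fusion pairs one sequence-type with one feature-type "
            f"method, but admission at r >= {threshold} left only {have}; "
            "lower the threshold or train more methods"
        )
    return groups


@dataclass
class StackingFrame:
    """Aligned out-of-fold layer-1 predictions and observed efficacies.

    Each record's predictions come from models trained on the other nine
    folds, so the layer-2 training signal is leakage-free.
    """

    pred1: np.ndarray
    pred2: np.ndarray
    observed: np.ndarray
    component_names: tuple[str, str]

    def __post_init__(self) -> None:
        if not len(self.pred1) == len(self.pred2) == len(self.observed):
            raise ValidationError("stacking frame columns must align")

    @property
    def X(self) -> np.ndarray:
        return np.column_stack([self.pred1, self.pred2])

    def __len__(self) -> int:
        return len(self.observed)


def build_stacking_frame(
    X,
    y,
    pair: tuple[Layer1Regressor, Layer1Regressor],
    n_folds: int = 10,
    seed: int = 0,
) -> StackingFrame:
    """Out-of-fold predictions of a fitted (sequence, feature) model pair.

    Both components are refit (encoder included) on each 9-fold training
    split using the hyperparameters they selected on the full data.
    """
    seqs = _as_sequences(X)
    y = np.asarray(y, dtype=float)
    m1, m2 = pair
    check_is_fitted(m1, "svr_")
    check_is_fitted(m2, "svr_")

    def oof(m: Layer1Regressor) -> np.ndarray:
        cached = (
            seed == m.random_state
            and n_folds == m.n_folds
            and getattr(m, "_train_seqs_", None) == seqs
            and np.array_equal(m._train_y_, y)
        )
        return m.oof_predictions_ if cached else m._oof_predictions(seqs, y, seed=seed)

    return StackingFrame(oof(m1), oof(m2), y, (m1.method_name, m2.method_name))


class SVRFusion(BaseEstimator, RegressorMixin):
    """Layer-2 epsilon-SVR on the two component predictions."""

    def __init__(self, param_grid: dict | None = None, random_state: int = 0):
        self.param_grid = param_grid
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if np.ptp(y) == 0:
            raise ValidationError("degenerate labels: efficacy has zero variance")
        grid = self.param_grid if self.param_grid is not None else DEFAULT_SVR_GRID
        inner = KFold(n_splits=5, shuffle=True, random_state=self.random_state)
        search = GridSearchCV(
            SVR(kernel="rbf"), grid, cv=inner, scoring=_pearson_scorer
        )
        search.fit(X, y)
        self.best_params_ = dict(search.best_params_)
        self.svr_ = SVR(kernel="rbf", **self.best_params_).fit(X, y)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "svr_")
        return self.svr_.predict(np.asarray(X, float))


class NeuralNetFusion(BaseEstimator, RegressorMixin):
    """2-6-1 feed-forward fusion network.

    Sigmoid hidden and output units; inputs are standardized and targets
    min-max scaled into [0.1, 0.9] (inverted on output, so predictions
    stay on the percent scale); training is full-batch gradient descent
    with momentum on squared error, with early stopping on a loss
    plateau.  Deterministic given ``random_state``.
    """

    def __init__(
        self,
        n_hidden: int = 6,
        learning_rate: float = 0.5,
        momentum: float = 0.9,
        max_epochs: int = 5000,
        tol: float = 1e-12,
        patience: int = 200,
        random_state: int = 0,
    ):
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.max_epochs = max_epochs
        self.tol = tol
        self.patience = patience
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if np.ptp(y) == 0:
            raise ValidationError("degenerate labels: efficacy has zero variance")
        self.x_mean_ = X.mean(axis=0)
        self.x_std_ = np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
        self.y_min_, self.y_max_ = float(y.min()), float(y.max())
        Xs = (X - self.x_mean_) / self.x_std_
        t = 0.1 + 0.8 * (y - self.y_min_) / (self.y_max_ - self.y_min_)

        rng = np.random.default_rng(self.random_state)
        n_in = X.shape[1]
        W1 = rng.normal(0, 0.5, (n_in, self.n_hidden))
        b1 = np.zeros(self.n_hidden)
        W2 = rng.normal(0, 0.5, (self.n_hidden, 1))
        b2 = np.zeros(1)
        vW1 = np.zeros_like(W1)
        vb1 = np.zeros_like(b1)
        vW2 = np.zeros_like(W2)
        vb2 = np.zeros_like(b2)

        n = len(t)
        best = np.inf
        stall = 0
        self.loss_curve_ = []
        converged = False
        for _ in range(self.max_epochs):
            h = _sigmoid(Xs @ W1 + b1)
            out = _sigmoid(h @ W2 + b2).ravel()
            err = out - t
            loss = float(np.mean(err**2))
            self.loss_curve_.append(loss)
            # backprop through the two sigmoid layers
            d_out = (2.0 / n) * err * out * (1 - out)
            gW2 = h.T @ d_out[:, None]
            gb2 = d_out.sum(keepdims=True)
            d_h = np.outer(d_out, W2.ravel()) * h * (1 - h)
            gW1 = Xs.T @ d_h
            gb1 = d_h.sum(axis=0)
            vW1 = self.momentum * vW1 - self.learning_rate * gW1
            vb1 = self.momentum * vb1 - self.learning_rate * gb1
            vW2 = self.momentum * vW2 - self.learning_rate * gW2
            vb2 = self.momentum * vb2 - self.learning_rate * gb2
            W1 += vW1
            b1 += vb1
            W2 += vW2
            b2 += vb2
            if loss < best - self.tol:
                best = loss
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    converged = True
                    break
        if not converged:
            warnings.warn(
                "fusion network hit max_epochs without a loss plateau; "
                "returning best-so-far weights",
                stacklevel=2,
            )
        self.W1_, self.b1_, self.W2_, self.b2_ = W1, b1, W2, b2
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "W1_")
        Xs = (np.asarray(X, float) - self.x_mean_) / self.x_std_
        h = _sigmoid(Xs @ self.W1_ + self.b1_)
        out = _sigmoid(h @ self.W2_ + self.b2_).ravel()
        pred = self.y_min_ + (out - 0.1) / 0.8 * (self.y_max_ - self.y_min_)
        return np.clip(pred, 0.0, 100.0)  # percent-inhibition range contract


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


class GAWeightFusion(BaseEstimator, RegressorMixin):
    """Linear fusion R_pred = W1*R1 + W2*R2 with GA-evolved weights.

    Each weight is a 16-bit chromosome segment mapped linearly onto
    [0, 1] (the weights are not constrained to sum to 1).  A generational
    GA with fitness-proportional (roulette) selection, one-point
    crossover, per-bit mutation and elitism of 1 minimizes the mean
    squared error between observed and fused efficacy.  Because the MSE
    is quadratic in (W1, W2), per-individual fitness is evaluated from
    precomputed second moments, so cost is independent of n.

    Attributes
    ----------
    weights_ : ndarray shape (2,)
        Best evolved (W1, W2).
    mse_ : float
        MSE of the best individual.
    mse_trajectory_ : ndarray shape (generations + 1,)
        Best-so-far MSE per generation; non-increasing under elitism.
    """

    def __init__(
        self,
        population: int = 100,
        crossover_rate: float = 0.7,
        mutation_rate: float = 0.001,
        generations: int = 2000,
        bits_per_weight: int = 16,
        random_state: int = 0,
    ):
        self.population = population
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.generations = generations
        self.bits_per_weight = bits_per_weight
        self.random_state = random_state

    def _validate(self) -> None:
        if self.population <= 1:
            raise ValidationError("population must exceed 1")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.generations < 1:
            raise ValidationError("generations must be >= 1")

    def fit(self, X, y):
        self._validate()
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        r1, r2 = X[:, 0], X[:, 1]
        if np.ptp(r1) == 0 or np.ptp(r2) == 0:
            raise ValidationError("zero-variance component predictions")

        # MSE(W) = m_yy - 2 W1 m_1y - 2 W2 m_2y + W1^2 m_11
        #          + W2^2 m_22 + 2 W1 W2 m_12   (means of products)
        m_yy = float(np.mean(y * y))
        m_1y = float(np.mean(r1 * y))
        m_2y = float(np.mean(r2 * y))
        m_11 = float(np.mean(r1 * r1))
        m_22 = float(np.mean(r2 * r2))
        m_12 = float(np.mean(r1 * r2))

        def mse(w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
            return (
                m_yy
                - 2 * w1 * m_1y
                - 2 * w2 * m_2y
                + w1**2 * m_11
                + w2**2 * m_22
                + 2 * w1 * w2 * m_12
            )

        bits = self.bits_per_weight
        L = 2 * bits
        denom = float(2**bits - 1)
        powers = 2.0 ** np.arange(bits - 1, -1, -1)
        rng = np.random.default_rng(self.random_state)
        pop = rng.integers(0, 2, size=(self.population, L))

        def decode(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            w1 = (p[:, :bits] @ powers) / denom
            w2 = (p[:, bits:] @ powers) / denom
            return w1, w2

        traj: list[float] = []
        w1, w2 = decode(pop)
        fit_mse = mse(w1, w2)
        for _ in range(self.generations):
            best_i = int(np.argmin(fit_mse))
            traj.append(float(fit_mse[best_i]))
            elite = pop[best_i].copy()
            # fitness-proportional (roulette) selection on 1/(1+MSE)
            fitness = 1.0 / (1.0 + fit_mse)
            prob = fitness / fitness.sum()
            parents = pop[rng.choice(self.population, size=self.population, p=prob)]
            # one-point crossover on consecutive pairs
            children = parents.copy()
            for i in range(0, self.population - 1, 2):
                if rng.random() < self.crossover_rate:
                    cut = int(rng.integers(1, L))
                    children[i, cut:] = parents[i + 1, cut:]
                    children[i + 1, cut:] = parents[i, cut:]
            # per-bit mutation
            flip = rng.random(children.shape) < self.mutation_rate
            children = np.where(flip, 1 - children, children)
            children[0] = elite  # elitism of 1
            pop = children
            w1, w2 = decode(pop)
            fit_mse = mse(w1, w2)
        best_i = int(np.argmin(fit_mse))
        traj.append(float(fit_mse[best_i]))
        w1b, w2b = decode(pop[best_i : best_i + 1])
        self.weights_ = np.array([w1b[0], w2b[0]])
        self.mse_ = float(fit_mse[best_i])
        self.mse_trajectory_ = np.minimum.accumulate(np.asarray(traj))
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = np.asarray(X, float)
        return X @ self.weights_


FUSION_MECHANISMS = {"svr": SVRFusion, "nn": NeuralNetFusion, "ga_linear": GAWeightFusion}


def make_fusion(mechanism: str, random_state: int = 0, **params):
    try:
        cls = FUSION_MECHANISMS[mechanism]
    except KeyError:
        raise ValidationError(
            f"unknown fusion mechanism {mechanism!r}; "
            f"choose from {sorted(FUSION_MECHANISMS)}"
        )
    return cls(random_state=random_state, **params)


class TwoLayerPredictor(BaseEstimator, RegressorMixin):
    """The full two-layer efficacy predictor.

    ``fit`` trains the requested layer-1 methods, admits those with
    10-fold cv r >= ``admission_threshold``, chooses a
    (sequence, feature) pair, builds the out-of-fold stacking frame and
    trains the fusion mechanism on it; ``predict`` runs the two fitted
    components and fuses their outputs.

    Parameters
    ----------
    methods : tuple of str
        Layer-1 methods to train; must span both a sequence-type and a
        feature-type method.
    fusion : str
        "svr", "nn" or "ga_linear".
    pair : "auto" or (str, str)
        Explicit (sequence_method, feature_method) pair, or "auto" to
        pick the pair with the best r on an internal 80/20 validation
        split of the stacking frame.
    admission_threshold : float
        Minimum layer-1 cv r (inclusive; default 0.6).
    svr_grid : dict or None
        Hyperparameter grid for layer-1 (and svr fusion) searches.
    fusion_params : dict or None
        Extra keyword arguments for the fusion estimator.
    """

    def __init__(
        self,
        methods: tuple[str, ...] = ("Binary", "Hybrid", "F85"),
        fusion: str = "svr",
        pair: str | tuple[str, str] = "auto",
        admission_threshold: float = 0.6,
        n_folds: int = 10,
        svr_grid: dict | None = None,
        fusion_params: dict | None = None,
        random_state: int = 0,
    ):
        self.methods = methods
        self.fusion = fusion
        self.pair = pair
        self.admission_threshold = admission_threshold
        self.n_folds = n_folds
        self.svr_grid = svr_grid
        self.fusion_params = fusion_params
        self.random_state = random_state

    def fit(self, X, y):
        seqs = _as_sequences(X)
        y = np.asarray(y, dtype=float)
        cats = {method_category(m) for m in self.methods}
        if "sequence" not in cats or "feature" not in cats:
            raise ValidationError(
                "methods must include at least one sequence-type "
                "(Numeric/Binary/Hybrid) and one feature-type "
                "(F162/F85/F65/F47) method for layer-2 fusion"
            )
        self.layer1_models_ = {}
        for name in self.methods:
            model = Layer1Regressor(
                method_name=name,
                param_grid=self.svr_grid,
                n_folds=self.n_folds,
                random_state=self.random_state,
            ).fit(seqs, y)
            self.layer1_models_[name] = model
        self.admitted_ = admit_methods(
            list(self.layer1_models_.values()), self.admission_threshold
        )

        candidates = self._candidate_pairs()
        frames = {
            p: build_stacking_frame(
                seqs,
                y,
                (self.layer1_models_[p[0]], self.layer1_models_[p[1]]),
                n_folds=self.n_folds,
                seed=self.random_state,
            )
            for p in candidates
        }
        fparams = dict(self.fusion_params or {})
        if self.fusion == "svr" and "param_grid" not in fparams:
            fparams["param_grid"] = self.svr_grid
        best: tuple[float, tuple[str, str]] | None = None
        self.pair_scores_ = {}
        for p, frame in frames.items():
            score = self._validation_r(frame, fparams)
            self.pair_scores_[p] = score
            if best is None or score > best[0]:
                best = (score, p)
        assert best is not None
        self.validation_r_, self.pair_ = best
        frame = frames[self.pair_]
        self.stacking_frame_ = frame
        self.fusion_ = make_fusion(
            self.fusion, random_state=self.random_state, **fparams
        ).fit(frame.X, frame.observed)
        self.components_ = (
            self.layer1_models_[self.pair_[0]],
            self.layer1_models_[self.pair_[1]],
        )
        return self

    def _candidate_pairs(self) -> list[tuple[str, str]]:
        if self.pair != "auto":
            s, f = self.pair  # type: ignore[misc]
            for name, want in ((s, "sequence"), (f, "feature")):
                if name not in self.layer1_models_:
                    raise ValidationError(f"pair references untrained method {name!r}")
                if self.layer1_models_[name].category != want:
                    raise ValidationError(
                        f"pair must be (sequence, feature); {name!r} is "
                        f"{self.layer1_models_[name].category}-type"
                    )
                if self.layer1_models_[name].cv_r_ < self.admission_threshold:
                    raise ValidationError(
                        f"method {name!r} (cv r = "
                        f"{self.layer1_models_[name].cv_r_:.3f}) is below the "
                        f"admission threshold {self.admission_threshold}"
                    )
            return [(s, f)]
        return [
            (s.method_name, f.method_name)
            for s in self.admitted_["sequence"]
            for f in self.admitted_["feature"]
        ]

    def _validation_r(self, frame: StackingFrame, fparams: dict) -> float:
        """r of the fusion on a seeded 80/20 split of the stacking frame."""
        n = len(frame)
        order = np.random.default_rng(self.random_state + 1).permutation(n)
        cut = max(1, int(0.8 * n))
        tr, te = order[:cut], order[cut:]
        if len(te) < 3:
            tr = te = order
        fus = make_fusion(self.fusion, random_state=self.random_state, **fparams)
        fus.fit(frame.X[tr], frame.observed[tr])
        return _pearson(fus.predict(frame.X[te]), frame.observed[te])

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "fusion_")
        seqs = _as_sequences(X)
        p1 = self.components_[0].predict(seqs)
        p2 = self.components_[1].predict(seqs)
        return self.fusion_.predict(np.column_stack([p1, p2]))
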