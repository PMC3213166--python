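"""Model bundle persistence.

A bundle is a directory holding everything needed to reload a trained
two-layer predictor and reproduce its predictions exactly:

* ``model.joblib``  — the fitted estimator graph;
* ``bundle.json``   — human-readable summary: estimator parameters,
  per-method cv r, the selected pair and its validation r, fusion
  details (GA weights / SVR hyperparameters), and a fingerprint of the
  training data used to flag in-sample evaluation later;
* ``feature_spec_<name>.json`` — the frozen feature set of each fitted
  feature-type method, for inspection and provenance.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import joblib

from .io import Dataset, ValidationError
from .models import GAWeightFusion, SVRFusion, TwoLayerPredictor

BUNDLE_META = "bundle.json"
BUNDLE_MODEL = "model.joblib"


def dataset_fingerprint(dataset: Dataset) -> str:
    """Order-insensitive SHA-256 over (id, sequence, efficacy) triples."""
    items = sorted((r.id, r.sense_seq, repr(r.efficacy)) for r in dataset)
    h = hashlib.sha256()
    for it in items:
        h.update("\t".join(it).encode())
        h.update(b"\n")
    return h.hexdigest()


def save_bundle(
    model: TwoLayerPredictor, path: str | os.PathLike, training_data: Dataset | None = None
) -> Path:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, out / BUNDLE_MODEL)
    meta: dict = {
        "params": {k: _jsonable(v) for k, v in model.get_params().items()},
        "layer1_cv_r": {
            name: m.cv_r_ for name, m in model.layer1_models_.items()
        },
        "layer1_svr_params": {
            name: m.best_params_ for name, m in model.layer1_models_.items()
        },
        "pair": list(model.pair_),
        "pair_scores": {" + ".join(k): v for k, v in model.pair_scores_.items()},
        "validation_r": model.validation_r_,
        "fusion_mechanism": model.fusion,
    }
    fus = model.fusion_
    if isinstance(fus, GAWeightFusion):
        meta["ga_weights"] = list(map(float, fus.weights_))
        meta["ga_best_mse"] = fus.mse_
        meta["ga_mse_trajectory"] = [float(v) for v in fus.mse_trajectory_]
    elif isinstance(fus, SVRFusion):
        meta["fusion_svr_params"] = fus.best_params_
    if training_data is not None:
        meta["training_fingerprint"] = dataset_fingerprint(training_data)
        meta["training_n"] = len(training_data)
    with open(out / BUNDLE_META, "w") as fh:
        json.dump(meta, fh, indent=1)
    for name, m in model.layer1_models_.items():
        spec = getattr(m.encoder_, "spec_", None)
        if spec is not None:
            spec.save(out / f"feature_spec_{name}.json")
    return out


def load_bundle(path: str | os.PathLike) -> tuple[TwoLayerPredictor, dict]:
    p = Path(path)
    if not (p / BUNDLE_MODEL).exists():
        raise ValidationError(f"{p} is not a model bundle (missing {BUNDLE_MODEL})")
    model = joblib.load(p / BUNDLE_MODEL)
    meta = {}
    if (p / BUNDLE_META).exists():
        with open(p / BUNDLE_META) as fh:
            meta = json.load(fh)
    return model, meta


def _jsonable(v):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, dict) or isinstance(v, (str, int, float, bool)) or v is None:
        return v
    return repr(v)
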