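"""Three-stage HFO classifier cascade with training and distillation.

Stage 1 rejects artifacts; stages 2 and 3 run only on the surviving "real"
events and flag spike-coupled HFOs (spkHFO) and epileptogenic HFOs (eHFO).
Every stage consumes the standardized 3x224x224 time–frequency input
(module :mod:`hfokit.features`) and exposes calibrated class probabilities.

The trainable reference model is a compact pipeline — block-average pooling
of the scalogram to a 28x28 patch grid, standardization, and a small
multilayer perceptron — deliberately desk-scale so the full train/distill
loop runs in seconds on one CPU while exercising the same input contract,
checkpoint format and cascade semantics as any user-supplied model.

Model sources are strings: ``local:<path>`` for checkpoint files and
``registry:<id>`` for a model registry.  Registry access is behind the
:class:`LocalRegistry` interface (a directory of checkpoints with a local
cache), so no code path here ever touches the network.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSource", "InferenceConfig", "ClassificationResult", "ReferenceClassifier",
    "LocalRegistry", "load_classifier", "save_classifier", "predict_batch",
    "run_cascade", "train_classifier", "distill_model",
]

_ROLES = ("artifact", "spk", "ehfo")
_INPUT_SHAPE = (3, 224, 224)
_CHECKPOINT_FORMAT = "hfokit-classifier"
_CHECKPOINT_VERSION = 1


@dataclass
class ModelSource:
    """Where a classifier comes from: a local checkpoint or a registry entry."""

    kind: str                   # 'local_checkpoint' | 'remote_registry_id'
    locator: str
    role: str = "artifact"

    def __post_init__(self) -> None:
        if not self.locator:
            raise ValueError("ModelSource locator must be non-empty")
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")

    @classmethod
    def parse(cls, spec: str, role: str = "artifact") -> "ModelSource":
        """Parse 'local:<path>' or 'registry:<id>' strings."""
        if spec.startswith("local:"):
            return cls("local_checkpoint", spec[len("local:"):], role)
        if spec.startswith("registry:"):
            return cls("remote_registry_id", spec[len("registry:"):], role)
        return cls("local_checkpoint", spec, role)


@dataclass
class InferenceConfig:
    device: str = "cpu"          # 'cpu' | 'accelerator' (accepted, runs on CPU)
    batch_size: int = 64

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class ClassificationResult:
    """Per-event cascade outputs plus category counts.

    ``p_spk``/``p_ehfo`` are NaN for events labeled artifact (the later
    stages never see them) and the corresponding arrays are ``None`` when a
    stage was not run at all.
    """

    p_artifact: np.ndarray
    label_artifact: np.ndarray                     # True = artifact
    p_spk: Optional[np.ndarray] = None
    label_spk: Optional[np.ndarray] = None
    p_ehfo: Optional[np.ndarray] = None
    label_ehfo: Optional[np.ndarray] = None

    @property
    def n_total(self) -> int:
        return int(self.p_artifact.size)

    @property
    def n_artifact(self) -> int:
        return int(np.count_nonzero(self.label_artifact))

    @property
    def n_real(self) -> int:
        return self.n_total - self.n_artifact

    @property
    def n_spk(self) -> Optional[int]:
        if self.label_spk is None:
            return None
        return int(np.count_nonzero(self.label_spk & ~self.label_artifact))

    @property
    def n_ehfo(self) -> Optional[int]:
        if self.label_ehfo is None:
            return None
        return int(np.count_nonzero(self.label_ehfo & ~self.label_artifact))

    def counts(self) -> dict:
        return {"n_total": self.n_total, "n_artifact": self.n_artifact,
                "n_real": self.n_real, "n_spk": self.n_spk, "n_ehfo": self.n_ehfo}


class ReferenceClassifier:
    """Pooled-scalogram MLP over the standard 3x224x224 input.

    The three input planes are identical by construction, so features come
    from plane 0: ``pool``x``pool`` block averaging (default 4 -> 56x56
    patches), flattening, standardization and a two-hidden-layer MLP with a
    softmax head.
    """

    def __init__(self, hidden_layer_sizes: tuple[int, ...] = (128, 64), pool: int = 4,
                 seed: int = 0, max_iter: int = 500, alpha: float = 1e-4):
        self.input_shape = _INPUT_SHAPE
        self.pool = int(pool)
        self.seed = int(seed)
        self.scaler = StandardScaler()
        self.mlp = MLPClassifier(hidden_layer_sizes=hidden_layer_sizes, alpha=alpha,
                                 max_iter=max_iter, random_state=seed)

    # -- feature extraction -------------------------------------------------
    def _check_images(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float32)  # float32 bounds memory on large pools
        if images.ndim == 3:  # single image
            images = images[np.newaxis]
        if images.ndim != 4 or images.shape[1:] != self.input_shape:
            raise ValueError(
                f"shape mismatch: classifier expects (n, {', '.join(map(str, self.input_shape))}) "
                f"inputs, got {images.shape}")
        return images

    def _features(self, images: np.ndarray) -> np.ndarray:
        plane = images[:, 0]
        n, h, w = plane.shape
        p = self.pool
        pooled = plane.reshape(n, h // p, p, w // p, p).mean(axis=(2, 4))
        return pooled.reshape(n, -1)

    # -- scikit-learn-style API --------------------------------------------
    def fit(self, images: np.ndarray, labels: Sequence[int]) -> "ReferenceClassifier":
        images = self._check_images(images)
        labels = np.asarray(labels)
        if np.unique(labels).size < 2:
            raise ValueError("training requires at least two classes")
        feats = self.scaler.fit_transform(self._features(images))
        self.mlp.fit(feats, labels)
        return self

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        images = self._check_images(images)
        if images.shape[0] == 0:
            return np.zeros((0, len(self.classes_)))
        feats = self.scaler.transform(self._features(images))
        return self.mlp.predict_proba(feats)

    def predict(self, images: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(images)
        return self.classes_[np.argmax(proba, axis=1)]

    @property
    def classes_(self) -> np.ndarray:
        return self.mlp.classes_

    def positive_proba(self, images: np.ndarray, positive: int = 1) -> np.ndarray:
        """Probability of the positive class (default label 1)."""
        proba = self.predict_proba(images)
        col = int(np.flatnonzero(self.classes_ == positive)[0])
        return proba[:, col]


# ---------------------------------------------------------------------------
# Checkpoints and registry


def save_classifier(clf: ReferenceClassifier, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "format": _CHECKPOINT_FORMAT,
        "version": _CHECKPOINT_VERSION,
        "input_shape": clf.input_shape,
        "pool": clf.pool,
        "seed": clf.seed,
        "scaler": clf.scaler,
        "mlp": clf.mlp,
    }
    joblib.dump(payload, path)
    return path


class LocalRegistry:
    """Filesystem model registry: checkpoints under ``root``, fetched into a cache.

    ``resolve(model_id)`` looks up ``<root>/<model_id>`` (``.joblib`` appended
    when missing) and copies it into ``cache_dir`` on first access, mirroring
    how remote registries cache artifacts locally.
    """

    def __init__(self, root: str | Path, cache_dir: Optional[str | Path] = None):
        self.root = Path(root)
        self.cache_dir = Path(cache_dir) if cache_dir else self.root / ".cache"

    def resolve(self, model_id: str) -> Path:
        src = self.root / model_id
        if not src.exists() and not model_id.endswith(".joblib"):
            src = self.root / f"{model_id}.joblib"
        if not src.exists():
            raise FileNotFoundError(f"registry id {model_id!r} not found under {self.root}")
        self.cache_dir.mkdir(parents=True, exist_ok=True)
        cached = self.cache_dir / src.name
        if not cached.exists():
            shutil.copy2(src, cached)
        return cached


def load_classifier(src: ModelSource | str, registry: Optional[LocalRegistry] = None
                    ) -> ReferenceClassifier:
    """Load a classifier checkpoint from a local path or a registry id."""
    if isinstance(src, str):
        src = ModelSource.parse(src)
    if src.kind == "remote_registry_id":
        if registry is None:
            raise ValueError(
                "registry model source requires a configured registry "
                "(hfokit uses a local-directory registry; pass LocalRegistry(root))")
        path = registry.resolve(src.locator)
    else:
        path = Path(src.locator)
        if not path.exists():
            raise FileNotFoundError(f"classifier checkpoint not found: {path}")
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != _CHECKPOINT_FORMAT:
        raise ValueError(f"{path} is not a hfokit classifier checkpoint")
    if payload.get("version") != _CHECKPOINT_VERSION:
        raise ValueError(f"incompatible checkpoint version {payload.get('version')}")
    if tuple(payload["input_shape"]) != _INPUT_SHAPE:
        raise ValueError(
            f"shape mismatch: checkpoint expects input {tuple(payload['input_shape'])}, "
            f"this pipeline produces {_INPUT_SHAPE}")
    clf = ReferenceClassifier(pool=payload["pool"], seed=payload["seed"])
    clf.scaler = payload["scaler"]
    clf.mlp = payload["mlp"]
    return clf


# ---------------------------------------------------------------------------
# Inference


def predict_batch(clf: ReferenceClassifier, images: np.ndarray,
                  cfg: Optional[InferenceConfig] = None) -> np.ndarray:
    """Class probabilities per image, processed in ``batch_size`` chunks.

    The output is independent of batch size (to float tolerance) and an empty
    input yields an empty output.
    """
    cfg = cfg or InferenceConfig()
    images = np.asarray(images)
    if images.shape[0] == 0:
        return np.zeros((0, len(clf.classes_)))
    chunks = [clf.predict_proba(images[i:i + cfg.batch_size])
              for i in range(0, images.shape[0], cfg.batch_size)]
    return np.vstack(chunks)


def run_cascade(events: Sequence, images: np.ndarray, models: dict,
                cfg: Optional[InferenceConfig] = None,
                threshold: float = 0.5) -> ClassificationResult:
    """Run artifact -> spk -> eHFO classification over one image per event.

    ``models`` maps roles to classifiers; 'artifact' is mandatory, 'spk' and
    'ehfo' optional.  Later stages see only non-artifact events; their
    probabilities are NaN for artifacts.  Ties at the threshold resolve
    toward the non-pathological label (artifact at stage 1, negative at
    stages 2–3).
    """
    if "artifact" not in models or models["artifact"] is None:
        raise ValueError("cascade requires an artifact model")
    images = np.asarray(images)
    if len(events) != images.shape[0]:
        raise ValueError(f"{len(events)} events but {images.shape[0]} images")
    cfg = cfg or InferenceConfig()

    p_art = predict_batch(models["artifact"], images, cfg)
    p_artifact = _positive_column(models["artifact"], p_art)
    label_artifact = p_artifact >= threshold
    real_idx = np.flatnonzero(~label_artifact)

    result = ClassificationResult(p_artifact=p_artifact, label_artifact=label_artifact)
    for role in ("spk", "ehfo"):
        model = models.get(role)
        if model is None:
            continue
        p = np.full(len(events), np.nan)
        if real_idx.size:
            p[real_idx] = _positive_column(model, predict_batch(model, images[real_idx], cfg))
        labels = np.zeros(len(events), dtype=bool)
        labels[real_idx] = p[real_idx] > threshold
        if role == "spk":
            result.p_spk, result.label_spk = p, labels
        else:
            result.p_ehfo, result.label_ehfo = p, labels
    return result


def _positive_column(clf: ReferenceClassifier, proba: np.ndarray) -> np.ndarray:
    classes = np.asarray(clf.classes_)
    pos = np.flatnonzero(classes == 1)
    col = int(pos[0]) if pos.size else int(np.argmax(classes))
    return proba[:, col]


# ---------------------------------------------------------------------------
# Training and distillation


def _split(n: int, val_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    return order[n_val:], order[:n_val]


def train_classifier(images: np.ndarray, labels: Sequence[int],
                     hyper: Optional[dict] = None) -> tuple[ReferenceClassifier, dict]:
    """Train the reference classifier; returns (classifier, training log).

    ``hyper`` keys (all optional): seed, hidden_layer_sizes, pool, max_iter,
    alpha, val_fraction.  Training is fully seeded: the same seed and data
    give identical weights.
    """
    hyper = dict(hyper or {})
    seed = int(hyper.pop("seed", 0))
    val_fraction = float(hyper.pop("val_fraction", 0.25))
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training requires at least two classes in the labels")
    clf = ReferenceClassifier(seed=seed, **hyper)
    images = clf._check_images(images)
    train_idx, val_idx = _split(images.shape[0], val_fraction, seed)
    clf.fit(images[train_idx], labels[train_idx])
    train_acc = float(np.mean(clf.predict(images[train_idx]) == labels[train_idx]))
    val_acc = float(np.mean(clf.predict(images[val_idx]) == labels[val_idx]))
    log = {"seed": seed, "n_train": int(train_idx.size), "n_val": int(val_idx.size),
           "train_accuracy": train_acc, "val_accuracy": val_acc,
           "val_predictions": clf.predict(images[val_idx]).tolist(),
           "classes": np.unique(labels).tolist()}
    logger.info("trained classifier: train acc %.3f, val acc %.3f", train_acc, val_acc)
    return clf, log


def distill_model(teacher: ReferenceClassifier, images: np.ndarray,
                  hyper: Optional[dict] = None) -> tuple[ReferenceClassifier, dict]:
    """Distill a teacher into a fresh student via hard pseudo-labels.

    The teacher's argmax predictions on ``images`` become the training labels
    (soft-label distillation is available via ``hyper={'soft': True}``, which
    weights samples by teacher confidence).  Aborts if the teacher emits a
    single class on all images.  Returns (student, report) where the report
    carries held-out teacher–student agreement.
    """
    hyper = dict(hyper or {})
    seed = int(hyper.pop("seed", 0))
    soft = bool(hyper.pop("soft", False))
    val_fraction = float(hyper.pop("val_fraction", 0.25))
    images = np.asarray(images)
    proba = predict_batch(teacher, images)
    pseudo = teacher.classes_[np.argmax(proba, axis=1)]
    if np.unique(pseudo).size < 2:
        raise ValueError(
            "distillation aborted: teacher predicts a single class on every image; "
            "check the teacher or the image pool")
    student = ReferenceClassifier(seed=seed, **hyper)
    train_idx, val_idx = _split(images.shape[0], val_fraction, seed)
    fit_idx = train_idx
    if soft:
        # confidence-weighted resampling: confident pseudo-labels count more
        conf = np.max(proba[train_idx], axis=1)
        repeats = 1 + np.round(2 * (conf - 0.5) * 2).astype(int).clip(0)
        fit_idx = np.repeat(train_idx, repeats)
    student.fit(images[fit_idx], pseudo[fit_idx])
    agree_train = float(np.mean(student.predict(images[train_idx]) == pseudo[train_idx]))
    agree_val = float(np.mean(student.predict(images[val_idx]) == pseudo[val_idx]))
    report = {"seed": seed, "n_train": int(train_idx.size), "n_val": int(val_idx.size),
              "agreement_train": agree_train, "agreement_holdout": agree_val}
    logger.info("distilled student: train agreement %.3f, held-out agreement %.3f",
                agree_train, agree_val)
    return student, report
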