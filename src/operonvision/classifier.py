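"""Image classification of gene pairs as operonic or non-operonic.

The classifier is a scikit-learn estimator: a frozen, deterministic visual
featurizer (alpha compositing over white, bilinear downscaling to a square
input, per-channel flattening) feeding a trained logistic-regression head.
This mirrors the frozen-backbone / trainable-head recipe of transfer learning
at a scale that runs in seconds on one CPU with no pretrained weights: only
the head ever sees the labels.

Explanations come from occlusion sensitivity: sliding a neutral patch across
the input and recording how much the predicted-class probability drops.  The
result is a normalized attention heat map aligned to the input image, with an
alpha-blended overlay, serving the same role as gradient-based class
activation maps for convolutional networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from PIL import Image
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .dataset import NON_OPERONIC, OPERONIC, DatasetManifest
from .render import RenderedExample, composite_on_white


class ClassifierError(ValueError):
    pass


@dataclass
class TrainConfig:
    """Training knobs; the featurizer itself has no trainable parameters.

    ``max_iter`` bounds the convex solver's iterations (the analog of training
    epochs); ``C`` is inverse L2 regularization strength for the head.
    """

    input_size_px: int = 64
    C: float = 1.0
    max_iter: int = 1000
    augment: bool = True
    seed: int = 0
    threshold: float = 0.5


@dataclass(frozen=True)
class PairCall:
    genome_id: str
    gene_a: str
    gene_b: str
    probability: float
    call: str
    threshold: float = 0.5

    def __post_init__(self) -> None:
        expect = OPERONIC if self.probability >= self.threshold else NON_OPERONIC
        if self.call != expect:
            raise ClassifierError(
                f"call {self.call!r} inconsistent with probability "
                f"{self.probability} at threshold {self.threshold}"
            )


@dataclass
class AttentionMap:
    heat: np.ndarray  # (H, W) float in [0, 1], max 1 unless degenerate
    predicted_label: str
    overlay: np.ndarray  # (H, W, 4) uint8
    degenerate: bool = False  # all-zero heat (no probability drop anywhere)


def _as_pixels(image) -> np.ndarray:
    if isinstance(image, RenderedExample):
        return image.pixels
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ClassifierError(f"expected (H, W, 3|4) image, got shape {arr.shape}")
    return arr


def _featurize_one(pixels: np.ndarray, size: int) -> np.ndarray:
    rgb = composite_on_white(pixels)
    img = Image.fromarray(rgb, mode="RGB").resize((size, size), Image.BILINEAR)
    return (np.asarray(img, dtype=np.float64) / 255.0).ravel()


class PairImageClassifier(ClassifierMixin, BaseEstimator):
    """Operonic-pair image classifier: frozen featurizer + logistic head.

    Parameters
    ----------
    input_size_px : side length of the square model input; images of any size
        are resized (never cropped).
    C : inverse regularization strength of the logistic head.
    max_iter : solver iteration budget.
    augment : if True, ``fit`` also trains on the horizontal mirror of every
        image — the only augmentation ever applied.
    random_state : seed for the solver (training is deterministic given it).
    """

    def __init__(
        self,
        input_size_px: int = 64,
        C: float = 1.0,
        max_iter: int = 1000,
        augment: bool = True,
        random_state: int = 0,
    ):
        self.input_size_px = input_size_px
        self.C = C
        self.max_iter = max_iter
        self.augment = augment
        self.random_state = random_state

    # -- sklearn API --------------------------------------------------------

    def fit(self, X: Sequence, y: Sequence[str]) -> "PairImageClassifier":
        images = [_as_pixels(x) for x in X]
        y = np.asarray(y, dtype=object)
        if len(images) != len(y):
            raise ClassifierError("X and y length mismatch")
        classes = sorted(set(y.tolist()))
        if len(classes) < 2:
            raise ClassifierError(f"training needs both classes, got {classes}")
        feats = [_featurize_one(px, self.input_size_px) for px in images]
        labels = list(y)
        if self.augment:
            feats += [_featurize_one(px[:, ::-1], self.input_size_px) for px in images]
            labels += list(y)
        Xmat = np.vstack(feats)
        self.head_ = LogisticRegression(
            C=self.C,
            max_iter=self.max_iter,
            random_state=self.random_state,
            solver="lbfgs",
        )
        self.head_.fit(Xmat, labels)
        self.classes_ = self.head_.classes_
        self.n_features_in_ = Xmat.shape[1]
        return self

    def _features(self, X: Sequence) -> np.ndarray:
        return np.vstack([_featurize_one(_as_pixels(x), self.input_size_px) for x in X])

    def predict_proba(self, X: Sequence) -> np.ndarray:
        check_is_fitted(self, "head_")
        return self.head_.predict_proba(self._features(X))

    def predict(self, X: Sequence) -> np.ndarray:
        check_is_fitted(self, "head_")
        return self.head_.predict(self._features(X))

    def operonic_probability(self, X: Sequence) -> np.ndarray:
        """Probability of the operonic class, per image."""
        proba = self.predict_proba(X)
        idx = int(np.where(self.classes_ == OPERONIC)[0][0])
        return proba[:, idx]


# ---------------------------------------------------------------------------
# Module-level wrappers
# ---------------------------------------------------------------------------

def _manifest_images_labels(manifest: DatasetManifest):
    images, labels, meta = [], [], []
    for e in manifest.entries:
        if isinstance(e.image, RenderedExample):
            images.append(e.image.pixels)
        elif isinstance(e.image, str):
            images.append(np.asarray(Image.open(e.image).convert("RGBA")))
        else:
            images.append(_as_pixels(e.image))
        labels.append(e.label)
        meta.append((e.genome_id, e.gene_a, e.gene_b))
    return images, labels, meta


def train(manifest: DatasetManifest, cfg: Optional[TrainConfig] = None) -> PairImageClassifier:
    """Fit a :class:`PairImageClassifier` on a labeled manifest."""
    cfg = cfg or TrainConfig()
    if len(manifest) == 0:
        raise ClassifierError("empty training manifest")
    images, labels, _ = _manifest_images_labels(manifest)
    clf = PairImageClassifier(
        input_size_px=cfg.input_size_px,
        C=cfg.C,
        max_iter=cfg.max_iter,
        augment=cfg.augment,
        random_state=cfg.seed,
    )
    return clf.fit(images, labels)


def save_model(model: PairImageClassifier, path: str | Path) -> None:
    joblib.dump(model, path)


def load_model(path: str | Path) -> PairImageClassifier:
    model = joblib.load(path)
    if not isinstance(model, PairImageClassifier):
        raise ClassifierError(f"{path} does not contain a PairImageClassifier")
    return model


def predict_pairs(
    model: PairImageClassifier,
    examples: Sequence[RenderedExample],
    threshold: float = 0.5,
) -> list[PairCall]:
    """Score rendered pair images; call operonic iff probability >= threshold."""
    if not examples:
        return []
    probs = model.operonic_probability([e.pixels for e in examples])
    calls = []
    for e, p in zip(examples, probs):
        genome, ga, gb = e.provenance
        p = float(p)
        calls.append(
            PairCall(
                genome_id=genome,
                gene_a=ga,
                gene_b=gb,
                probability=p,
                call=OPERONIC if p >= threshold else NON_OPERONIC,
                threshold=threshold,
            )
        )
    return calls


def write_calls(calls: Sequence[PairCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tgene_a\tgene_b\tprobability\tcall\n")
        for c in calls:
            fh.write(f"{c.genome_id}\t{c.gene_a}\t{c.gene_b}\t{c.probability:.6f}\t{c.call}\n")


# ---------------------------------------------------------------------------
# Occlusion-based attention maps
# ---------------------------------------------------------------------------

_HEAT_CMAP = None


def _heat_rgb(heat: np.ndarray) -> np.ndarray:
    global _HEAT_CMAP
    if _HEAT_CMAP is None:
        import matplotlib

        _HEAT_CMAP = matplotlib.colormaps["jet"]
    return (np.asarray(_HEAT_CMAP(heat))[..., :3] * 255).astype(np.uint8)


def explain_pair(
    model: PairImageClassifier,
    image,
    patch_px: int = 8,
    stride_px: int = 4,
) -> AttentionMap:
    """Occlusion-sensitivity attention map for the model's predicted class.

    A white patch slides over the downscaled model input; the per-pixel mean
    probability drop (clipped at zero) is min-max normalized and upsampled to
    the original image size.  All-zero maps are allowed and flagged.
    """
    check_is_fitted(model, "head_")
    pixels = _as_pixels(image)
    H, W = pixels.shape[:2]
    size = model.input_size_px
    base = _featurize_one(pixels, size).reshape(size, size, 3)

    pred = model.predict([pixels])[0]
    cls_idx = int(np.where(model.classes_ == pred)[0][0])
    p0 = float(model.head_.predict_proba(base.reshape(1, -1))[0, cls_idx])

    drops = np.zeros((size, size), dtype=np.float64)
    counts = np.zeros((size, size), dtype=np.float64)
    patches = []
    spans = []
    for y in range(0, size - patch_px + 1, stride_px):
        for x in range(0, size - patch_px + 1, stride_px):
            occluded = base.copy()
            occluded[y : y + patch_px, x : x + patch_px, :] = 1.0  # white patch
            patches.append(occluded.reshape(-1))
            spans.append((y, x))
    probs = model.head_.predict_proba(np.vstack(patches))[:, cls_idx]
    for (y, x), p in zip(spans, probs):
        drops[y : y + patch_px, x : x + patch_px] += max(0.0, p0 - float(p))
        counts[y : y + patch_px, x : x + patch_px] += 1.0
    heat_small = np.where(counts > 0, drops / np.maximum(counts, 1.0), 0.0)

    peak = heat_small.max()
    degenerate = bool(peak <= 0.0)
    if not degenerate:
        heat_small = heat_small / peak
    heat = np.asarray(
        Image.fromarray((heat_small * 255).astype(np.uint8), mode="L").resize(
            (W, H), Image.BILINEAR
        ),
        dtype=np.float64,
    ) / 255.0
    if heat.max() > 0:
        heat = heat / heat.max()

    rgb_in = composite_on_white(pixels).astype(np.float64)
    heat_rgb = _heat_rgb(heat).astype(np.float64)
    blend = np.round(0.5 * rgb_in + 0.5 * heat_rgb).astype(np.uint8)
    overlay = np.dstack([blend, np.full((H, W), 255, dtype=np.uint8)])
    return AttentionMap(
        heat=heat, predicted_label=str(pred), overlay=overlay, degenerate=degenerate
    )
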