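"""Procedural generation of order-discrimination image pairs.

Each stimulus is a 224x224 grayscale image of identical shapes placed on a
3x3 grid, described by five features: grayscale color, number of shapes,
size, grid arrangement and shape type.  A pair of images realizes a rule: a
single scalar *predictive feature* (color, size or number) differs between
the left and the right image by the signed, normalized amount ``alpha``
(``alpha = +1`` is the maximal feasible increase); every other feature is
drawn once per pair and is identical in both images.

Conventions (normalizations and pixel maps):

* color, size live in [0, 1]; number n in {1..9} normalizes to (n-1)/8,
  so a predictive-number rule requires alpha to be a multiple of 1/8;
* size maps to the diameter of the enclosing circle, 12..70 px at the
  native 224-px side (scaled proportionally for other sides);
* color maps to the shape gray level 0..0.78 on a white (1.0) background,
  so shapes never blend into the background;
* rasterization is hard-edged (a pixel is filled iff its center falls
  inside the shape), which makes rendering bit-exact reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json

import numpy as np
from matplotlib.path import Path as MplPath

SHAPE_CATALOG = ("circle", "square", "triangle", "star", "cross")
PREDICTIVE_FEATURES = ("color", "number", "size")

_DIAM_MIN, _DIAM_MAX = 12.0, 70.0   # enclosing-circle diameter at side=224
_GRAY_MAX = 0.78                    # darkest..lightest shape gray level span
_BACKGROUND = 1.0


@dataclass(frozen=True)
class FeatureVector:
    """Complete description of one stimulus image."""

    color: float                 # normalized gray level in [0, 1]
    number: int                  # shape count in {1..9}
    size: float                  # normalized enclosing-circle diameter in [0, 1]
    arrangement: tuple[int, ...]  # occupied cells (0..8), |arrangement| == number
    shape_type: str

    def __post_init__(self):
        if not 0.0 <= self.color <= 1.0:
            raise ValueError(f"color {self.color} outside [0, 1]")
        if not 0.0 <= self.size <= 1.0:
            raise ValueError(f"size {self.size} outside [0, 1]")
        if not 1 <= self.number <= 9:
            raise ValueError(f"number {self.number} outside 1..9")
        if len(set(self.arrangement)) != self.number:
            raise ValueError("arrangement must hold `number` distinct cells")
        if self.shape_type not in SHAPE_CATALOG:
            raise ValueError(f"unknown shape type {self.shape_type!r}")


@dataclass(frozen=True)
class TaskConfig:
    """Defines one stimulus stream (a rule plus counts and a seed)."""

    predictive_feature: str = "size"
    alpha: float = 0.5
    n_train_pairs: int = 160
    n_test_pairs: int = 32
    image_side: int = 224
    seed: int = 0

    def __post_init__(self):
        if self.predictive_feature not in PREDICTIVE_FEATURES:
            raise ValueError(
                f"predictive_feature must be one of {PREDICTIVE_FEATURES}")
        if not abs(self.alpha) <= 1.0:
            raise ValueError(f"|alpha| must be <= 1, got {self.alpha}")
        if self.predictive_feature == "number":
            if abs(round(self.alpha * 8) - self.alpha * 8) > 1e-9:
                raise ValueError(
                    "a predictive-number rule needs alpha in multiples of 1/8")

    def with_alpha(self, alpha: float) -> "TaskConfig":
        return replace(self, alpha=alpha)


@dataclass
class ImagePair:
    """Two rendered images plus the feature values that generated them."""

    left_image: np.ndarray
    right_image: np.ndarray
    left_features: FeatureVector
    right_features: FeatureVector
    alpha: float


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _polygon_mask(xx, yy, verts):
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    return MplPath(verts).contains_points(pts).reshape(xx.shape)


def _shape_mask(shape_type: str, xx, yy, cx, cy, diam: float) -> np.ndarray:
    """Boolean mask of a shape inscribed in a circle of diameter `diam`."""
    R = diam / 2.0
    dx, dy = xx - cx, yy - cy
    if shape_type == "circle":
        return dx * dx + dy * dy <= R * R
    if shape_type == "square":
        h = R / np.sqrt(2.0)
        return (np.abs(dx) <= h) & (np.abs(dy) <= h)
    if shape_type == "cross":
        w = 0.35 * R
        return ((np.abs(dx) <= w) & (np.abs(dy) <= R)) | \
               ((np.abs(dy) <= w) & (np.abs(dx) <= R))
    if shape_type == "triangle":
        ang = np.deg2rad([90.0, 210.0, 330.0])
    elif shape_type == "star":
        outer = np.deg2rad(90.0 + 72.0 * np.arange(5))
        inner = np.deg2rad(126.0 + 72.0 * np.arange(5))
        ang = np.empty(10)
        ang[0::2], ang[1::2] = outer, inner
        rad = np.empty(10)
        rad[0::2], rad[1::2] = R, 0.4 * R
        verts = np.column_stack([cx + rad * np.cos(ang),
                                 cy - rad * np.sin(ang)])
        return _polygon_mask(xx, yy, verts)
    else:  # pragma: no cover - guarded by FeatureVector validation
        raise ValueError(shape_type)
    verts = np.column_stack([cx + R * np.cos(ang), cy - R * np.sin(ang)])
    return _polygon_mask(xx, yy, verts)


def render_image(features: FeatureVector, side: int = 224) -> np.ndarray:
    """Rasterize a FeatureVector to a (side, side) float32 array in [0, 1].

    Deterministic: identical features yield pixel-identical images.
    """
    cell = side / 3.0
    diam = (_DIAM_MIN + features.size * (_DIAM_MAX - _DIAM_MIN)) * (side / 224.0)
    if diam > cell:
        raise ValueError(
            f"shape diameter {diam:.1f}px exceeds grid-cell extent {cell:.1f}px")
    gray = np.float32(_GRAY_MAX * features.color)
    img = np.full((side, side), _BACKGROUND, dtype=np.float32)
    half = diam / 2.0
    for c in features.arrangement:
        row, col = divmod(c, 3)
        cy, cx = (row + 0.5) * cell, (col + 0.5) * cell
        # restrict rasterization to the shape's bounding box
        i0, i1 = int(np.floor(cy - half)), int(np.ceil(cy + half)) + 1
        j0, j1 = int(np.floor(cx - half)), int(np.ceil(cx + half)) + 1
        i0, j0 = max(i0, 0), max(j0, 0)
        i1, j1 = min(i1, side), min(j1, side)
        ii = np.arange(i0, i1) + 0.5
        jj = np.arange(j0, j1) + 0.5
        yy, xx = np.meshgrid(ii, jj, indexing="ij")
        mask = _shape_mask(features.shape_type, xx, yy, cx, cy, diam)
        img[i0:i1, j0:j1][mask] = gray
    return img


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _feasible_uniform(alpha: float, rng: np.random.Generator) -> float:
    # uniform over left values whose partner left+alpha stays in [0, 1]
    if alpha >= 0.0:
        return float(rng.uniform(0.0, 1.0 - alpha))
    return float(rng.uniform(-alpha, 1.0))


def _nested_arrangements(n_left: int, n_right: int, rng: np.random.Generator):
    # one random cell order per pair; each image occupies a prefix of it, so
    # the arrangements are nested when the predictive feature is the number
    order = rng.permutation(9)
    return tuple(int(v) for v in order[:n_left]), \
        tuple(int(v) for v in order[:n_right])


def sample_pair(config: TaskConfig, rng: np.random.Generator) -> ImagePair:
    """Draw one image pair realizing the rule in `config`.

    The left predictive value is uniform over its feasible interval; all
    non-predictive features are drawn once and shared by both images.
    """
    if not abs(config.alpha) <= 1.0:
        raise ValueError("|alpha| must be <= 1")
    alpha = config.alpha
    feat = config.predictive_feature

    color = float(rng.uniform(0.0, 1.0))
    size = float(rng.uniform(0.0, 1.0))
    number = int(rng.integers(1, 10))
    shape_type = SHAPE_CATALOG[rng.integers(0, len(SHAPE_CATALOG))]

    left = {"color": color, "size": size, "number": number}
    right = dict(left)
    if feat == "number":
        k = int(round(alpha * 8))
        lo, hi = max(1, 1 - k), min(9, 9 - k)
        n_left = int(rng.integers(lo, hi + 1))
        left["number"], right["number"] = n_left, n_left + k
    else:
        v = _feasible_uniform(alpha, rng)
        left[feat], right[feat] = v, v + alpha
    arr_l, arr_r = _nested_arrangements(left["number"], right["number"], rng)

    fl = FeatureVector(color=left["color"], number=left["number"],
                       size=left["size"], arrangement=arr_l,
                       shape_type=shape_type)
    fr = FeatureVector(color=right["color"], number=right["number"],
                       size=right["size"], arrangement=arr_r,
                       shape_type=shape_type)
    return ImagePair(
        left_image=render_image(fl, config.image_side),
        right_image=render_image(fr, config.image_side),
        left_features=fl, right_features=fr, alpha=alpha)


def make_phase(config: TaskConfig):
    """Training pairs plus a held-out probe/test set from the same rule.

    Returns (train_pairs, test_pairs); reproducible from ``config.seed``.
    """
    if config.n_train_pairs < 0 or config.n_test_pairs <= 0:
        raise ValueError("pair counts must be positive")
    rng = np.random.default_rng(config.seed)
    train = [sample_pair(config, rng) for _ in range(config.n_train_pairs)]
    test = [sample_pair(config, rng) for _ in range(config.n_test_pairs)]
    return train, test


# ---------------------------------------------------------------------------
# external interfaces
# ---------------------------------------------------------------------------

def predictive_value(f: FeatureVector, feature: str) -> float:
    """The normalized scalar value of `feature` in a FeatureVector."""
    if feature == "number":
        return (f.number - 1) / 8.0
    return float(getattr(f, feature))


def save_pair_png(pair: ImagePair, left_path, right_path) -> None:
    from PIL import Image
    for img, path in ((pair.left_image, left_path),
                      (pair.right_image, right_path)):
        Image.fromarray((img * 255).astype(np.uint8), mode="L").save(path)


def phase_manifest(pairs: list[ImagePair], feature: str) -> list[dict]:
    rows = []
    for i, p in enumerate(pairs):
        rows.append({
            "pair": i, "alpha": p.alpha,
            "left_value": predictive_value(p.left_features, feature),
            "right_value": predictive_value(p.right_features, feature),
            "color": p.left_features.color, "size": p.left_features.size,
            "number_left": p.left_features.number,
            "number_right": p.right_features.number,
            "shape_type": p.left_features.shape_type,
        })
    return rows


def load_task_config(path) -> TaskConfig:
    """Read a TaskConfig from a YAML or JSON file."""
    text = open(path).read()
    if str(path).endswith((".yml", ".yaml")):
        import yaml
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return TaskConfig(**data)
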