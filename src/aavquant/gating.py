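"""Morphology-feature gating of marker detections.

Detection alone accepts anything bright enough; real sections also contain
debris speckles and (in the GFP channel) a dim nuclear autofluorescence
floor.  The gate reproduces the researcher-in-the-loop step of an HCS
workflow: detections are described by geometric and intensity-distribution
features, a researcher labels a set of them true/false, and a seeded,
regularised linear classifier learns the boundary.  The decision threshold
on the classifier's probability score is the *stringency* knob: the default
gate is stringent, the relaxed gate lowers the threshold so that more
(including some background) detections pass — mirroring the published
relaxed-GFP reanalysis.

Interactive labelling is replaced by CSV files (object_id,label) matched
against an exported feature table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.linear_model import LogisticRegression

from .imgio import Mosaic
from .segment import DetectedObject

FEATURE_NAMES = (
    "area_um2",
    "roundness",
    "aspect_ratio",  # width / length of the mask (minor / major axis)
    "mean_intensity",
    "peak_intensity",
    "std_intensity",
    "contrast",
    "radial_slope",  # (inner-half mean - rim mean) / (inner + rim): flat-top
    #                  nuclei score near 0-0.3, sharp speckles near 1
    "texture_energy",  # mean squared gradient inside the mask, normalised
)

DEFAULT_STRINGENCY = 0.5
RELAXED_STRINGENCY = 0.05


@dataclass
class FeatureVector:
    values: np.ndarray  # aligned with FEATURE_NAMES

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, map(float, self.values)))


def extract_features(obj: DetectedObject, mosaic: Mosaic | np.ndarray) -> FeatureVector:
    """Geometric and intensity-distribution features of one detection.

    Deterministic; intensity features are read from the (unsmoothed)
    mosaic channel the object was detected on, geometry is in um units.
    """
    if obj.mask is None or obj.mask.sum() == 0:
        raise ValueError("object has an empty mask")
    image = mosaic.channels[obj.channel] if isinstance(mosaic, Mosaic) else mosaic
    r0, c0 = obj.mask_offset
    h, w = obj.mask.shape
    patch = np.asarray(image[r0 : r0 + h, c0 : c0 + w], dtype=np.float64)
    mask = obj.mask
    vals = patch[mask]
    mean = float(vals.mean())
    peak = float(vals.max())
    std = float(vals.std())

    rows, cols = np.nonzero(mask)
    cy, cx = rows.mean(), cols.mean()
    # principal axes of the pixel distribution -> width/length ratio
    if len(rows) > 1:
        cov = np.cov(np.vstack([cols - cx, rows - cy]))
        evals = np.linalg.eigvalsh(cov)
        evals = np.clip(evals, 1e-9, None)
        aspect = float(np.sqrt(evals[0] / evals[1]))
    else:
        aspect = 1.0

    # radial intensity slope: centre half vs rim of the mask
    r = np.sqrt((rows - cy) ** 2 + (cols - cx) ** 2)
    r_max = max(float(r.max()), 1.0)
    inner = vals[r <= 0.5 * r_max]
    rim = vals[r > 0.8 * r_max]
    if len(inner) and len(rim):
        im_, rm_ = float(inner.mean()), float(rim.mean())
        radial_slope = (im_ - rm_) / (im_ + rm_) if (im_ + rm_) > 0 else 0.0
    else:
        radial_slope = 0.0

    gy = ndimage.sobel(patch, axis=0)
    gx = ndimage.sobel(patch, axis=1)
    g2 = (gx**2 + gy**2)[mask]
    texture = float(g2.mean()) / (mean**2 + 1.0)

    values = np.array(
        [obj.area_um2, obj.roundness, aspect, mean, peak, std, obj.contrast, radial_slope, texture]
    )
    return FeatureVector(values=values)


def feature_table(objects: list[DetectedObject], mosaic: Mosaic | np.ndarray) -> pd.DataFrame:
    rows = []
    for obj in objects:
        fv = extract_features(obj, mosaic)
        row = {"object_id": obj.object_id, "x_um": obj.x_um, "y_um": obj.y_um}
        row.update(fv.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["object_id", "x_um", "y_um", *FEATURE_NAMES])


@dataclass
class GateModel:
    """Linear decision function over the feature vector.

    Features are standardised with the stored training mean/scale; the
    score is a logistic probability in [0, 1] and ``threshold`` is the
    default stringency.
    """

    weights: np.ndarray
    bias: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    threshold: float = DEFAULT_STRINGENCY
    n_true: int = 0
    n_false: int = 0
    seed: int = 0

    def score(self, features: np.ndarray) -> np.ndarray:
        """Probability-of-true for feature rows (shape (n, n_features))."""
        X = np.atleast_2d(np.asarray(features, dtype=np.float64))
        Z = (X - self.feature_mean) / self.feature_scale
        logits = Z @ self.weights + self.bias
        return 1.0 / (1.0 + np.exp(-np.clip(logits, -500, 500)))

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"threshold = {float(self.threshold)!r}\n")
            fh.write(f"bias = {float(self.bias)!r}\n")
            fh.write(f"n_true = {self.n_true}\n")
            fh.write(f"n_false = {self.n_false}\n")
            fh.write(f"seed = {self.seed}\n")
            for name, w, mu, sc in zip(FEATURE_NAMES, self.weights, self.feature_mean, self.feature_scale):
                fh.write(f"weight.{name} = {float(w)!r}\n")
                fh.write(f"mean.{name} = {float(mu)!r}\n")
                fh.write(f"scale.{name} = {float(sc)!r}\n")

    @classmethod
    def load(cls, path: str) -> "GateModel":
        kv: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, v = (s.strip() for s in line.split("=", 1))
                kv[k] = v
        return cls(
            weights=np.array([float(kv[f"weight.{n}"]) for n in FEATURE_NAMES]),
            bias=float(kv["bias"]),
            feature_mean=np.array([float(kv[f"mean.{n}"]) for n in FEATURE_NAMES]),
            feature_scale=np.array([float(kv[f"scale.{n}"]) for n in FEATURE_NAMES]),
            threshold=float(kv["threshold"]),
            n_true=int(kv["n_true"]),
            n_false=int(kv["n_false"]),
            seed=int(kv["seed"]),
        )


def train_gate(
    examples: list[tuple[FeatureVector, bool]] | tuple[np.ndarray, np.ndarray],
    seed: int = 0,
    threshold: float = DEFAULT_STRINGENCY,
) -> GateModel:
    """Fit the linear gate from researcher-labelled examples.

    ``examples`` is either a list of (FeatureVector, label) pairs or an
    (X, y) tuple.  Both classes must be present.  The fit is an L2-
    regularised logistic regression on standardised features and is
    deterministic for a given seed.
    """
    if isinstance(examples, tuple):
        X, y = examples
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=bool)
    else:
        X = np.array([fv.values for fv, _ in examples], dtype=np.float64)
        y = np.array([bool(lbl) for _, lbl in examples])
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("malformed training data")
    if y.all() or (~y).all():
        raise ValueError("training examples must include both a true and a false class")
    mu = X.mean(axis=0)
    sc = X.std(axis=0)
    sc = np.where(sc < 1e-12, 1.0, sc)
    Z = (X - mu) / sc
    clf = LogisticRegression(C=20.0, max_iter=2000, random_state=int(seed))
    clf.fit(Z, y.astype(int))
    return GateModel(
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        feature_mean=mu,
        feature_scale=sc,
        threshold=threshold,
        n_true=int(y.sum()),
        n_false=int((~y).sum()),
        seed=int(seed),
    )


def train_gate_from_tables(features: pd.DataFrame, labels: pd.DataFrame, seed: int = 0) -> GateModel:
    """Train from an exported feature table and a (object_id,label) CSV table."""
    merged = features.merge(labels[["object_id", "label"]], on="object_id", how="inner")
    X = merged[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    y = merged["label"].astype(bool).to_numpy()
    return train_gate((X, y), seed=seed)


def apply_gate(
    objects: list[DetectedObject],
    model: GateModel,
    mosaic: Mosaic | np.ndarray,
    stringency: float | None = None,
) -> list[DetectedObject]:
    """Keep the objects whose gate score reaches the stringency threshold.

    The output is always a subset of the input and shrinks monotonically as
    stringency rises: -inf passes everything, +inf nothing.
    """
    if stringency is None:
        stringency = model.threshold
    if not objects:
        return []
    X = np.array([extract_features(o, mosaic).values for o in objects])
    scores = model.score(X)
    return [o for o, s in zip(objects, scores) if s >= stringency]
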