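"""Pixel-wise density regression with extremely randomized trees.

Training pairs every pixel inside the labelled regions with its density
value; an ensemble of extremely randomized regression trees (random split
feature and uniformly random threshold per candidate, best candidate by
variance reduction of the density labels) learns the mapping.  Predicted
density maps are the per-pixel ensemble mean, and their sum over the image
is the raw predicted count (PC).

The scikit-learn ``ExtraTreesRegressor`` implements exactly this split
family and backs the ensemble.  Defaults: 30 fully grown trees, minimum
one sample per leaf, sqrt(F) split candidates per node.
"""

from __future__ import annotations

import hashlib
import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import joblib
import numpy as np
import sklearn
from sklearn.ensemble import ExtraTreesRegressor

from . import __version__
from .annotations import ROI, DotAnnotation
from .bias import BiasModel, RegionPair
from .density import DensityConfig, DensityMap, count_from_density, make_density_map
from .features import FeatureConfig, FeatureStack, compute_feature_stack

ARCHIVE_FORMAT_VERSION = 1


class ModelFormatError(RuntimeError):
    """Raised when a model archive cannot be loaded safely."""


@dataclass
class TrainingSet:
    """Design matrix of ROI pixels and their density targets."""

    X: np.ndarray                    # (N, F) float32
    y: np.ndarray                    # (N,) float64, objects/pixel
    provenance: List[Tuple[str, ROI]] = field(default_factory=list)
    feature_names: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.X.shape[0] == 0:
            raise ValueError("training set is empty")
        if (self.y < 0).any():
            raise ValueError("density targets must be non-negative")


@dataclass
class TrainedModel:
    ensemble: ExtraTreesRegressor
    n_trees: int
    feature_config: FeatureConfig
    density_config: DensityConfig
    seed: Optional[int]
    training_digest: dict = field(default_factory=dict)
    bias: Optional[BiasModel] = None

    @property
    def feature_names(self) -> List[str]:
        return self.feature_config.feature_names()


def build_training_set(images: Sequence[np.ndarray],
                       annotations: Sequence[DotAnnotation],
                       rois: Optional[Sequence[Sequence[ROI]]] = None,
                       feature_cfg: Optional[FeatureConfig] = None,
                       density_cfg: Optional[DensityConfig] = None,
                       stacks: Optional[Sequence[FeatureStack]] = None,
                       max_pixels: Optional[int] = None,
                       seed: Optional[int] = None) -> TrainingSet:
    """Assemble (features, density) rows from the labelled ROIs.

    The density map is built on the FULL image and then cropped to each
    ROI, so Gaussian mass from eggs just outside an ROI still contributes
    to its border pixels.  Row order is deterministic: image order, then
    ROI order, then row-major within the ROI.

    ``stacks`` may supply precomputed feature stacks (one per image) to
    avoid recomputation.  ``max_pixels`` draws a seeded uniform subsample
    of the rows, useful when ROIs cover whole high-resolution images.
    """
    feature_cfg = feature_cfg or FeatureConfig()
    density_cfg = density_cfg or DensityConfig()
    if len(images) != len(annotations):
        raise ValueError("need one annotation per image")
    if rois is None:
        rois = [[ROI.whole_image(np.asarray(img).shape[:2])] for img in images]
    if len(rois) != len(images):
        raise ValueError("need one ROI list per image")
    if all(len(r) == 0 for r in rois):
        raise ValueError("no ROIs given")

    x_blocks: List[np.ndarray] = []
    y_blocks: List[np.ndarray] = []
    provenance: List[Tuple[str, ROI]] = []
    for idx, (img, ann, img_rois) in enumerate(zip(images, annotations, rois)):
        if not img_rois:
            continue
        img = np.asarray(img)
        shape = img.shape[:2]
        if stacks is not None:
            stack = stacks[idx]
        else:
            stack = compute_feature_stack(img, feature_cfg, dtype=np.float32)
        dens = make_density_map(ann, shape, density_cfg)
        for roi in img_rois:
            roi.validate_for_shape(shape)
            sl = roi.slices()
            x_blocks.append(stack.values[sl].reshape(roi.area, -1))
            y_blocks.append(dens.values[sl].reshape(roi.area))
            provenance.append((ann.image_id, roi))

    X = np.concatenate(x_blocks, axis=0).astype(np.float32, copy=False)
    y = np.concatenate(y_blocks, axis=0)
    if max_pixels is not None and X.shape[0] > max_pixels:
        rng = np.random.default_rng(seed)
        keep = rng.choice(X.shape[0], size=max_pixels, replace=False)
        keep.sort()
        X, y = X[keep], y[keep]
    return TrainingSet(X=X, y=y, provenance=provenance,
                       feature_names=feature_cfg.feature_names())


def fit(ts: TrainingSet, n_trees: int = 30, seed: Optional[int] = None,
        feature_cfg: Optional[FeatureConfig] = None,
        density_cfg: Optional[DensityConfig] = None,
        max_features="sqrt", min_samples_leaf: int = 1) -> TrainedModel:
    """Fit the tree ensemble; deterministic given (ts, n_trees, seed)."""
    if n_trees < 1:
        raise ValueError(f"n_trees must be >= 1, got {n_trees}")
    if ts.X.shape[0] < 2:
        raise ValueError("need at least 2 training pixels")
    ensemble = ExtraTreesRegressor(
        n_estimators=n_trees,
        criterion="squared_error",
        max_features=max_features,
        min_samples_leaf=min_samples_leaf,
        bootstrap=False,
        random_state=seed,
        n_jobs=1,
    )
    ensemble.fit(ts.X, ts.y)
    digest = {
        "n_pixels": int(ts.X.shape[0]),
        "n_features": int(ts.X.shape[1]),
        "images": sorted({img_id for img_id, _ in ts.provenance}),
        "n_rois": len(ts.provenance),
        "y_min": float(ts.y.min()),
        "y_max": float(ts.y.max()),
        "y_sum": float(ts.y.sum()),
    }
    return TrainedModel(
        ensemble=ensemble, n_trees=n_trees,
        feature_config=feature_cfg or FeatureConfig(),
        density_config=density_cfg or DensityConfig(),
        seed=seed, training_digest=digest,
    )


def predict_density(m: TrainedModel, stack: FeatureStack) -> DensityMap:
    """Per-pixel ensemble-mean density for one feature stack."""
    expected = m.feature_names
    if stack.feature_names != expected:
        missing = [n for n in expected if n not in stack.feature_names]
        extra = [n for n in stack.feature_names if n not in expected]
        raise ValueError(
            "feature stack does not match the model's feature configuration; "
            f"missing={missing!r} unexpected={extra!r}")
    X = stack.as_matrix().astype(np.float32, copy=False)
    pred = m.ensemble.predict(X)
    h, w = stack.image_shape
    return DensityMap(values=pred.reshape(h, w))


def predict_count(m: TrainedModel, image: np.ndarray,
                  stack: Optional[FeatureStack] = None) -> float:
    """Raw predicted count PC: features -> density -> whole-image sum."""
    if stack is None:
        stack = compute_feature_stack(np.asarray(image), m.feature_config,
                                      dtype=np.float32)
    return count_from_density(predict_density(m, stack))


# -- model archive ----------------------------------------------------------

def _header_dict(m: TrainedModel) -> dict:
    return {
        "format_version": ARCHIVE_FORMAT_VERSION,
        "package": "ovicount",
        "package_version": __version__,
        "sklearn_version": sklearn.__version__,
        "n_trees": m.n_trees,
        "seed": m.seed,
        "feature_config": {"scales": list(m.feature_config.scales),
                           "channels": list(m.feature_config.channels)},
        "density_config": {"sigma": m.density_config.sigma,
                           "truncation_radius": m.density_config.truncation_radius},
        "training_digest": m.training_digest,
    }


def _content_digest(header: dict, ensemble_bytes: bytes) -> str:
    canon = json.dumps(header, sort_keys=True).encode("utf-8")
    return hashlib.sha256(canon + ensemble_bytes).hexdigest()


def save_model(m: TrainedModel, path) -> None:
    """Write a self-describing archive: JSON header + serialized ensemble."""
    buf = io.BytesIO()
    joblib.dump(m.ensemble, buf)
    ensemble_bytes = buf.getvalue()
    header = _header_dict(m)
    header["digest"] = _content_digest(header, ensemble_bytes)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("header.json", json.dumps(header, indent=2, sort_keys=True))
        zf.writestr("ensemble.joblib", ensemble_bytes)
        if m.bias is not None:
            b = m.bias
            zf.writestr("bias.json", json.dumps({
                "beta": b.beta, "c": b.c, "n": b.n, "pc_mean": b.pc_mean,
                "s_xx": b.s_xx, "residual_var": b.residual_var,
                "pairs": [{"pc": p.pc, "ac": p.ac} for p in b.pairs],
            }, indent=2))


def load_model(path) -> TrainedModel:
    """Load an archive; refuses on version or integrity mismatch."""
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        header = json.loads(zf.read("header.json"))
        ensemble_bytes = zf.read("ensemble.joblib")
        bias_json = (json.loads(zf.read("bias.json"))
                     if "bias.json" in zf.namelist() else None)
    if header.get("format_version") != ARCHIVE_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: archive format version {header.get('format_version')!r} "
            f"is not supported (expected {ARCHIVE_FORMAT_VERSION})")
    if header.get("sklearn_version") != sklearn.__version__:
        raise ModelFormatError(
            f"{path}: archive was written with scikit-learn "
            f"{header.get('sklearn_version')}, running {sklearn.__version__}; "
            "refusing to load rather than risk silent misprediction")
    stored_digest = header.pop("digest", None)
    if stored_digest != _content_digest(header, ensemble_bytes):
        raise ModelFormatError(f"{path}: content digest mismatch; archive corrupt "
                               "or header tampered with")
    ensemble = joblib.load(io.BytesIO(ensemble_bytes))
    bias = None
    if bias_json is not None:
        bias = BiasModel(
            beta=bias_json["beta"], c=bias_json["c"],
            pairs=[RegionPair(pc=p["pc"], ac=p["ac"]) for p in bias_json["pairs"]],
            n=bias_json["n"], pc_mean=bias_json["pc_mean"],
            s_xx=bias_json["s_xx"], residual_var=bias_json["residual_var"],
        )
    return TrainedModel(
        ensemble=ensemble,
        n_trees=header["n_trees"],
        feature_config=FeatureConfig(
            scales=tuple(header["feature_config"]["scales"]),
            channels=tuple(header["feature_config"]["channels"])),
        density_config=DensityConfig(**header["density_config"]),
        seed=header["seed"],
        training_digest=header["training_digest"],
        bias=bias,
    )
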