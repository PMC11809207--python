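"""Trainable voxel segmentation from sparse manual labels.

Mirrors the interactive workflow used on real data: a single annotated
confocal slice provides sparse mitochondrion/background labels, a classifier
is trained on per-voxel image features and then applied to the whole stack.
The default classifier is a random forest over a multiscale feature stack
(intensity, Gaussian blurs, gradient magnitude, Laplacian, Hessian
eigenvalues); a plain intensity-threshold classifier is available behind the
same interface for quick runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from sklearn.ensemble import RandomForestClassifier

from .core import BinaryMask, ContractError, GeometryError, ParameterError, VolumetricImage

BACKGROUND, MITOCHONDRION = 0, 1


@dataclass
class LabelSet:
    """Sparse voxel labels, typically from one annotated slice."""

    coords: np.ndarray          # (n, 3) int voxel indices (z, y, x)
    classes: np.ndarray         # (n,) in {0 background, 1 mitochondrion}
    source_slice: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int).reshape(-1, 3)
        self.classes = np.asarray(self.classes, dtype=int).ravel()
        if len(self.coords) != len(self.classes):
            raise ParameterError("coords and classes must have equal length")
        if not set(np.unique(self.classes)) <= {BACKGROUND, MITOCHONDRION}:
            raise ParameterError("classes must be 0 (background) or 1 (mitochondrion)")

    def validate_against(self, shape: tuple[int, int, int]) -> None:
        if np.any(self.coords < 0) or np.any(self.coords >= np.asarray(shape)):
            raise GeometryError("label coordinates outside the image grid")


def labels_from_slice(truth_mask: np.ndarray, z: int, n_per_class: int,
                      seed: int, allow_fewer: bool = False) -> LabelSet:
    """Sample a balanced label set from one z-slice of a reference mask.

    Stands in for the manual single-slice annotation; used by the synthetic
    benchmarks where the reference is the generator's truth mask.  With
    ``allow_fewer`` a sparse slice contributes as many voxels per class as
    it has (at least 10), the way a human annotates whatever the slice shows.
    """
    rng = np.random.default_rng(seed)
    plane = truth_mask[z]
    fg = np.argwhere(plane)
    bg = np.argwhere(~plane)
    n_take = n_per_class
    if len(fg) < n_per_class or len(bg) < n_per_class:
        if not allow_fewer or min(len(fg), len(bg)) < 10:
            raise ParameterError(
                f"slice {z} has {len(fg)} fg / {len(bg)} bg voxels; "
                f"cannot sample {n_per_class} per class")
        n_take = min(len(fg), len(bg), n_per_class)
    fg = fg[rng.choice(len(fg), n_take, replace=False)]
    bg = bg[rng.choice(len(bg), n_take, replace=False)]
    coords = np.concatenate([
        np.column_stack([np.full(len(fg), z), fg]),
        np.column_stack([np.full(len(bg), z), bg]),
    ])
    classes = np.concatenate([np.ones(len(fg), int), np.zeros(len(bg), int)])
    return LabelSet(coords, classes, source_slice=z)


def best_label_slice(truth_mask: np.ndarray) -> int:
    """The z-slice with the most foreground voxels (richest to annotate)."""
    return int(np.argmax(truth_mask.sum(axis=(1, 2))))


# --------------------------------------------------------------------------
# Feature stack
# --------------------------------------------------------------------------

def compute_feature_stack(image: VolumetricImage,
                          scales: Sequence[float] = (1.0, 2.0)) -> np.ndarray:
    """Per-voxel features: raw intensity plus, at each scale, the Gaussian
    blur, gradient magnitude, Laplacian and the smallest/largest Hessian
    eigenvalues — 1 + 5·|scales| channels, float32, shape (C, z, y, x).

    Features are meant to be computed on the isotropically resampled grid;
    scales are in pixels.
    """
    scales = list(scales)
    if not scales or any(s <= 0 for s in scales):
        raise ParameterError("scales must be non-empty and positive")
    data = image.data.astype(np.float32)
    channels: list[np.ndarray] = [data]
    for s in scales:
        smoothed = ndi.gaussian_filter(data, s, mode="reflect")
        grads = [ndi.gaussian_filter(data, s, order=tuple(int(i == ax) for i in range(3)),
                                     mode="reflect") for ax in range(3)]
        grad_mag = np.sqrt(sum(g ** 2 for g in grads))
        laplacian = ndi.gaussian_laplace(data, s, mode="reflect")
        eig_min, eig_max = _hessian_extreme_eigenvalues(data, s)
        channels += [smoothed, grad_mag.astype(np.float32), laplacian,
                     eig_min, eig_max]
    return np.stack([c.astype(np.float32) for c in channels], axis=0)


def _hessian_extreme_eigenvalues(data: np.ndarray, sigma: float):
    """Smallest and largest eigenvalues of the Gaussian-scale Hessian."""
    h = {}
    for a in range(3):
        for b in range(a, 3):
            order = [0, 0, 0]
            order[a] += 1
            order[b] += 1
            h[(a, b)] = ndi.gaussian_filter(data, sigma, order=tuple(order),
                                            mode="reflect")
    H = np.empty(data.shape + (3, 3), dtype=np.float32)
    for a in range(3):
        for b in range(3):
            H[..., a, b] = h[(min(a, b), max(a, b))]
    eig = np.linalg.eigvalsh(H)  # ascending
    return eig[..., 0], eig[..., 2]


def n_feature_channels(scales: Sequence[float]) -> int:
    return 1 + 5 * len(scales)


# --------------------------------------------------------------------------
# Classifiers
# --------------------------------------------------------------------------

@dataclass
class VoxelClassifier:
    """Bagged decision trees over the feature stack.

    The feature specification (the scales used) is frozen at fit time;
    prediction on a stack whose channel count disagrees is a contract error.
    """

    scales: tuple[float, ...]
    seed: int = 0
    n_estimators: int = 50
    model: RandomForestClassifier | None = field(default=None, repr=False)

    @property
    def n_channels(self) -> int:
        return n_feature_channels(self.scales)

    def fit(self, features: np.ndarray, labels: LabelSet) -> "VoxelClassifier":
        self._check_features(features)
        labels.validate_against(features.shape[1:])
        classes = labels.classes
        counts = np.bincount(classes, minlength=2)
        if counts.min() == 0:
            raise ParameterError("training labels must include both classes")
        if counts.min() < 10:
            raise ParameterError("need at least 10 labelled voxels per class")
        # balance by uniform subsampling of the majority class
        rng = np.random.default_rng(self.seed)
        keep = np.zeros(len(classes), dtype=bool)
        n_keep = counts.min()
        for c in (BACKGROUND, MITOCHONDRION):
            idx = np.flatnonzero(classes == c)
            keep[rng.choice(idx, n_keep, replace=False)] = True
        coords = labels.coords[keep]
        y = classes[keep]
        X = features[:, coords[:, 0], coords[:, 1], coords[:, 2]].T
        self.model = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.seed,
            n_jobs=1, min_samples_leaf=1)
        self.model.fit(X, y)
        return self

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Per-voxel foreground probability in [0, 1]."""
        self._check_features(features)
        if self.model is None:
            raise ContractError("classifier has not been fitted")
        shape = features.shape[1:]
        X = features.reshape(features.shape[0], -1).T
        proba = self.model.predict_proba(X)
        col = list(self.model.classes_).index(MITOCHONDRION) \
            if MITOCHONDRION in self.model.classes_ else None
        p = proba[:, col] if col is not None else np.zeros(X.shape[0])
        return p.reshape(shape)

    def _check_features(self, features: np.ndarray) -> None:
        if features.ndim != 4 or features.shape[0] != self.n_channels:
            raise ContractError(
                f"feature stack with {features.shape[0] if features.ndim == 4 else '?'} "
                f"channels does not match spec ({self.n_channels} expected)")


@dataclass
class ThresholdVoxelClassifier:
    """Fallback: threshold on raw intensity, placed midway between the
    class-conditional medians of the training labels."""

    scales: tuple[float, ...] = ()
    threshold_: float | None = None

    @property
    def n_channels(self) -> int:
        return n_feature_channels(self.scales) if self.scales else 1

    def fit(self, features: np.ndarray, labels: LabelSet) -> "ThresholdVoxelClassifier":
        coords = labels.coords
        vals = features[0, coords[:, 0], coords[:, 1], coords[:, 2]]
        fg = vals[labels.classes == MITOCHONDRION]
        bg = vals[labels.classes == BACKGROUND]
        if len(fg) == 0 or len(bg) == 0:
            raise ParameterError("training labels must include both classes")
        self.threshold_ = float((np.median(fg) + np.median(bg)) / 2.0)
        return self

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        if self.threshold_ is None:
            raise ContractError("classifier has not been fitted")
        return (features[0] >= self.threshold_).astype(float)


def train_voxel_classifier(features: np.ndarray, labels: LabelSet, seed: int,
                           scales: Sequence[float] = (1.0, 2.0),
                           family: str = "forest"):
    """Fit a voxel classifier; reproducible under ``seed``."""
    if family == "forest":
        clf = VoxelClassifier(scales=tuple(scales), seed=seed)
    elif family == "threshold":
        clf = ThresholdVoxelClassifier(scales=tuple(scales))
    else:
        raise ParameterError(f"unknown classifier family {family!r}")
    return clf.fit(features, labels)


def classify_stack(classifier, features: np.ndarray) -> np.ndarray:
    """Apply a fitted classifier to a whole feature stack."""
    return classifier.predict_proba(features)


# --------------------------------------------------------------------------
# Binarization and per-cell cropping
# --------------------------------------------------------------------------

def binarize(probabilities: np.ndarray, spacing, threshold: float = 0.5,
             min_component_size: int = 0) -> BinaryMask:
    """Threshold a probability grid into a binary mask.

    ``min_component_size`` optionally removes small 26-connected components
    (off by default); the cleanup is recorded in provenance.
    """
    if not (0.0 < threshold < 1.0):
        raise ParameterError("threshold must be in (0, 1)")
    mask = np.asarray(probabilities) >= threshold
    prov = [{"step": "binarize", "threshold": threshold}]
    if min_component_size > 0:
        mask = morphology.remove_small_objects(
            mask, max_size=min_component_size - 1, connectivity=3)
        prov.append({"step": "remove_small_components",
                     "min_size": min_component_size, "connectivity": 26})
    return BinaryMask(mask, spacing, provenance=prov)


@dataclass
class CellROI:
    """Per-cell region of interest: a polygonal footprint over a z range.

    Vertices are (y, x) pixel coordinates of the mask grid; the footprint
    applies to slices ``zmin..zmax`` inclusive.  Group labels use the closed
    vocabularies region ∈ {proximal, distal}, age ∈ {E8, E10, E14}.
    """

    cell_id: str
    vertices: np.ndarray   # (k, 2) float pixels (y, x)
    zmin: int
    zmax: int
    region: str | None = None
    age: str | None = None

    REGIONS = ("proximal", "distal")
    AGES = ("E8", "E10", "E14")

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if len(self.vertices) < 3:
            raise ParameterError("ROI polygon needs at least 3 vertices")
        if self.zmax < self.zmin:
            raise ParameterError("zmax must be ≥ zmin")
        if self.region is not None and self.region not in self.REGIONS:
            raise ParameterError(f"region must be one of {self.REGIONS}")
        if self.age is not None and self.age not in self.AGES:
            raise ParameterError(f"age must be one of {self.AGES}")

    @classmethod
    def box(cls, cell_id: str, zmin: int, zmax: int, ymin: float, ymax: float,
            xmin: float, xmax: float, **labels) -> "CellROI":
        verts = [(ymin, xmin), (ymin, xmax), (ymax, xmax), (ymax, xmin)]
        return cls(cell_id, np.asarray(verts), zmin, zmax, **labels)

    def footprint(self, shape_yx: tuple[int, int]) -> np.ndarray:
        from skimage.draw import polygon
        rr, cc = polygon(self.vertices[:, 0], self.vertices[:, 1], shape=shape_yx)
        fp = np.zeros(shape_yx, dtype=bool)
        fp[rr, cc] = True
        return fp


def crop_cell(mask: BinaryMask, roi: CellROI) -> BinaryMask:
    """Keep only the mask voxels inside the ROI (same grid geometry)."""
    nz, ny, nx = mask.shape
    if roi.zmin < 0 or roi.zmax >= nz:
        raise GeometryError(f"ROI {roi.cell_id}: z range outside the stack")
    if (np.any(roi.vertices < -0.5)
            or np.any(roi.vertices[:, 0] > ny - 0.5)
            or np.any(roi.vertices[:, 1] > nx - 0.5)):
        raise GeometryError(f"ROI {roi.cell_id}: polygon outside the image bounds")
    keep = np.zeros(mask.shape, dtype=bool)
    fp = roi.footprint((ny, nx))
    keep[roi.zmin:roi.zmax + 1] = fp
    return BinaryMask(mask.data & keep, mask.spacing,
                      provenance=[*mask.provenance,
                                  {"step": "crop_cell", "cell_id": roi.cell_id}])


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
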