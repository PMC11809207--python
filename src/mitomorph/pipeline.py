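"""Orchestration and file I/O: run the full analysis from a config over a
directory of stacks (real or synthetic) and emit tidy per-cell tables plus a
JSON run manifest.

Stacks are OME-TIFF with voxel-size metadata; ROIs are CSV vertex lists
(one row per vertex); all outputs are CSV + JSON so a run is archivable and
diffable.  Per-cell failures are isolated: one bad ROI is logged and skipped
rather than aborting the run.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import synth
from .core import GeometryError, ParameterError, VolumetricImage
from .preprocess import PreprocessConfig, preprocess_stack
from .segment import (CellROI, binarize, best_label_slice, classify_stack,
                      compute_feature_stack, crop_cell, labels_from_slice,
                      train_voxel_classifier)
from .skeleton import CellMorphometry, measure_mask
from .stats import (compare_groups, confidence_ellipse, ellipse_overlap,
                    feature_matrix, fit_pca)


# --------------------------------------------------------------------------
# Stack I/O
# --------------------------------------------------------------------------

def write_stack(image: VolumetricImage, path: str | Path) -> Path:
    """Write an OME-TIFF stack carrying the physical voxel size."""
    path = Path(path)
    sz, sy, sx = image.spacing
    tifffile.imwrite(
        path, image.data.astype(np.float32), ome=True,
        photometric="minisblack",
        metadata={"axes": "ZYX",
                  "PhysicalSizeZ": sz, "PhysicalSizeZUnit": "µm",
                  "PhysicalSizeY": sy, "PhysicalSizeYUnit": "µm",
                  "PhysicalSizeX": sx, "PhysicalSizeXUnit": "µm"})
    return path


def read_stack(path: str | Path,
               spacing_override: tuple[float, float, float] | None = None
               ) -> VolumetricImage:
    """Read a TIFF/OME-TIFF stack; voxel spacing comes from the metadata.

    A config-supplied ``spacing_override`` wins over file metadata (with a
    warning); a stack with no spacing metadata and no override is an error.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        spacing = _spacing_from_metadata(tf)
    if data.ndim != 3:
        raise GeometryError(f"{path.name}: expected a 3D stack, got ndim={data.ndim}")
    if spacing_override is not None:
        if spacing is not None and not np.allclose(spacing, spacing_override):
            warnings.warn(f"{path.name}: spacing override {spacing_override} "
                          f"replaces file metadata {spacing}")
        spacing = tuple(spacing_override)
    if spacing is None:
        raise ParameterError(
            f"{path.name}: no voxel-size metadata; supply a spacing override")
    return VolumetricImage(np.asarray(data, dtype=float), spacing)


def _spacing_from_metadata(tf: "tifffile.TiffFile"):
    if tf.ome_metadata:
        import re
        m = {}
        for ax in "ZYX":
            hit = re.search(rf'PhysicalSize{ax}="([\d.eE+-]+)"', tf.ome_metadata)
            if hit:
                m[ax] = float(hit.group(1))
        if set(m) == {"Z", "Y", "X"}:
            return (m["Z"], m["Y"], m["X"])
    ij = tf.imagej_metadata
    if ij and "spacing" in ij:
        tags = tf.pages[0].tags
        if "XResolution" in tags:
            xres = tags["XResolution"].value
            px = xres[1] / xres[0]
            return (float(ij["spacing"]), px, px)
    return None


# --------------------------------------------------------------------------
# ROI I/O (CSV vertex lists)
# --------------------------------------------------------------------------

ROI_COLUMNS = ["cell_id", "region", "age", "zmin", "zmax", "y", "x"]


def write_rois(rois: list[CellROI], path: str | Path) -> Path:
    rows = []
    for r in rois:
        for (y, x) in r.vertices:
            rows.append({"cell_id": r.cell_id, "region": r.region or "",
                         "age": r.age or "", "zmin": r.zmin, "zmax": r.zmax,
                         "y": y, "x": x})
    pd.DataFrame(rows, columns=ROI_COLUMNS).to_csv(path, index=False)
    return Path(path)


def read_rois(path: str | Path) -> list[CellROI]:
    """Parse the native CSV ROI dialect (one row per polygon vertex)."""
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{Path(path).name}: no ROIs")
        return []
    missing = set(ROI_COLUMNS) - set(df.columns)
    if missing:
        raise ParameterError(f"malformed ROI file: missing columns {sorted(missing)}")
    rois = []
    for cell_id, g in df.groupby("cell_id", sort=False):
        meta = g.iloc[0]
        if g["zmin"].nunique() > 1 or g["zmax"].nunique() > 1:
            raise ParameterError(f"ROI {cell_id!r}: inconsistent z range")
        region = meta["region"] if isinstance(meta["region"], str) and meta["region"] else None
        age = meta["age"] if isinstance(meta["age"], str) and meta["age"] else None
        rois.append(CellROI(str(cell_id), g[["y", "x"]].to_numpy(float),
                            int(meta["zmin"]), int(meta["zmax"]),
                            region=region, age=age))
    ids = [r.cell_id for r in rois]
    if len(ids) != len(set(ids)):
        raise ParameterError("duplicate cell ids in ROI file")
    return rois


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class SegmentationSettings:
    scales: tuple[float, ...] = (1.0, 2.0)
    classifier: str = "forest"         # forest | threshold
    labels_per_class: int = 200
    threshold: float = 0.5
    min_component_size: int = 0


@dataclass
class RegimeSpec:
    """Generator parameters for one synthetic condition ('regime')."""

    name: str
    n_cells: int = 15
    n_branches: int = 5
    length_range: tuple[float, float] = (2.5, 4.5)
    radius_range: tuple[float, float] = (0.25, 0.35)
    region: str | None = None
    age: str | None = None


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/out"
    # synthetic mode: list of regimes; file mode: stack+roi paths
    regimes: list[RegimeSpec] = field(default_factory=list)
    stack_path: str | None = None
    roi_path: str | None = None
    spacing_override: tuple[float, float, float] | None = None
    box: tuple[float, float, float] = (6.4, 6.4, 6.4)
    voxel_spacing: tuple[float, float, float] = (0.1, 0.1, 0.1)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segmentation: SegmentationSettings = field(default_factory=SegmentationSettings)
    pca_standardize: bool = True
    ellipse_level: float = 0.95

    def to_yaml(self, path: str | Path) -> Path:
        payload = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "preprocess" in payload:
            payload["preprocess"] = PreprocessConfig(**payload["preprocess"])
        if "segmentation" in payload:
            payload["segmentation"] = SegmentationSettings(**payload["segmentation"])
        if "regimes" in payload:
            regimes = []
            for r in payload["regimes"]:
                for key in ("length_range", "radius_range"):
                    if r.get(key) is not None:
                        r[key] = tuple(r[key])
                regimes.append(RegimeSpec(**r))
            payload["regimes"] = regimes
        if isinstance(payload.get("segmentation"), SegmentationSettings):
            payload["segmentation"].scales = tuple(payload["segmentation"].scales)
        for key in ("spacing_override", "box", "voxel_spacing"):
            if payload.get(key) is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class RunReport:
    morphometry: pd.DataFrame
    pca_scores: pd.DataFrame | None
    explained_variance: list[float] | None
    ellipses: dict
    ellipse_overlaps: dict[str, float]
    comparisons: list
    warnings: list[dict]

    def write(self, out_dir: str | Path, config: RunConfig) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.morphometry.to_csv(out / "morphometry.csv", index=False)
        if self.pca_scores is not None:
            self.pca_scores.to_csv(out / "pca_scores.csv", index=False)
        ell_rows = [{"group": g, "center_pc1": e.center[0], "center_pc2": e.center[1],
                     "semi_major": e.radii[0], "semi_minor": e.radii[1],
                     "angle_deg": e.angle_deg, "level": e.level, "kind": e.kind,
                     "n": e.n}
                    for g, e in self.ellipses.items()]
        pd.DataFrame(ell_rows).to_csv(out / "ellipses.csv", index=False)
        manifest = {
            "config": dataclasses.asdict(config),
            "explained_variance": self.explained_variance,
            "ellipse_overlaps": self.ellipse_overlaps,
            "warnings": self.warnings,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        config.to_yaml(out / "config.yaml")
        return out


# --------------------------------------------------------------------------
# Synthetic cell processing
# --------------------------------------------------------------------------

def process_rendered_cell(image: VolumetricImage, truth: synth.SyntheticTruth,
                          config: RunConfig, seed: int, cell_id: str,
                          region: str | None = None, age: str | None = None,
                          classifier=None) -> CellMorphometry:
    """Preprocess → segment → skeletonize → summarize one rendered cell.

    A fitted classifier can be shared across cells (train on one annotated
    slice, segment the rest); otherwise one is trained from this cell's
    truth slice.
    """
    pre = preprocess_stack(image, config.preprocess)
    seg = config.segmentation
    features = compute_feature_stack(pre, seg.scales)
    if classifier is None:
        z = best_label_slice(truth.true_mask)
        labels = labels_from_slice(truth.true_mask, z, seg.labels_per_class, seed,
                                   allow_fewer=True)
        classifier = train_voxel_classifier(features, labels, seed,
                                            scales=seg.scales,
                                            family=seg.classifier)
    proba = classify_stack(classifier, features)
    mask = binarize(proba, pre.spacing, seg.threshold, seg.min_component_size)
    return measure_mask(mask, cell_id=cell_id, region=region, age=age)


def run_pipeline(config: RunConfig) -> RunReport:
    """End-to-end run: synthesize (or load) stacks, measure every cell,
    fit the PCA, draw group ellipses and run the group comparison."""
    warn_log: list[dict] = []
    records: list[CellMorphometry] = []
    rng = np.random.default_rng(config.seed)

    if config.regimes:
        for regime in config.regimes:
            classifier = None
            for i in range(regime.n_cells):
                cell_id = f"{regime.name}_{i:03d}"
                cell_seed = int(rng.integers(2 ** 31 - 1))
                try:
                    image, truth = synth.make_network_cell(
                        cell_seed, regime.n_branches, regime.length_range,
                        regime.radius_range, config.box, config.voxel_spacing)
                    morph = process_rendered_cell(
                        image, truth, config, cell_seed, cell_id,
                        region=regime.region, age=regime.age,
                        classifier=classifier)
                    records.append(morph)
                except Exception as exc:  # isolate per-cell failures
                    warn_log.append({"cell_id": cell_id, "stage": "cell",
                                     "error": str(exc)})
    elif config.stack_path:
        image = read_stack(config.stack_path, config.spacing_override)
        rois = read_rois(config.roi_path) if config.roi_path else []
        pre = preprocess_stack(image, config.preprocess)
        seg = config.segmentation
        features = compute_feature_stack(pre, seg.scales)
        # without training labels the threshold fallback segments the stack
        from .segment import LabelSet, ThresholdVoxelClassifier
        mid = pre.shape[0] // 2
        plane = pre.data[mid]
        hi = np.argwhere(plane > np.quantile(plane, 0.99))
        lo = np.argwhere(plane < np.quantile(plane, 0.5))
        coords = np.concatenate([
            np.column_stack([np.full(len(hi), mid), hi]),
            np.column_stack([np.full(len(lo), mid), lo])])
        classes = np.concatenate([np.ones(len(hi), int), np.zeros(len(lo), int)])
        clf = ThresholdVoxelClassifier(scales=tuple(seg.scales)).fit(
            features, LabelSet(coords, classes, source_slice=mid))
        proba = classify_stack(clf, features)
        full_mask = binarize(proba, pre.spacing, seg.threshold,
                             seg.min_component_size)
        for roi in rois:
            try:
                crop = crop_cell(full_mask, roi)
                records.append(measure_mask(crop, cell_id=roi.cell_id,
                                            region=roi.region, age=roi.age))
            except Exception as exc:
                warn_log.append({"cell_id": roi.cell_id, "stage": "morphometry",
                                 "error": str(exc)})
    else:
        raise ParameterError("config needs either synthetic regimes or a stack path")

    usable = [r for r in records if not r.degenerate]
    for r in records:
        if r.degenerate:
            warn_log.append({"cell_id": r.cell_id, "stage": "morphometry",
                             "error": "degenerate (empty) skeleton"})
    morph_df = pd.DataFrame([r.to_dict() for r in records])

    pca_scores = None
    evr = None
    ellipses: dict = {}
    overlaps: dict[str, float] = {}
    comparisons: list = []
    if len(usable) >= 3:
        fm = feature_matrix(usable)
        groups = fm["region"].fillna("all") if fm["region"].notna().any() \
            else pd.Series(["all"] * len(fm))
        try:
            model = fit_pca(fm, standardize=config.pca_standardize)
            pca_scores = model.scores_
            evr = [float(v) for v in model.explained_variance_ratio_]
            ellipses = confidence_ellipse(model.scores_, groups,
                                          level=config.ellipse_level)
            names = list(ellipses)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    overlaps[f"{names[i]}|{names[j]}"] = ellipse_overlap(
                        ellipses[names[i]], ellipses[names[j]])
        except Exception as exc:
            warn_log.append({"cell_id": "-", "stage": "pca", "error": str(exc)})
        if groups.nunique() == 2:
            fm2 = fm.assign(group=groups.to_numpy())
            res = compare_groups(fm2, "avg_branch_length", ["group"], test="t_test")
            comparisons.append(res)

    return RunReport(morph_df, pca_scores, evr, ellipses, overlaps,
                     comparisons, warn_log)
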