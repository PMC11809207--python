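"""Statistical tail: standardized PCA of per-cell morphometrics with 95%
group ellipses and out-of-sample projection, plus the group-comparison tests
used for the figure panels (two-way ANOVA with Sidak contrasts, unpaired t,
Kruskal–Wallis).

The descriptor matrix holds the eight shape descriptors per cell (network
volume is reported separately and excluded from the PCA).  PC signs are
fixed by forcing each component's largest-magnitude loading positive, so
scores are comparable across runs and new samples (e.g. fibroblast
mitochondria) can be projected onto hair-cell axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from shapely import affinity
from shapely.geometry import Point

from .core import ContractError, ParameterError
from .skeleton import DESCRIPTOR_COLUMNS


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass
class PCAModel:
    columns: list[str]
    mean_: np.ndarray
    scale_: np.ndarray               # all ones when standardize was off
    components_: np.ndarray          # (k, p) orthonormal rows
    explained_variance_ratio_: np.ndarray
    scores_: pd.DataFrame            # training scores, PC1..PCk
    standardized: bool = True


def feature_matrix(cells: Sequence, columns: list[str] | None = None) -> pd.DataFrame:
    """Assemble the descriptor matrix (rows = cells) from CellMorphometry
    records or dicts; group labels ride along as 'region'/'age' columns."""
    columns = columns or DESCRIPTOR_COLUMNS
    rows = []
    for c in cells:
        d = c.to_dict() if hasattr(c, "to_dict") else dict(c)
        rows.append({"cell_id": d.get("cell_id"),
                     **{k: d[k] for k in columns},
                     "region": d.get("region"), "age": d.get("age")})
    df = pd.DataFrame(rows)
    if df[columns].isna().any().any():
        raise ParameterError("descriptor matrix contains missing values")
    return df


def fit_pca(features: pd.DataFrame, columns: list[str] | None = None,
            standardize: bool = True, n_components: int | None = None) -> PCAModel:
    """PCA of the descriptor matrix (z-scored by default).

    Components are ordered by decreasing explained variance; each
    component's sign is fixed so its largest-magnitude loading is positive.
    """
    columns = columns or [c for c in (DESCRIPTOR_COLUMNS if columns is None else columns)
                          if c in features.columns]
    X = features[columns].to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ParameterError("PCA needs at least 3 rows")
    mean = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0, ddof=1)
        if np.any(scale == 0):
            bad = [c for c, s in zip(columns, scale) if s == 0]
            raise ContractError(f"constant columns cannot be standardized: {bad}")
    else:
        scale = np.ones(p)
    Z = (X - mean) / scale
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    k = n_components or min(n - 1, p)
    comps = vt[:k]
    var = s ** 2 / (n - 1)
    total = (Z ** 2).sum() / (n - 1)
    evr = var[:k] / total
    # deterministic sign convention
    signs = np.sign(comps[np.arange(k), np.argmax(np.abs(comps), axis=1)])
    signs[signs == 0] = 1.0
    comps = comps * signs[:, None]
    scores = Z @ comps.T
    score_df = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(k)],
                            index=features.index)
    for lab in ("cell_id", "region", "age"):
        if lab in features.columns:
            score_df[lab] = features[lab].to_numpy()
    return PCAModel(list(columns), mean, scale, comps, evr, score_df,
                    standardized=standardize)


def project(model: PCAModel, new_features: pd.DataFrame) -> pd.DataFrame:
    """Project new samples onto a fitted PCA (same columns, stored scaling)."""
    missing = [c for c in model.columns if c not in new_features.columns]
    if missing:
        raise ContractError(f"missing descriptor columns: {missing}")
    X = new_features[model.columns].to_numpy(dtype=float)
    Z = (X - model.mean_) / model.scale_
    scores = Z @ model.components_.T
    out = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(len(model.components_))],
                       index=new_features.index)
    for lab in ("cell_id", "region", "age"):
        if lab in new_features.columns:
            out[lab] = new_features[lab].to_numpy()
    return out


# --------------------------------------------------------------------------
# Confidence ellipses
# --------------------------------------------------------------------------

@dataclass
class GroupEllipse:
    """2D confidence ellipse for one group in score space.

    ``kind='population'`` covers the stated fraction of a normal population
    (the default of the usual PCA-visualisation ellipses); ``kind='mean'``
    is the Hotelling confidence region for the group mean.
    """

    group: str
    center: np.ndarray        # (2,)
    radii: np.ndarray         # semi-axes (2,), descending
    angle_deg: float          # orientation of the major axis, from +x
    level: float = 0.95
    kind: str = "population"
    n: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.level < 1):
            raise ParameterError("level must be in (0, 1)")
        if np.any(self.radii <= 0):
            raise ParameterError("ellipse axes must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for (n, 2) points."""
        pts = np.asarray(points, dtype=float) - self.center
        t = np.deg2rad(self.angle_deg)
        rot = np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])
        q = pts @ rot.T
        return (q[:, 0] / self.radii[0]) ** 2 + (q[:, 1] / self.radii[1]) ** 2 <= 1.0

    def to_polygon(self, n: int = 256):
        circ = Point(0, 0).buffer(1.0, quad_segs=max(n // 4, 8))
        e = affinity.scale(circ, self.radii[0], self.radii[1])
        e = affinity.rotate(e, self.angle_deg)
        return affinity.translate(e, self.center[0], self.center[1])

    @property
    def area(self) -> float:
        return float(np.pi * self.radii[0] * self.radii[1])


def confidence_ellipse(scores: pd.DataFrame | np.ndarray,
                       groups: Sequence | None = None,
                       level: float = 0.95,
                       kind: str = "population",
                       components: tuple[str, str] = ("PC1", "PC2"),
                       ) -> dict[str, GroupEllipse]:
    """Per-group 95% ellipse from the 2D mean and covariance of the scores.

    Groups with fewer than 3 points are skipped with a warning.
    """
    if isinstance(scores, pd.DataFrame):
        pts = scores[list(components)].to_numpy(dtype=float)
    else:
        pts = np.asarray(scores, dtype=float)[:, :2]
    if groups is None:
        groups = ["all"] * len(pts)
    groups = np.asarray(groups)
    out: dict[str, GroupEllipse] = {}
    for g in pd.unique(groups):
        sel = pts[groups == g]
        n = len(sel)
        if n < 3:
            warnings.warn(f"group {g!r} has {n} < 3 points; ellipse skipped")
            continue
        center = sel.mean(axis=0)
        cov = np.cov(sel.T)
        if kind == "population":
            scale2 = sps.chi2.ppf(level, df=2)
        elif kind == "mean":
            scale2 = (2.0 * (n - 1) / (n * (n - 2))) * sps.f.ppf(level, 2, n - 2)
        else:
            raise ParameterError("kind must be 'population' or 'mean'")
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        radii = np.sqrt(np.clip(evals, 1e-300, None) * scale2)
        angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
        out[str(g)] = GroupEllipse(str(g), center, radii, angle, level, kind, n)
    return out


def ellipse_overlap(a: GroupEllipse, b: GroupEllipse) -> float:
    """Overlap fraction: intersection area / area of the smaller ellipse."""
    inter = a.to_polygon().intersection(b.to_polygon()).area
    return float(inter / min(a.area, b.area))


# --------------------------------------------------------------------------
# Group comparisons
# --------------------------------------------------------------------------

def sidak_adjust(p: float, m: int) -> float:
    """Sidak multiple-comparison adjustment: 1 − (1 − p)^m."""
    if m < 1:
        raise ParameterError("m must be ≥ 1")
    return float(1.0 - (1.0 - p) ** m)


@dataclass
class Contrast:
    name: str
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass
class ComparisonResult:
    test: str
    factors: list[str]
    statistic: float
    df: tuple
    p_value: float
    contrasts: list[Contrast] = field(default_factory=list)


def compare_groups(data: pd.DataFrame, value: str, factors: Sequence[str],
                   test: str = "two_way_anova") -> ComparisonResult:
    """Group comparison with Sidak-adjusted post-hoc contrasts.

    test ∈ {two_way_anova, t_test, kruskal}.  Two-way ANOVA uses Type II
    sums of squares (statsmodels OLS); post-hoc contrasts compare the levels
    of the first factor within each level of the second (unpaired t),
    Sidak-adjusted over the number of contrasts.  Kruskal–Wallis post-hocs
    are pairwise Mann–Whitney, Sidak-adjusted.
    """
    factors = list(factors)
    for f in factors:
        if data[f].isna().any():
            raise ParameterError(f"factor {f!r} has missing levels")

    if test == "t_test":
        (f,) = factors
        levels = list(pd.unique(data[f]))
        if len(levels) != 2:
            raise ParameterError("t_test needs exactly 2 levels")
        a = data.loc[data[f] == levels[0], value]
        b = data.loc[data[f] == levels[1], value]
        res = sps.ttest_ind(a, b)
        dfree = len(a) + len(b) - 2
        return ComparisonResult("t_test", factors, float(res.statistic),
                                (dfree,), float(res.pvalue))

    if test == "kruskal":
        (f,) = factors
        levels = list(pd.unique(data[f]))
        samples = [data.loc[data[f] == lv, value] for lv in levels]
        if any(len(s) == 0 for s in samples):
            raise ParameterError("empty group in the design")
        stat, p = sps.kruskal(*samples)
        pairs = [(i, j) for i in range(len(levels)) for j in range(i + 1, len(levels))]
        contrasts = []
        for i, j in pairs:
            u, pr = sps.mannwhitneyu(samples[i], samples[j], alternative="two-sided")
            contrasts.append(Contrast(f"{levels[i]} vs {levels[j]}", float(u),
                                      float(pr), sidak_adjust(float(pr), len(pairs))))
        return ComparisonResult("kruskal", factors, float(stat),
                                (len(levels) - 1,), float(p), contrasts)

    if test == "two_way_anova":
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        f1, f2 = factors
        counts = data.groupby([f1, f2], observed=True)[value].count()
        if (counts == 0).any() or len(counts) < \
                data[f1].nunique() * data[f2].nunique():
            raise ParameterError("empty cell in the two-way design")
        d = data.rename(columns={value: "_y", f1: "_f1", f2: "_f2"})
        model = smf.ols("_y ~ C(_f1) * C(_f2)", data=d).fit()
        table = sm.stats.anova_lm(model, typ=2)
        interaction = [ix for ix in table.index if ":" in ix][0]
        main = table.index[0]
        # contrasts: levels of f1 within each level of f2
        lv1 = list(pd.unique(data[f1]))
        lv2 = list(pd.unique(data[f2]))
        contrasts = []
        if len(lv1) == 2:
            for lv in lv2:
                a = data.loc[(data[f1] == lv1[0]) & (data[f2] == lv), value]
                b = data.loc[(data[f1] == lv1[1]) & (data[f2] == lv), value]
                res = sps.ttest_ind(a, b)
                contrasts.append(Contrast(f"{lv1[0]} vs {lv1[1]} @ {lv}",
                                          float(res.statistic), float(res.pvalue),
                                          sidak_adjust(float(res.pvalue), len(lv2))))
        return ComparisonResult(
            "two_way_anova", factors,
            float(table.loc[main, "F"]),
            (float(table.loc[main, "df"]), float(table.loc["Residual", "df"])),
            float(table.loc[main, "PR(>F)"]),
            contrasts)

    raise ParameterError(f"unknown test {test!r}")
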