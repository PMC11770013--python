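"""From ring-histogram features to a quantitative pigmentation-pattern trait.

PCA is run on the pooled fruit-level 30-bin feature matrix (mean-centered,
unscaled — all features are frequencies on a common scale).  Components are
named by their Pearson correlation with two color descriptors: the axis
most correlated with mean a* is the *intensity* axis (how red the flesh
is), and among the remaining components the one most correlated with the
standard deviation of a* is the *pattern* axis (how heterogeneously the
red is distributed).  The pattern axis is oriented so that higher scores
mean higher a* dispersion.  Fruit scores are then averaged per
genotype x year to produce phenotypes, and genotypes can be filtered on
overall redness and marker presence before genetic analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .color_features import feature_names

__all__ = [
    "TraitScores",
    "AxesNotSeparableError",
    "fit_pca",
    "correlate_components",
    "identify_pattern_axis",
    "aggregate_genotype_year",
    "filter_genotypes",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = feature_names()
DESCRIPTOR_COLUMNS = ["mean_a", "sd_a"]
ID_COLUMNS = ["image_id", "genotype", "year", "fruit"]


class AxesNotSeparableError(ValueError):
    """Intensity and pattern resolve to the same component."""


@dataclass
class TraitScores:
    """PCA decomposition of the feature matrix plus axis identification.

    loadings : DataFrame (n_features x K), columns pc1..pcK
    fruit_scores : DataFrame with id/metadata columns plus pc1..pcK
    explained_variance : per-component variance (descending)
    corr_table : DataFrame (K x 2), Pearson r of each component's scores
        with mean_a and sd_a (NaN where a descriptor has zero variance)
    """

    loadings: pd.DataFrame
    explained_variance: np.ndarray
    fruit_scores: pd.DataFrame
    corr_table: pd.DataFrame | None = None
    pattern_axis_index: int | None = None
    intensity_axis_index: int | None = None
    warnings: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.explained_variance / self.explained_variance.sum()

    def component_name(self, index: int) -> str:
        return self.loadings.columns[index]


def fit_pca(features: pd.DataFrame, k: int = 10) -> TraitScores:
    """PCA on the mean-centered (unscaled) 30-bin feature columns.

    Components are ordered by decreasing explained variance, with a
    deterministic sign convention: the largest-magnitude loading of each
    component is positive.  If the matrix has rank < k, only the rank
    components are returned and a warning is recorded.
    """
    feat_cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    if len(feat_cols) != len(FEATURE_COLUMNS):
        missing = set(FEATURE_COLUMNS) - set(feat_cols)
        raise ValueError(f"feature matrix is missing columns: {sorted(missing)[:3]}...")
    x = features[feat_cols].to_numpy(dtype=np.float64)
    if np.isnan(x).any():
        raise ValueError("feature matrix contains missing values")
    n = x.shape[0]
    if n < 3:
        raise ValueError("PCA requires at least 3 fruit rows")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    tol = s.max() * max(xc.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    warnings = []
    k_eff = min(k, rank)
    if k_eff < k:
        warnings.append(f"rank-deficient features: returning {k_eff} of {k} requested components")
    u, s, vt = u[:, :k_eff], s[:k_eff], vt[:k_eff]
    # sign convention: largest |loading| positive per component
    flip = np.sign(vt[np.arange(k_eff), np.abs(vt).argmax(axis=1)])
    vt = vt * flip[:, None]
    scores = u * s * flip[None, :]
    pc_names = [f"pc{i + 1}" for i in range(k_eff)]
    loadings = pd.DataFrame(vt.T, index=feat_cols, columns=pc_names)
    keep = [c for c in ID_COLUMNS + DESCRIPTOR_COLUMNS if c in features.columns]
    fruit_scores = features[keep].copy().reset_index(drop=True)
    fruit_scores[pc_names] = scores
    return TraitScores(
        loadings=loadings,
        explained_variance=s**2 / (n - 1),
        fruit_scores=fruit_scores,
        warnings=warnings,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        return np.nan
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def correlate_components(scores: TraitScores, features: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each component's fruit scores with mean_a / sd_a.

    A zero-variance descriptor yields NaN (undefined), not 0.
    """
    if len(features) != len(scores.fruit_scores):
        raise ValueError("features and fruit scores are not row-aligned")
    pc_names = list(scores.loadings.columns)
    rows = {}
    for pc in pc_names:
        rows[pc] = [
            _pearson(scores.fruit_scores[pc], features[d]) for d in DESCRIPTOR_COLUMNS
        ]
    corr = pd.DataFrame.from_dict(rows, orient="index", columns=DESCRIPTOR_COLUMNS)
    scores.corr_table = corr
    return corr


def identify_pattern_axis(scores: TraitScores) -> tuple[int, int]:
    """Name the intensity and pattern axes from the correlation table.

    intensity = argmax |corr with mean_a|; pattern = argmax |corr with
    sd_a| over the remaining components.  The pattern component (scores
    and loadings) is sign-flipped if needed so its correlation with sd_a
    is positive.  Returns (pattern_axis_index, intensity_axis_index).
    """
    corr = scores.corr_table
    if corr is None:
        raise ValueError("run correlate_components first")
    if len(corr) < 2:
        raise AxesNotSeparableError("axes not separable: fewer than 2 components")
    abs_mean = corr["mean_a"].abs().to_numpy()
    abs_sd = corr["sd_a"].abs().to_numpy()
    if np.isnan(abs_mean).all() or np.isnan(abs_sd).all():
        raise AxesNotSeparableError("axes not separable: descriptor correlations undefined")
    intensity = int(np.nanargmax(abs_mean))
    abs_sd = abs_sd.copy()
    abs_sd[intensity] = -np.inf
    pattern = int(np.nanargmax(abs_sd))
    if pattern == intensity:
        raise AxesNotSeparableError(
            "axes not separable: intensity and pattern resolve to the same "
            "component; inspect the correlation table and the population design"
        )
    pc = scores.loadings.columns[pattern]
    if corr.iloc[pattern]["sd_a"] < 0:
        scores.fruit_scores[pc] = -scores.fruit_scores[pc]
        scores.loadings[pc] = -scores.loadings[pc]
        scores.corr_table.loc[pc] = -scores.corr_table.loc[pc]
    scores.pattern_axis_index = pattern
    scores.intensity_axis_index = intensity
    return pattern, intensity


def aggregate_genotype_year(fruit_scores: pd.DataFrame) -> pd.DataFrame:
    """Mean of fruit coordinates per (genotype, year).

    Averages every pc* column plus mean_a / sd_a where present, and
    records the number of fruits contributing to each cell.
    """
    for col in ("genotype", "year"):
        if col not in fruit_scores.columns:
            raise ValueError(f"fruit scores lack the {col!r} column")
    value_cols = [
        c
        for c in fruit_scores.columns
        if c.startswith("pc") or c in DESCRIPTOR_COLUMNS
    ]
    grouped = fruit_scores.groupby(["genotype", "year"], sort=True)
    out = grouped[value_cols].mean()
    out["n_fruits"] = grouped.size()
    return out.reset_index()


def filter_genotypes(
    pheno: pd.DataFrame,
    marker_presence: pd.DataFrame,
    mean_a_threshold: float = 10.0,
) -> tuple[set, pd.DataFrame]:
    """Retain genotypes with mean a* strictly above threshold AND marker present.

    ``pheno`` must carry genotype and mean_a columns at fruit or cell
    level; the per-genotype mean a* is the mean over all its rows.
    ``marker_presence`` has columns genotype, present (boolean).  Returns
    the retained genotype set and an audit table giving the reason for
    every exclusion (genotypes absent from the marker table are excluded
    with reason "no marker data").
    """
    if "mean_a" not in pheno.columns or "genotype" not in pheno.columns:
        raise ValueError("phenotype table needs 'genotype' and 'mean_a' columns")
    mean_a = pheno.groupby("genotype")["mean_a"].mean()
    presence = marker_presence.set_index("genotype")["present"]
    rows = []
    retained = set()
    for geno, ma in mean_a.items():
        if geno not in presence.index:
            rows.append((geno, ma, None, False, "no marker data"))
            continue
        pres = bool(presence.loc[geno])
        if not ma > mean_a_threshold:
            reason = f"mean_a {ma:.3g} <= threshold {mean_a_threshold:g}"
            rows.append((geno, ma, pres, False, reason))
        elif not pres:
            rows.append((geno, ma, pres, False, "marker allele absent"))
        else:
            retained.add(geno)
            rows.append((geno, ma, pres, True, ""))
    audit = pd.DataFrame(
        rows, columns=["genotype", "mean_a", "marker_present", "retained", "reason"]
    )
    return retained, audit
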