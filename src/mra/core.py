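"""Isosize, shape coordinates, shape PCA, allometry, and ratio spectra.

Multivariate ratio analysis decomposes log-measurements into an isometric
size axis — *isosize*, the natural log of the geometric mean of all of a
specimen's measurements — and *shape coordinates*, the log-measurements
centred by isosize.  A shape coordinate is a log-ratio against the geometric
mean, so a PCA of the shape coordinates ("shape PCA") is a PCA in the space
of all body ratios.  Allometry is estimated as the regression of each shape
coordinate on isosize.  A *ratio spectrum* orders the variables by their
coefficient on one axis (a shape PC, or the allometry vector); ratios formed
from variables at the opposite ends of the spectrum dominate that axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .measurement_data import MeasurementTable

__all__ = [
    "ShapeTable",
    "ShapePCAResult",
    "RatioSpectrum",
    "shape_decompose",
    "shape_pca",
    "variance_explained",
    "allometry_coefficients",
    "pca_ratio_spectrum",
    "allometry_ratio_spectrum",
    "size_shape_scatter",
]


@dataclass
class ShapeTable:
    """Per-specimen isosize and shape coordinates.

    ``shape`` rows sum to zero: each row is the specimen's log-measurement
    vector centred by its own mean (the isosize).
    """

    isosize: pd.Series
    shape: pd.DataFrame
    group: pd.Series
    strain: pd.Series

    @property
    def columns(self) -> list[str]:
        return list(self.shape.columns)

    @property
    def n_specimens(self) -> int:
        return len(self.shape)


@dataclass
class ShapePCAResult:
    """Eigendecomposition of the shape-coordinate covariance.

    ``loadings`` is a (components × variables) DataFrame of unit-norm
    vectors, each orthogonal to the all-ones vector (shape space has
    dimension p − 1, so p − 1 components are returned).  Signs are fixed so
    each loading's largest-magnitude entry is positive.
    """

    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_fraction: np.ndarray


@dataclass
class RatioSpectrum:
    """Variables ordered by their coefficient on one axis, with bootstrap CIs."""

    axis_tag: str
    coefficients: pd.Series
    ordering: list[str]
    ci_low: pd.Series
    ci_high: pd.Series
    n_boot: int
    level: float
    n_skipped: int = 0
    stratified: bool = True

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "coefficient": self.coefficients,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }).loc[self.ordering]
        df.index.name = "character"
        return df


def shape_decompose(table: MeasurementTable) -> ShapeTable:
    """Split log-measurements into isosize and shape coordinates.

    isosize_i = (1/p) Σ_k ln x_ik (the log geometric mean); shape
    z_ik = ln x_ik − isosize_i.  Requires a complete table (impute or drop
    specimens first) with strictly positive values.
    """
    vals = table.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("table has missing cells; impute_missing() or drop "
                         "incomplete specimens before shape analysis")
    if not np.all(vals > 0):
        raise ValueError("measurements must be strictly positive")
    logs = np.log(vals)
    iso = logs.mean(axis=1)
    shape = logs - iso[:, None]
    return ShapeTable(
        isosize=pd.Series(iso, index=table.values.index, name="isosize"),
        shape=pd.DataFrame(shape, index=table.values.index,
                           columns=table.columns),
        group=table.group.copy(),
        strain=table.strain.copy(),
    )


def _shape_eig(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the covariance of shape rows, sorted descending,
    keeping the p−1 components orthogonal to the all-ones direction."""
    p = Z.shape[1]
    C = np.cov(Z, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # drop the component aligned with the all-ones vector (exact null space
    # of the shape covariance); it is the last one up to numerical noise
    ones = np.ones(p) / math.sqrt(p)
    align = np.abs(evecs.T @ ones)
    drop = int(np.argmax(align))
    keep = [j for j in range(p) if j != drop]
    evals = np.clip(evals[keep], 0.0, None)
    evecs = evecs[:, keep]
    # remove any numerical leakage along ones and renormalize
    evecs = evecs - ones[:, None] * (ones @ evecs)
    evecs /= np.linalg.norm(evecs, axis=0)
    # sign convention: largest-magnitude entry positive
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])])
    flip[flip == 0] = 1.0
    evecs *= flip
    return evals, evecs


def shape_pca(shape: ShapeTable) -> ShapePCAResult:
    """PCA of the shape coordinates (covariance PCA, specimens as rows)."""
    if shape.n_specimens < 3:
        raise ValueError("shape PCA needs at least 3 specimens")
    Z = shape.shape.to_numpy(dtype=float)
    if Z.shape[1] < 2:
        raise ValueError("shape PCA needs at least 2 variables")
    evals, evecs = _shape_eig(Z)
    k = evecs.shape[1]
    comp_names = [f"PC{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(evecs.T, index=comp_names, columns=shape.columns)
    scores = pd.DataFrame(Z @ evecs, index=shape.shape.index,
                          columns=comp_names)
    total = evals.sum()
    vf = evals / total if total > 0 else np.zeros_like(evals)
    return ShapePCAResult(evals, loadings, scores, vf)


def variance_explained(result: ShapePCAResult, k: int) -> float:
    """Cumulative variance fraction of the first *k* shape PCs."""
    if not 1 <= k <= len(result.variance_fraction):
        raise ValueError(f"k={k} out of range 1..{len(result.variance_fraction)}")
    return float(result.variance_fraction[:k].sum())


def allometry_coefficients(shape: ShapeTable) -> pd.Series:
    """Slopes of each shape coordinate on isosize.

    b_k = cov(z_·k, isosize) / var(isosize).  The coefficients sum to zero
    because the shape rows do.  A positive b_k means the variable grows
    faster than isometrically with size.
    """
    iso = shape.isosize.to_numpy(dtype=float)
    if np.var(iso) == 0:
        raise ValueError("isosize has zero variance; allometry undefined")
    Z = shape.shape.to_numpy(dtype=float)
    iso_c = iso - iso.mean()
    b = (Z - Z.mean(axis=0)).T @ iso_c / (iso_c @ iso_c)
    return pd.Series(b, index=shape.columns, name="allometry")


def _stratified_resample(rng: np.random.Generator, groups: np.ndarray) -> np.ndarray:
    """Indices of a bootstrap resample, stratified by group label."""
    idx = np.arange(len(groups))
    out = []
    for g in pd.unique(groups):
        members = idx[groups == g]
        out.append(rng.choice(members, size=len(members), replace=True))
    return np.concatenate(out)


def _bootstrap_spectrum(shape: ShapeTable, point: np.ndarray,
                        stat, n_boot: int, level: float,
                        seed: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Bootstrap CIs for a per-variable statistic, resampling specimens with
    replacement stratified by group, sign-aligned to the point estimate."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    groups = shape.group.to_numpy()
    Z = shape.shape.to_numpy(dtype=float)
    iso = shape.isosize.to_numpy(dtype=float)
    reps = np.empty((n_boot, Z.shape[1]))
    skipped = 0
    b = 0
    while b < n_boot:
        idx = _stratified_resample(rng, groups)
        Zb, isob = Z[idx], iso[idx]
        # degenerate resample: a constant shape column or constant isosize
        if np.any(Zb.std(axis=0) == 0):
            skipped += 1
            continue
        try:
            coef = stat(Zb, isob)
        except (ValueError, np.linalg.LinAlgError):
            skipped += 1
            continue
        if coef @ point < 0:
            coef = -coef
        reps[b] = coef
        b += 1
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(reps, alpha, axis=0)
    hi = np.quantile(reps, 1.0 - alpha, axis=0)
    return lo, hi, skipped


def pca_ratio_spectrum(result: ShapePCAResult, pc: int, shape: ShapeTable,
                       n_boot: int = 1000, level: float = 0.68,
                       seed: int = 0) -> RatioSpectrum:
    """PCA ratio spectrum: the *pc*-th loading with bootstrap CIs.

    *pc* is 1-based.  Bootstrap resamples specimens with replacement
    (stratified by group), recomputes the loading, aligns its sign with the
    point estimate, and takes the central *level* interval per variable.
    """
    if not 1 <= pc <= len(result.eigenvalues):
        raise ValueError(f"pc={pc} out of range")
    point = result.loadings.iloc[pc - 1].to_numpy()

    def stat(Zb: np.ndarray, isob: np.ndarray) -> np.ndarray:
        _, evecs = _shape_eig(Zb)
        return evecs[:, pc - 1]

    lo, hi, skipped = _bootstrap_spectrum(shape, point, stat, n_boot, level, seed)
    coeffs = pd.Series(point, index=shape.columns)
    ordering = list(coeffs.sort_values().index)
    return RatioSpectrum(f"PC{pc}", coeffs, ordering,
                         pd.Series(lo, index=shape.columns),
                         pd.Series(hi, index=shape.columns),
                         n_boot, level, skipped)


def allometry_ratio_spectrum(shape: ShapeTable, n_boot: int = 1000,
                             level: float = 0.68, seed: int = 0) -> RatioSpectrum:
    """Allometry ratio spectrum: allometric coefficients with bootstrap CIs."""
    point = allometry_coefficients(shape).to_numpy()

    def stat(Zb: np.ndarray, isob: np.ndarray) -> np.ndarray:
        isoc = isob - isob.mean()
        denom = isoc @ isoc
        if denom == 0:
            raise ValueError("zero isosize variance in resample")
        return (Zb - Zb.mean(axis=0)).T @ isoc / denom

    lo, hi, skipped = _bootstrap_spectrum(shape, point, stat, n_boot, level, seed)
    coeffs = pd.Series(point, index=shape.columns)
    ordering = list(coeffs.sort_values().index)
    return RatioSpectrum("allometry", coeffs, ordering,
                         pd.Series(lo, index=shape.columns),
                         pd.Series(hi, index=shape.columns),
                         n_boot, level, skipped)


def size_shape_scatter(result: ShapePCAResult, shape: ShapeTable,
                       pc: int) -> tuple[pd.DataFrame, float | None]:
    """Paired (isosize, shape-PC score) values and their Pearson r.

    The correlation of size with shape measures the amount of allometry.
    Returns ``(pairs, r)``; *r* is None when either variable is constant
    (correlation undefined).
    """
    if not 1 <= pc <= len(result.eigenvalues):
        raise ValueError(f"pc={pc} out of range")
    score = result.scores.iloc[:, pc - 1]
    pairs = pd.DataFrame({"isosize": shape.isosize, f"PC{pc}": score,
                          "group": shape.group})
    iso = shape.isosize.to_numpy(dtype=float)
    sc = score.to_numpy(dtype=float)
    if np.std(iso) == 0 or np.std(sc) == 0:
        return pairs, None
    r = float(np.corrcoef(iso, sc)[0, 1])
    return pairs, r
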