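"""ROI summarization and scalar statistics.

Sphere/labeled ROI handling, ROI mean extraction, Bayesian Pearson
correlations (stretched-beta prior, numerical integration of the exact
sampling density of r), ANCOVA with a Levene homogeneity check, and the
basic two-sample statistics (t, chi-square, Mann-Whitney z).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import integrate, special, stats

__all__ = [
    "RoiSet",
    "sphere_roi",
    "extract_roi_mean",
    "BayesCorrelationResult",
    "bayes_pearson",
    "AncovaResult",
    "ancova_group_effect",
    "two_sample_t",
    "chi2_test",
    "mann_whitney_z",
]


# ---------------------------------------------------------------------------
# ROIs


@dataclass
class RoiSet:
    """Named 3D boolean masks on one grid.

    Component masks may overlap composite masks (e.g. a composite-DMN
    union), so overlap is allowed across entries.
    """

    masks: dict[str, np.ndarray]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all ROI masks must share one grid")
        for name, m in self.masks.items():
            if not np.asarray(m).any():
                raise ValueError(f"ROI {name!r} is empty")
            self.masks[name] = np.asarray(m, dtype=bool)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    def save(self, nifti_path: str, labels_path: str) -> None:
        """Write as a labeled NIfTI + JSON label map.

        Overlapping voxels get the label of the last ROI listed, so a
        composite (e.g. a DMN union) is stored as the list of label values
        whose union reconstructs it.  Raises if some mask cannot be
        expressed that way.
        """
        labels = np.zeros(next(iter(self.masks.values())).shape, dtype=np.int16)
        for i, m in enumerate(self.masks.values(), start=1):
            labels[m] = i
        mapping: dict[str, list[int]] = {}
        for name, m in self.masks.items():
            inside = sorted(int(v) for v in np.unique(labels[m]) if v > 0)
            if not np.array_equal(np.isin(labels, inside), m):
                raise ValueError(
                    f"ROI {name!r} is not representable in a single label "
                    "volume (partial overlap with another ROI)"
                )
            mapping[name] = inside
        nib.save(nib.Nifti1Image(labels, self.affine), nifti_path)
        with open(labels_path, "w") as fh:
            json.dump(mapping, fh, indent=2)

    @classmethod
    def load(cls, nifti_path: str, labels_path: str) -> "RoiSet":
        img = nib.load(nifti_path)
        labels = np.asarray(img.dataobj).astype(int)
        with open(labels_path) as fh:
            mapping = json.load(fh)
        masks = {name: np.isin(labels, vals) for name, vals in mapping.items()}
        return cls(masks, img.affine)


def sphere_roi(
    center_mm,
    radius_mm: float,
    shape: tuple[int, int, int],
    affine: np.ndarray,
) -> np.ndarray:
    """Boolean mask of voxels whose center lies within ``radius_mm`` of
    ``center_mm`` (center-to-center mm distance, inclusive)."""
    if radius_mm < 0:
        raise ValueError(f"radius must be >= 0, got {radius_mm}")
    center_mm = np.asarray(center_mm, dtype=float)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    mm = vox @ np.asarray(affine, dtype=float).T
    d = np.linalg.norm(mm[..., :3] - center_mm, axis=-1)
    mask = d <= radius_mm + 1e-9
    if not mask.any():
        raise ValueError("sphere center lies outside the grid")
    return mask


def extract_roi_mean(map3: np.ndarray, roi: np.ndarray) -> float:
    """Arithmetic mean of the finite map values inside the ROI."""
    map3 = np.asarray(map3, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if map3.shape != roi.shape:
        raise ValueError("map and ROI shapes differ")
    vals = map3[roi]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("ROI contains no finite voxels")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# Bayesian Pearson correlation


def _rho_kernel(rho: float, r: float, n: int) -> float:
    """Likelihood of rho given the observed sample correlation r, i.e. the
    exact sampling density of r with all rho-independent factors dropped
    (they cancel in the Bayes factor, which also keeps r = +/-1 finite to
    work with)."""
    return float(
        (1 - rho**2) ** ((n - 1) / 2)
        / (1 - rho * r) ** (n - 1.5)
        * special.hyp2f1(0.5, 0.5, (2 * n - 1) / 2, (rho * r + 1) / 2)
    )


@dataclass
class BayesCorrelationResult:
    r: float
    n: int
    bf10: float
    bf01: float

    def __post_init__(self) -> None:
        if not -1 <= self.r <= 1:
            raise ValueError("r out of [-1, 1]")
        if self.bf10 <= 0:
            raise ValueError("bf10 must be positive")


def bayes_pearson(x, y, kappa: float = 1.0) -> BayesCorrelationResult:
    """Bayesian Pearson correlation with a two-sided stretched-beta prior.

    The prior on rho is Beta(1/kappa, 1/kappa) stretched to (-1, 1); with
    the default width kappa = 1 it is uniform.  BF10 is computed by
    adaptive quadrature of the exact sampling density of r over the prior;
    BF01 = 1 / BF10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs contain non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])

    if abs(r) >= 1.0 - 1e-12:
        # likelihood of |rho| -> 1 is unbounded: overwhelming evidence for H1
        return BayesCorrelationResult(r=r, n=n, bf10=np.inf, bf01=0.0)

    a = 1.0 / kappa

    def integrand(rho: float) -> float:
        prior = stats.beta.pdf((rho + 1) / 2, a, a) / 2
        return prior * _rho_kernel(rho, r, n)

    num, _ = integrate.quad(integrand, -1, 1)
    bf10 = num / _rho_kernel(0.0, r, n)
    return BayesCorrelationResult(r=r, n=n, bf10=bf10, bf01=1.0 / bf10)


# ---------------------------------------------------------------------------
# ANCOVA and basic tests


@dataclass
class AncovaResult:
    f: float
    df1: int
    df2: int
    p: float
    levene_stat: float
    levene_p: float


def ancova_group_effect(y, group, covariates=None) -> AncovaResult:
    """Partial (type-III) F test for a two-level group factor adjusting for
    covariates, with Levene's test (mean-centered) on the residuals.

    ``covariates`` is an (n, k) array or None.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {len(levels)}")
    counts = [(group == lv).sum() for lv in levels]
    if min(counts) < 2:
        raise ValueError("need at least 2 observations per group")
    g = (group == levels[1]).astype(float)
    n = y.size
    cols = [np.ones(n), g]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        cols.extend(covariates.T)
    x_full = np.column_stack(cols)
    p = x_full.shape[1]
    if np.linalg.matrix_rank(x_full) < p:
        raise ValueError("collinear covariates in the ANCOVA design")
    x_red = np.delete(x_full, 1, axis=1)

    def rss(xm):
        beta, *_ = np.linalg.lstsq(xm, y, rcond=None)
        e = y - xm @ beta
        return float(e @ e), y - xm @ beta

    rss_full, resid = rss(x_full)
    rss_red, _ = rss(x_red)
    df1 = 1
    df2 = n - p
    f = (rss_red - rss_full) / df1 / (rss_full / df2)
    pval = float(stats.f.sf(f, df1, df2))
    lev_stat, lev_p = stats.levene(
        resid[group == levels[0]], resid[group == levels[1]], center="mean"
    )
    return AncovaResult(f=float(f), df1=df1, df2=df2, p=pval,
                        levene_stat=float(lev_stat), levene_p=float(lev_p))


@dataclass
class TestResult:
    statistic: float
    p: float
    df: float | None = None
    kind: str = ""


def two_sample_t(x, y, equal_var: bool = True) -> TestResult:
    """Student (default) or Welch two-sample t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per sample")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    kind = "student_t" if equal_var else "welch_t"
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue),
                      df=float(res.df), kind=kind)


def chi2_test(table) -> TestResult:
    """Pearson chi-square on a contingency table (no Yates correction)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("contingency table must be a non-negative 2D array")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate contingency table (empty row or column)")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(statistic=float(chi2), p=float(p), df=float(dof), kind="chi2")


def mann_whitney_z(x, y) -> TestResult:
    """Mann-Whitney U with tie-corrected normal approximation.

    Reports z = (U_x - m*n/2) / sigma_ties (no continuity correction) and
    the two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u_x = ranks[:m].sum() - m * (m + 1) / 2
    mu = m * n / 2
    nn = m + n
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (nn * (nn - 1))
    sigma2 = m * n / 12 * ((nn + 1) - tie_term)
    if sigma2 <= 0:
        raise ValueError("all values tied; z undefined")
    z = (u_x - mu) / np.sqrt(sigma2)
    p = 2 * stats.norm.sf(abs(z))
    return TestResult(statistic=float(z), p=float(p), kind="mann_whitney_z")
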