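"""Voxel-wise multi-modal group GLM.

The group design combines categorical cells (age group x scanner),
group-wise mean-centered scalar covariates (optionally split into
group-specific columns), and voxel-wise imaging covariates (a
subject-specific 3D map expanded into cell-specific columns whose values
differ at every voxel, making the design matrix voxel-dependent).

Inference: per-voxel OLS, t-contrasts, and family-wise error control by
permutation of the maximum statistic (Freedman-Lane residual permutation
under the reduced model, optionally stratified), with Bonferroni as a
fallback.  Surviving voxels are grouped with 26-connectivity and clusters
below the extent threshold are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "VoxelGrid",
    "ScalarCovariate",
    "VoxelwiseCovariate",
    "GroupModelSpec",
    "model1_spec",
    "model2_spec",
    "model3_spec",
    "build_inclusive_mask",
    "GroupDesign",
    "assemble_designs",
    "GroupFit",
    "fit_group_glm",
    "fit_voxelwise",
    "StatMap",
    "t_contrast",
    "contrast_vector",
    "FweResult",
    "fwe_threshold",
    "cluster_table",
    "overlap_maps",
]

CELL_ORDER = (("young", "Skyra"), ("young", "Verio"), ("older", "Skyra"), ("older", "Verio"))
_GROUP_SHORT = {"young": "young", "older": "old"}
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)
MIN_PERMUTABLE = 10


# ---------------------------------------------------------------------------
# spatial bookkeeping


@dataclass
class VoxelGrid:
    """Flat indexing over the in-mask voxels of a 3D grid."""

    mask: np.ndarray  # 3D bool
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_vox(self) -> int:
        return int(self.mask.sum())

    def flatten(self, maps: np.ndarray) -> np.ndarray:
        """(n, x, y, z) or (x, y, z) -> (n, V) or (V,)."""
        maps = np.asarray(maps, dtype=float)
        if maps.ndim == 3:
            return maps[self.mask]
        return maps[:, self.mask]

    def unflatten(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        out = np.full(self.mask.shape, fill, dtype=float)
        out[self.mask] = values
        return out


def build_inclusive_mask(*map_stacks: np.ndarray) -> np.ndarray:
    """Voxels finite and nonzero in every subject's map of every modality."""
    if not map_stacks:
        raise ValueError("need at least one map stack")
    mask = None
    for stack in map_stacks:
        stack = np.asarray(stack, dtype=float)
        if stack.ndim != 4:
            raise ValueError("each stack must be (n_subjects, x, y, z)")
        good = np.all(np.isfinite(stack) & (stack != 0), axis=0)
        mask = good if mask is None else (mask & good)
        if mask.shape != good.shape:
            raise ValueError("map stacks are on different grids")
    if not mask.any():
        raise ValueError("inclusive mask is empty")
    return mask


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ScalarCovariate:
    column: str  # cohort column
    label: str | None = None  # regressor label (defaults to column)
    center: str = "groupwise"  # {"groupwise", "none"}
    split_by_group: bool = True

    def __post_init__(self) -> None:
        if self.center not in ("groupwise", "none"):
            raise ValueError(f"unknown centering policy {self.center!r}")


@dataclass(frozen=True)
class VoxelwiseCovariate:
    key: str  # key into the maps dict
    label: str | None = None
    center: bool = True  # mean-center within cell, per voxel
    split_by_cell: bool = True


@dataclass
class GroupModelSpec:
    dependent: str  # key into the maps dict (mperaf | sme | gmv | ...)
    scalar_covariates: list[ScalarCovariate] = field(default_factory=list)
    voxelwise_covariates: list[VoxelwiseCovariate] = field(default_factory=list)
    cell_factors: tuple[str, str] = ("age_group", "scanner")


def model1_spec() -> GroupModelSpec:
    """mPerAF ~ cells + HCvol + TIV + WMLV + age + voxel-wise GMV."""
    return GroupModelSpec(
        dependent="mperaf",
        scalar_covariates=[
            ScalarCovariate("hc_vol", "HCvol"),
            ScalarCovariate("tiv", "TIV"),
            ScalarCovariate("wmlv", "WMLV"),
            ScalarCovariate("age", "age", split_by_group=False),
        ],
        voxelwise_covariates=[VoxelwiseCovariate("gmv", "GMV")],
    )


def model2_spec() -> GroupModelSpec:
    """SME ~ same regressors as model 1."""
    spec = model1_spec()
    spec.dependent = "sme"
    return spec


def model3_spec() -> GroupModelSpec:
    """SME ~ cells + age + voxel-wise mPerAF + voxel-wise GMV."""
    return GroupModelSpec(
        dependent="sme",
        scalar_covariates=[ScalarCovariate("age", "age", split_by_group=False)],
        voxelwise_covariates=[
            VoxelwiseCovariate("mperaf", "mPerAF"),
            VoxelwiseCovariate("gmv", "GMV"),
        ],
    )


# ---------------------------------------------------------------------------
# design assembly


@dataclass
class VoxelFiller:
    """One voxel-dependent design column."""

    col: int
    members: np.ndarray  # subject row indices contributing to this column
    key: str  # maps dict key
    center: bool


@dataclass
class GroupDesign:
    base: np.ndarray  # (n, p); voxel-dependent columns are zero here
    names: list[str]
    fillers: list[VoxelFiller]
    maps: dict[str, np.ndarray]  # key -> (n, V)
    cohort: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return self.base.shape[0]

    @property
    def n_columns(self) -> int:
        return self.base.shape[1]

    @property
    def has_voxelwise(self) -> bool:
        return bool(self.fillers)

    def matrix_at(self, vox: int) -> np.ndarray:
        """Materialize the design matrix at one voxel."""
        x = self.base.copy()
        for f in self.fillers:
            vals = self.maps[f.key][f.members, vox]
            if f.center:
                vals = vals - vals.mean()
            x[f.members, f.col] = vals
        return x

    def matrices_at(self, vox_idx: np.ndarray) -> np.ndarray:
        """Materialize a (len(vox_idx), n, p) stack of design matrices."""
        xs = np.broadcast_to(self.base, (len(vox_idx),) + self.base.shape).copy()
        for f in self.fillers:
            vals = self.maps[f.key][np.ix_(f.members, vox_idx)]  # (m_members, m_vox)
            if f.center:
                vals = vals - vals.mean(axis=0, keepdims=True)
            xs[:, f.members, f.col] = vals.T
        return xs


def _check_cohort(cohort: pd.DataFrame, spec: GroupModelSpec) -> None:
    needed = set(spec.cell_factors) | {c.column for c in spec.scalar_covariates}
    missing = needed - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    g_col, s_col = spec.cell_factors
    if not set(cohort[g_col]) <= {"young", "older"}:
        raise ValueError("age_group must be 'young' or 'older'")
    if not set(cohort[s_col]) <= {"Skyra", "Verio"}:
        raise ValueError("scanner must be 'Skyra' or 'Verio'")


def assemble_designs(
    spec: GroupModelSpec,
    cohort: pd.DataFrame,
    maps: dict[str, np.ndarray],
) -> GroupDesign:
    """Build the (voxel-dependent) group design.

    ``maps`` holds one (n_subjects, n_voxels) array per imaging modality,
    row-aligned with ``cohort``.  Scalar covariates are centered per policy
    and optionally split into group-specific columns; each voxel-wise
    covariate is expanded into cell-specific columns whose values vary by
    voxel (centered within cell at each voxel).
    """
    cohort = cohort.reset_index(drop=True)
    _check_cohort(cohort, spec)
    n = len(cohort)
    g_col, s_col = spec.cell_factors
    group = cohort[g_col].to_numpy()
    scanner = cohort[s_col].to_numpy()

    for cov in spec.voxelwise_covariates:
        if cov.key not in maps:
            raise ValueError(f"missing map stack for voxelwise covariate {cov.key!r}")
        stack = np.asarray(maps[cov.key], dtype=float)
        if stack.ndim != 2 or stack.shape[0] != n:
            raise ValueError(
                f"map stack {cov.key!r} must be (n_subjects, n_voxels) with "
                f"{n} rows, got {stack.shape}"
            )
        bad = ~np.all(np.isfinite(stack), axis=1)
        if bad.any():
            sid = cohort.get("subject_id", pd.Series(np.arange(n)))[np.flatnonzero(bad)[0]]
            raise ValueError(
                f"non-finite {cov.key!r} map for subject {sid!r}"
            )

    columns: list[np.ndarray] = []
    names: list[str] = []
    fillers: list[VoxelFiller] = []

    # cell indicator columns
    cell_members: dict[tuple[str, str], np.ndarray] = {}
    for g, s in CELL_ORDER:
        members = np.flatnonzero((group == g) & (scanner == s))
        cell_members[(g, s)] = members
        ind = np.zeros(n)
        ind[members] = 1.0
        columns.append(ind)
        names.append(f"{g}_{s}")

    # scalar covariates
    for cov in spec.scalar_covariates:
        label = cov.label or cov.column
        vals = cohort[cov.column].to_numpy(dtype=float)
        centered = vals.copy()
        if cov.center == "groupwise":
            for g in ("young", "older"):
                sel = group == g
                if sel.any():
                    centered[sel] = vals[sel] - vals[sel].mean()
        if cov.split_by_group:
            for g in ("young", "older"):
                col = np.where(group == g, centered, 0.0)
                columns.append(col)
                names.append(f"{label}_{_GROUP_SHORT[g]}")
        else:
            columns.append(centered)
            names.append(label)

    # voxelwise covariates (placeholder zero columns + fillers)
    for cov in spec.voxelwise_covariates:
        label = cov.label or cov.key
        if cov.split_by_cell:
            for g, s in CELL_ORDER:
                columns.append(np.zeros(n))
                names.append(f"{label}_{_GROUP_SHORT[g]}_{s}")
                fillers.append(
                    VoxelFiller(len(columns) - 1, cell_members[(g, s)], cov.key, cov.center)
                )
        else:
            columns.append(np.zeros(n))
            names.append(label)
            fillers.append(
                VoxelFiller(len(columns) - 1, np.arange(n), cov.key, cov.center)
            )

    base = np.column_stack(columns)
    return GroupDesign(base=base, names=names, fillers=fillers, maps=dict(maps), cohort=cohort)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class GroupFit:
    betas: np.ndarray  # (V, p)
    xtx_inv: np.ndarray  # (p, p) shared, or (V, p, p)
    sigma2: np.ndarray  # (V,)
    df: int
    names: list[str]
    valid: np.ndarray  # (V,) bool; rank-deficient voxels are False

    @property
    def shared_design(self) -> bool:
        return self.xtx_inv.ndim == 2


def fit_group_glm(x: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> GroupFit:
    """Standard single-design group GLM, vectorized over voxels.

    ``x`` is (n, p), ``y`` is (n, V).  Requires a full-rank design.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        raise ValueError(f"group design is rank-deficient (rank {rank} < {p} columns)")
    pinv = np.linalg.pinv(x)
    b = pinv @ y  # (p, V)
    resid = y - x @ b
    df = n - p
    if df <= 0:
        raise ValueError("no error degrees of freedom")
    sigma2 = np.sum(resid**2, axis=0) / df
    xtx_inv = pinv @ pinv.T
    if names is None:
        names = [f"x{i}" for i in range(p)]
    return GroupFit(
        betas=b.T,
        xtx_inv=xtx_inv,
        sigma2=sigma2,
        df=df,
        names=list(names),
        valid=np.ones(y.shape[1], dtype=bool),
    )


def fit_voxelwise(
    design: GroupDesign,
    y: np.ndarray,
    chunk: int = 512,
    max_deficient_frac: float = 0.5,
) -> GroupFit:
    """Independent OLS at each voxel of a voxel-dependent design.

    With no voxel-wise covariates the design is identical at every voxel
    and the fit reduces to (and delegates to) :func:`fit_group_glm`, so the
    two routes agree bit for bit.  Rank-deficient voxels (e.g. a voxel-wise
    covariate locally constant within a cell) are masked out and reported
    via ``valid``; if more than ``max_deficient_frac`` of voxels are
    deficient the fit aborts.
    """
    y = np.asarray(y, dtype=float)
    n, v = y.shape
    if n != design.n_subjects:
        raise ValueError(f"y has {n} rows but the design has {design.n_subjects} subjects")
    if not design.has_voxelwise:
        return fit_group_glm(design.base, y, design.names)

    p = design.n_columns
    df = n - p
    if df <= 0:
        raise ValueError("no error degrees of freedom")
    betas = np.zeros((v, p))
    sigma2 = np.zeros(v)
    xtx_inv = np.zeros((v, p, p))
    valid = np.ones(v, dtype=bool)

    for start in range(0, v, chunk):
        idx = np.arange(start, min(start + chunk, v))
        xs = design.matrices_at(idx)  # (m, n, p)
        ranks = np.linalg.matrix_rank(xs)
        ok = ranks == p
        valid[idx] = ok
        pinvs = np.linalg.pinv(xs)  # (m, p, n)
        yc = y[:, idx].T[:, :, None]  # (m, n, 1)
        b = pinvs @ yc  # (m, p, 1)
        resid = yc - xs @ b
        betas[idx] = b[:, :, 0]
        sigma2[idx] = np.sum(resid[:, :, 0] ** 2, axis=1) / df
        xtx_inv[idx] = pinvs @ pinvs.transpose(0, 2, 1)

    n_bad = int((~valid).sum())
    if n_bad > max_deficient_frac * v:
        raise RuntimeError(
            f"{n_bad}/{v} voxels have rank-deficient designs; check that "
            "voxel-wise covariates vary within every cell"
        )
    return GroupFit(betas=betas, xtx_inv=xtx_inv, sigma2=sigma2, df=df,
                    names=list(design.names), valid=valid)


# ---------------------------------------------------------------------------
# contrasts


def contrast_vector(names: list[str], weights: dict[str, float]) -> np.ndarray:
    """Build a contrast vector from column-name weights."""
    unknown = set(weights) - set(names)
    if unknown:
        raise ValueError(f"unknown design columns: {sorted(unknown)}")
    c = np.array([weights.get(nm, 0.0) for nm in names])
    if not c.any():
        raise ValueError("contrast is all-zero")
    return c


@dataclass
class StatMap:
    t: np.ndarray  # (V,)
    df: int
    name: str = ""


def t_contrast(fit: GroupFit, contrast: np.ndarray, name: str = "") -> StatMap:
    """t = c'beta / sqrt(sigma2 * c'(X'X)^-1 c), per voxel."""
    c = np.asarray(contrast, dtype=float)
    if c.shape != (len(fit.names),):
        raise ValueError(f"contrast length {c.size} != {len(fit.names)} columns")
    if not c.any():
        raise ValueError("contrast is all-zero")
    num = fit.betas @ c
    if fit.shared_design:
        cvc = float(c @ fit.xtx_inv @ c)
        var = fit.sigma2 * cvc
    else:
        cvc = np.einsum("vij,i,j->v", fit.xtx_inv, c, c)
        var = fit.sigma2 * cvc
    if np.any(var[fit.valid] <= 0) and not np.all(fit.sigma2[fit.valid] > 0):
        # zero residual variance (noise-free data): t undefined, report inf sign
        pass
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / np.sqrt(var)
    t[~fit.valid] = 0.0
    t[~np.isfinite(t)] = 0.0
    return StatMap(t=t, df=fit.df, name=name)


# ---------------------------------------------------------------------------
# permutation max-T FWE


def _permutation_indices(
    n: int, n_perm: int, rng: np.random.Generator, strata: np.ndarray | None
) -> np.ndarray:
    """(n_perm, n) row-permutation indices; first row is the identity."""
    perms = np.tile(np.arange(n), (n_perm, 1))
    if strata is None:
        for i in range(1, n_perm):
            perms[i] = rng.permutation(n)
    else:
        strata = np.asarray(strata)
        groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
        for i in range(1, n_perm):
            for g in groups:
                perms[i, g] = g[rng.permutation(len(g))]
    return perms


def _perm_maxt_shared(
    x: np.ndarray,
    y: np.ndarray,
    c: np.ndarray,
    df: int,
    perms: np.ndarray,
) -> np.ndarray:
    """Freedman-Lane max-T null for a shared (voxel-independent) design."""
    n = x.shape[0]
    nuis = c == 0
    z = x[:, nuis]
    if z.shape[1]:
        hz = z @ np.linalg.pinv(z)
        fz = hz @ y
    else:
        fz = np.zeros_like(y)
    e = y - fz
    pinv = np.linalg.pinv(x)
    a = c @ pinv  # (n,)
    r_full = np.eye(n) - x @ pinv
    cvc = float(c @ (pinv @ pinv.T) @ c)
    maxt = np.empty(len(perms))
    for i, perm in enumerate(perms):
        yp = fz + e[perm]
        num = a @ yp
        rss = np.sum((r_full @ yp) ** 2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = num / np.sqrt(rss / df * cvc)
        t[~np.isfinite(t)] = 0.0
        maxt[i] = t.max()
    return maxt


def _perm_maxt_voxelwise(
    design: GroupDesign,
    y: np.ndarray,
    c: np.ndarray,
    df: int,
    perms: np.ndarray,
    chunk: int = 256,
) -> np.ndarray:
    n, v = y.shape
    nuis = c == 0
    maxt = np.full(len(perms), -np.inf)
    eye = np.eye(n)
    for start in range(0, v, chunk):
        idx = np.arange(start, min(start + chunk, v))
        xs = design.matrices_at(idx)  # (m, n, p)
        pinvs = np.linalg.pinv(xs)
        zs = xs[:, :, nuis]
        if zs.shape[2]:
            hz = zs @ np.linalg.pinv(zs)  # (m, n, n)
            fz = np.einsum("mij,jm->mi", hz, y[:, idx])  # (m, n)
        else:
            fz = np.zeros((len(idx), n))
        e = y[:, idx].T - fz  # (m, n)
        a = np.einsum("j,mjn->mn", c, pinvs)  # (m, n)
        r_full = eye[None] - xs @ pinvs  # (m, n, n)
        cvc = np.einsum("mpn,mqn,p,q->m", pinvs, pinvs, c, c)
        for i, perm in enumerate(perms):
            yp = fz + e[:, perm]
            num = np.sum(a * yp, axis=1)
            res = np.einsum("mij,mj->mi", r_full, yp)
            rss = np.sum(res**2, axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = num / np.sqrt(rss / df * cvc)
            t[~np.isfinite(t)] = 0.0
            t_max = t.max() if t.size else -np.inf
            if t_max > maxt[i]:
                maxt[i] = t_max
    return maxt


@dataclass
class FweResult:
    tmap: np.ndarray  # 3D t map (0 outside mask)
    sig: np.ndarray  # 3D bool, surviving voxels after extent threshold
    clusters: pd.DataFrame
    p_fwe: np.ndarray  # (V,) voxel-level FWE p-values
    threshold: float  # critical t at alpha
    df: int
    method: str
    maxt_null: np.ndarray | None = None


def fwe_threshold(
    design: GroupDesign,
    y: np.ndarray,
    contrast: np.ndarray,
    grid: VoxelGrid,
    method: str = "permutation_maxT",
    alpha: float = 0.05,
    cluster_k: int = 10,
    n_perm: int = 2000,
    seed: int | None = None,
    strata: np.ndarray | None = None,
) -> FweResult:
    """Voxel-level FWE threshold + cluster table for a one-sided contrast.

    ``permutation_maxT`` uses Freedman-Lane residual permutation under the
    reduced model (the identity permutation is included in the null set, so
    p-values are valid with p = #{maxT >= t}/n_perm).  ``bonferroni``
    divides alpha by the voxel count.  Two-sided questions are asked as two
    one-sided contrasts (c and -c).
    """
    c = np.asarray(contrast, dtype=float)
    fit = fit_voxelwise(design, y)
    stat = t_contrast(fit, c)
    v = y.shape[1]

    if method == "bonferroni":
        p_fwe = np.minimum(1.0, stats.t.sf(stat.t, fit.df) * v)
        threshold = float(stats.t.isf(alpha / v, fit.df))
        maxt = None
    elif method == "permutation_maxT":
        n = design.n_subjects
        if n < MIN_PERMUTABLE:
            raise ValueError(f"too few permutable units ({n} < {MIN_PERMUTABLE})")
        rng = np.random.default_rng(seed)
        perms = _permutation_indices(n, n_perm, rng, strata)
        if design.has_voxelwise:
            maxt = _perm_maxt_voxelwise(design, y, c, fit.df, perms)
        else:
            maxt = _perm_maxt_shared(design.base, y, c, fit.df, perms)
        p_fwe = np.array([(maxt >= t).mean() for t in stat.t])
        # smallest t value that still achieves p <= alpha
        srt = np.sort(maxt)[::-1]
        k_crit = int(np.floor(alpha * n_perm))
        threshold = float(srt[max(k_crit - 1, 0)]) if k_crit >= 1 else float("inf")
    else:
        raise ValueError(f"unknown method {method!r}")

    sig_flat = (p_fwe <= alpha) & fit.valid
    t3 = grid.unflatten(stat.t)
    sig3 = grid.unflatten(sig_flat.astype(float)) > 0
    p3 = grid.unflatten(p_fwe, fill=1.0)
    clusters, keep3 = cluster_table(sig3, t3, grid.affine, k=cluster_k, p_fwe=p3)
    return FweResult(
        tmap=t3,
        sig=keep3,
        clusters=clusters,
        p_fwe=p_fwe,
        threshold=threshold,
        df=fit.df,
        method=method,
        maxt_null=maxt,
    )


# ---------------------------------------------------------------------------
# clusters and overlap


def cluster_table(
    sig: np.ndarray,
    tmap: np.ndarray,
    affine: np.ndarray,
    k: int = 10,
    p_fwe: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Label supra-threshold voxels (26-connectivity) and tabulate clusters.

    Clusters smaller than ``k`` voxels are removed.  Returns the table
    (cluster, size, peak_t, x/y/z in mm via the affine, p_fwe of the peak)
    and the retained 3D mask.
    """
    sig = np.asarray(sig, dtype=bool)
    labels, n_lab = ndimage.label(sig, structure=CONNECTIVITY_26)
    keep = np.zeros_like(sig)
    rows = []
    for lab in range(1, n_lab + 1):
        m = labels == lab
        size = int(m.sum())
        if size < k:
            continue
        keep |= m
        t_in = np.where(m, tmap, -np.inf)
        peak = np.unravel_index(np.argmax(t_in), tmap.shape)
        mm = affine @ np.array([*peak, 1.0])
        rows.append(
            {
                "cluster": lab,
                "size": size,
                "peak_t": float(tmap[peak]),
                "x": float(mm[0]),
                "y": float(mm[1]),
                "z": float(mm[2]),
                "p_fwe": float(p_fwe[peak]) if p_fwe is not None else np.nan,
            }
        )
    table = pd.DataFrame(rows, columns=["cluster", "size", "peak_t", "x", "y", "z", "p_fwe"])
    table = table.sort_values("peak_t", ascending=False, ignore_index=True)
    return table, keep


def overlap_maps(
    sig_a: np.ndarray,
    sig_b: np.ndarray,
    affine: np.ndarray,
    tmap_a: np.ndarray | None = None,
    tmap_b: np.ndarray | None = None,
    k: int = 1,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Voxel-wise logical AND of two thresholded maps + cluster table.

    When both t maps are supplied, cluster peaks are located on the
    element-wise minimum of the two (the weaker of the two effects).
    """
    sig_a = np.asarray(sig_a, dtype=bool)
    sig_b = np.asarray(sig_b, dtype=bool)
    if sig_a.shape != sig_b.shape:
        raise ValueError(f"grid mismatch: {sig_a.shape} vs {sig_b.shape}")
    inter = sig_a & sig_b
    if tmap_a is not None and tmap_b is not None:
        stat = np.minimum(tmap_a, tmap_b)
    else:
        stat = inter.astype(float)
    table, keep = cluster_table(inter, stat, affine, k=k)
    return keep, table
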