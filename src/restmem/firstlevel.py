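"""Single-subject task GLM for the parametric subsequent-memory effect.

The design contains a novelty onset regressor, the novelty regressor
parametrically modulated by the (mean-centered) arcsine-transformed
confidence rating, a master-image regressor, six motion covariates and a
constant.  Boxcars are built on a microtime grid, convolved with a
canonical double-gamma HRF and downsampled at a reference bin.  Fitting is
OLS after DCT high-pass filtering; the SME map is the beta of the
novelty-by-modulator regressor (positive values: activity predicts later
remembering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from restmem.amplitude import BoldSeries
from restmem.behavior import parametric_modulator

__all__ = [
    "canonical_hrf",
    "DesignMatrix",
    "build_design",
    "dct_highpass_basis",
    "FirstLevelResult",
    "fit_first_level",
    "validate_events",
]

# double-gamma kernel parameters: peaks (= gamma modes) in seconds
HRF_RESPONSE_PEAK = 6.0
HRF_UNDERSHOOT_PEAK = 16.0
HRF_RESPONSE_DISPERSION = 1.0
HRF_UNDERSHOOT_DISPERSION = 1.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0
HRF_LENGTH = 32.0

MICROTIME = 16
REF_BIN = 8


def canonical_hrf(dt: float) -> np.ndarray:
    """Canonical double-gamma HRF sampled at resolution ``dt`` seconds.

    Response gamma peaks at 6 s, undershoot gamma at 16 s (dispersion 1,
    undershoot ratio 1/6), 32 s support, peak-normalized to max 1.  A gamma
    density with scale ``d`` peaks (mode) at ``(a - 1) d``, so the shape is
    ``peak / d + 1``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    t = np.arange(0, HRF_LENGTH + dt / 2, dt)
    resp = stats.gamma.pdf(
        t, a=HRF_RESPONSE_PEAK / HRF_RESPONSE_DISPERSION + 1, scale=HRF_RESPONSE_DISPERSION
    )
    under = stats.gamma.pdf(
        t, a=HRF_UNDERSHOOT_PEAK / HRF_UNDERSHOOT_DISPERSION + 1, scale=HRF_UNDERSHOOT_DISPERSION
    )
    h = resp - HRF_UNDERSHOOT_RATIO * under
    return h / h.max()


def validate_events(events: pd.DataFrame, run_duration: float | None = None) -> pd.DataFrame:
    """Validate an event table (onset, duration, trial_type[, rating])."""
    required = {"onset", "duration", "trial_type"}
    if not required.issubset(events.columns):
        raise ValueError(f"event table needs columns {sorted(required)}")
    onsets = events["onset"].to_numpy(dtype=float)
    durations = events["duration"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) < 0):
        raise ValueError("onsets must be non-decreasing")
    if np.any(durations <= 0):
        raise ValueError("durations must be positive")
    if not set(events["trial_type"]) <= {"novel", "master"}:
        raise ValueError("trial_type must be 'novel' or 'master'")
    if run_duration is not None and len(events):
        end = (onsets + durations).max()
        if end > run_duration:
            raise ValueError(
                f"events extend to {end:.2f} s but the run is only "
                f"{run_duration:.2f} s long"
            )
    return events


@dataclass
class DesignMatrix:
    values: np.ndarray  # (n_scans, n_regressors)
    names: list[str]
    tr: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values shape does not match names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("design matrix contains non-finite entries")
        if "constant" not in self.names:
            raise ValueError("design must contain a constant column")

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


def _microtime_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    weights: np.ndarray,
    n_scans: int,
    dt: float,
    hrf: np.ndarray,
) -> np.ndarray:
    grid = np.zeros(n_scans * MICROTIME)
    for onset, dur, w in zip(onsets, durations, weights):
        i0 = int(round(onset / dt))
        i1 = int(round((onset + dur) / dt))
        grid[i0:i1] += w
    conv = np.convolve(grid, hrf)[: grid.size]
    return conv[np.arange(n_scans) * MICROTIME + REF_BIN]


def build_design(
    events: pd.DataFrame,
    n_scans: int,
    tr: float,
    motion: np.ndarray | None = None,
) -> DesignMatrix:
    """Build the first-level design matrix.

    Columns (in order): novelty, novelty_x_pm, master, motion_1..motion_6
    (if ``motion`` is given), constant.  The parametric-modulator column is
    the novelty boxcar weighted by the mean-centered PM of each novel
    event, then convolved with the HRF; if all ratings are equal it is
    all-zero after centering (and the design is then rank-deficient by
    construction, which :func:`fit_first_level` reports).  Novelty and
    modulator columns are only present when novel events exist; the master
    column only when master events exist.
    """
    validate_events(events, run_duration=n_scans * tr)
    dt = tr / MICROTIME
    hrf = canonical_hrf(dt)

    columns: list[np.ndarray] = []
    names: list[str] = []

    novel = events[events["trial_type"] == "novel"]
    master = events[events["trial_type"] == "master"]

    if len(novel):
        on = novel["onset"].to_numpy(dtype=float)
        dur = novel["duration"].to_numpy(dtype=float)
        columns.append(_microtime_regressor(on, dur, np.ones(len(novel)), n_scans, dt, hrf))
        names.append("novelty")
        if "rating" in novel.columns and novel["rating"].notna().all():
            pm = parametric_modulator(novel["rating"].to_numpy(dtype=int))
            pm = pm - pm.mean()
            columns.append(_microtime_regressor(on, dur, pm, n_scans, dt, hrf))
            names.append("novelty_x_pm")
    if len(master):
        on = master["onset"].to_numpy(dtype=float)
        dur = master["duration"].to_numpy(dtype=float)
        columns.append(_microtime_regressor(on, dur, np.ones(len(master)), n_scans, dt, hrf))
        names.append("master")

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_scans, 6):
            raise ValueError(f"motion must be (n_scans, 6), got {motion.shape}")
        for i in range(6):
            columns.append(motion[:, i])
            names.append(f"motion_{i + 1}")

    columns.append(np.ones(n_scans))
    names.append("constant")
    return DesignMatrix(np.column_stack(columns), names, tr)


def dct_highpass_basis(n_scans: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """Orthonormal DCT columns spanning drifts slower than ``cutoff`` seconds.

    Order follows the SPM convention floor(2 * n * tr / cutoff), excluding
    the constant term.  Returns an (n_scans, order) matrix (possibly with 0
    columns).
    """
    order = int(np.floor(2.0 * n_scans * tr / cutoff))
    t = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * (2 * t + 1) * k / (2 * n_scans))
        for k in range(1, order + 1)
    ]
    if not cols:
        return np.zeros((n_scans, 0))
    return np.column_stack(cols)


@dataclass
class FirstLevelResult:
    betas: dict[str, np.ndarray]  # name -> 3D beta map
    sme: np.ndarray | None  # beta map of novelty_x_pm (None if absent)
    design: DesignMatrix
    df: int
    mask: np.ndarray
    affine: np.ndarray
    subject_id: str | None = None
    ar1_rho: float | None = None


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    return [names[i] for i in np.flatnonzero(diag < tol)]


def fit_first_level(
    bold: BoldSeries,
    design: DesignMatrix,
    highpass: float = 128.0,
    ar1: bool = False,
    subject_id: str | None = None,
) -> FirstLevelResult:
    """Mass-univariate OLS fit of a first-level design.

    High-pass filtering projects the DCT drift basis out of both data and
    design.  With ``ar1=True``, a pooled lag-1 autocorrelation is estimated
    from the OLS residuals and both sides are prewhitened before refitting
    (contrast estimates are unbiased either way).
    """
    if design.n_scans != bold.n_vols:
        raise ValueError(
            f"design has {design.n_scans} scans but BOLD has {bold.n_vols} volumes"
        )
    y = bold.data[bold.mask].T  # (n_scans, n_vox)
    x = design.values.copy()

    k = dct_highpass_basis(design.n_scans, design.tr, highpass)
    if k.shape[1]:
        x = x - k @ (k.T @ x)
        y = y - k @ (k.T @ y)

    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _collinear_columns(x, design.names)
        raise ValueError(f"design is rank-deficient after filtering; collinear columns: {bad}")

    pinv = np.linalg.pinv(x)
    b = pinv @ y
    rho = None
    if ar1:
        resid = y - x @ b
        num = float(np.sum(resid[1:] * resid[:-1]))
        den = float(np.sum(resid[:-1] ** 2))
        rho = num / den if den > 0 else 0.0
        w_first = np.sqrt(max(1.0 - rho**2, np.finfo(float).tiny))
        xw = np.vstack([x[:1] * w_first, x[1:] - rho * x[:-1]])
        yw = np.vstack([y[:1] * w_first, y[1:] - rho * y[:-1]])
        b = np.linalg.pinv(xw) @ yw

    df = design.n_scans - k.shape[1] - x.shape[1]
    betas: dict[str, np.ndarray] = {}
    for i, name in enumerate(design.names):
        m = np.zeros(bold.spatial_shape)
        m[bold.mask] = b[i]
        betas[name] = m
    sme = betas.get("novelty_x_pm")
    return FirstLevelResult(
        betas=betas,
        sme=sme,
        design=design,
        df=df,
        mask=bold.mask.copy(),
        affine=bold.affine,
        subject_id=subject_id,
        ar1_rho=rho,
    )
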