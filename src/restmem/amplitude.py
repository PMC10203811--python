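"""Percent amplitude of fluctuation (PerAF) and its global-mean-normalized
variant (mPerAF) from 4D BOLD time series.

PerAF is the mean absolute deviation of a voxel's band-limited BOLD time
series relative to its mean signal intensity, expressed in percent:

    PerAF(v) = 100 / n * sum_i |y_i - mu| / mu

It is scale-independent (multiplying the raw series by any positive
constant leaves it unchanged) and sign-free (always >= 0).  mPerAF is the
ratio of a voxel's PerAF to the global mean PerAF over a normalization
mask, so that the mean of mPerAF over that mask is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "BoldSeries",
    "AmplitudeMap",
    "detrend_bandpass",
    "compute_peraf",
    "normalize_global_mean",
    "peraf_pipeline",
]

DEFAULT_BAND = (0.01, 0.08)


@dataclass
class BoldSeries:
    """A 4D BOLD image with repetition time, affine and brain mask.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Signal intensities in arbitrary scanner units.
    tr : float
        Repetition time in seconds.
    affine : ndarray, shape (4, 4)
        Voxel-to-mm transform (RAS convention).
    mask : ndarray of bool, shape (x, y, z), optional
        Brain mask; defaults to all voxels.
    """

    data: np.ndarray
    tr: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (x, y, z, t), got ndim={self.data.ndim}")
        if self.data.shape[-1] < 2:
            raise ValueError("need at least 2 time points")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match "
                    f"spatial shape {self.data.shape[:3]}"
                )

    @property
    def n_vols(self) -> int:
        return self.data.shape[-1]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in Hz."""
        return 1.0 / (2.0 * self.tr)

    def save(self, path: str) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(img.header.get_zooms()[:3] + (self.tr,))
        nib.save(img, path)

    @classmethod
    def load(cls, path: str, tr: float | None = None, mask: np.ndarray | None = None) -> "BoldSeries":
        img = nib.load(path)
        if tr is None:
            zooms = img.header.get_zooms()
            if len(zooms) < 4 or zooms[3] <= 0:
                raise ValueError("TR not stored in header; pass tr explicitly")
            tr = float(zooms[3])
        return cls(np.asarray(img.dataobj, dtype=float), tr, img.affine, mask)


@dataclass
class AmplitudeMap:
    """A 3D PerAF (percent units) or mPerAF (unitless ratio) map.

    ``qc`` lists voxels whose PerAF was forced to 0 (non-positive mean or
    zero variance) with one row per flagged voxel (columns i, j, k, reason).
    """

    data: np.ndarray
    kind: str  # "peraf" | "mperaf"
    affine: np.ndarray
    mask: np.ndarray
    band: tuple[float, float] | None = None
    norm_mask_id: str | None = None
    qc: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("peraf", "mperaf"):
            raise ValueError(f"kind must be 'peraf' or 'mperaf', got {self.kind!r}")
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != self.mask.shape:
            raise ValueError("data and mask shapes differ")

    def save(self, path: str) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), path)


def _flatten(bold: BoldSeries) -> np.ndarray:
    return bold.data.reshape(-1, bold.n_vols)


def detrend_bandpass(
    bold: BoldSeries,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
) -> BoldSeries:
    """Linear detrend, then rectangular frequency-domain band-pass.

    The per-voxel linear trend is removed, frequency content outside
    [low, high] Hz is zeroed on the FFT (in-band edge bins inclusive), and
    the original series mean is re-added so that the PerAF denominator mu
    remains defined.
    """
    nyq = bold.nyquist
    if not (0 <= low < high):
        raise ValueError(f"need 0 <= low < high, got low={low}, high={high}")
    if high > nyq:
        raise ValueError(
            f"high={high} Hz exceeds the Nyquist frequency {nyq:.6g} Hz "
            f"for tr={bold.tr} s"
        )
    n = bold.n_vols
    y = _flatten(bold)
    mean = y.mean(axis=-1, keepdims=True)
    y = signal.detrend(y, axis=-1, type="linear")
    freqs = np.fft.rfftfreq(n, d=bold.tr)
    keep = (freqs >= low) & (freqs <= high)
    spec = np.fft.rfft(y, axis=-1)
    spec[:, ~keep] = 0.0
    y = np.fft.irfft(spec, n=n, axis=-1) + mean
    return replace(bold, data=y.reshape(bold.data.shape))


def compute_peraf(bold: BoldSeries, mu: np.ndarray | None = None) -> AmplitudeMap:
    """Percent amplitude of fluctuation per voxel.

    Parameters
    ----------
    bold : BoldSeries
        Typically the output of :func:`detrend_bandpass`.
    mu : ndarray, shape (x, y, z), optional
        Denominator mean map.  Defaults to the per-voxel mean of ``bold``
        itself; pass the raw-series mean here to use the "raw-mu" dialect
        with a filter that does not preserve the mean.

    Voxels inside the mask with mu <= 0 are set to 0 and flagged in the QC
    table (reason ``nonpositive_mean``); constant series yield PerAF 0 and
    are flagged as ``zero_variance``.  Voxels outside the mask are 0.
    """
    y = _flatten(bold)
    if mu is None:
        mu_flat = y.mean(axis=-1)
    else:
        mu = np.asarray(mu, dtype=float)
        if mu.shape != bold.spatial_shape:
            raise ValueError("mu map shape does not match spatial shape")
        mu_flat = mu.reshape(-1)
    dev = np.abs(y - mu_flat[:, None]).mean(axis=-1)
    mask_flat = bold.mask.reshape(-1)

    good = mask_flat & (mu_flat > 0)
    out = np.zeros_like(mu_flat)
    out[good] = dev[good] / mu_flat[good] * 100.0

    qc_rows = []
    bad_mu = mask_flat & (mu_flat <= 0)
    zero_var = mask_flat & (mu_flat > 0) & (y.std(axis=-1) == 0)
    for flat_idx_arr, reason in ((np.flatnonzero(bad_mu), "nonpositive_mean"),
                                 (np.flatnonzero(zero_var), "zero_variance")):
        for flat_idx in flat_idx_arr:
            i, j, k = np.unravel_index(flat_idx, bold.spatial_shape)
            qc_rows.append({"i": int(i), "j": int(j), "k": int(k), "reason": reason})
    qc = pd.DataFrame(qc_rows, columns=["i", "j", "k", "reason"])

    return AmplitudeMap(
        data=out.reshape(bold.spatial_shape),
        kind="peraf",
        affine=bold.affine,
        mask=bold.mask.copy(),
        qc=qc,
    )


def _default_norm_mask(peraf: AmplitudeMap) -> np.ndarray:
    """Brain mask minus QC-flagged (degenerate) voxels."""
    mask = peraf.mask.copy()
    if peraf.qc is not None and len(peraf.qc):
        mask[peraf.qc["i"].to_numpy(), peraf.qc["j"].to_numpy(), peraf.qc["k"].to_numpy()] = False
    return mask


def normalize_global_mean(
    peraf: AmplitudeMap,
    mask: np.ndarray | None = None,
    norm_mask_id: str | None = None,
) -> AmplitudeMap:
    """Divide a PerAF map by its global mean over ``mask`` (-> mPerAF).

    The mean of the output over the normalization mask is 1 by
    construction.  Default mask: brain mask intersected with non-degenerate
    (QC-clean) voxels.
    """
    if peraf.kind != "peraf":
        raise ValueError("input must be a PerAF map")
    if mask is None:
        mask = _default_norm_mask(peraf)
        norm_mask_id = norm_mask_id or "brain∩nondegenerate"
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("normalization mask is empty")
    g = peraf.data[mask].mean()
    if g <= 0:
        raise ValueError(f"global mean PerAF is {g}; degenerate image")
    out = peraf.data / g
    out[~peraf.mask] = 0.0
    return AmplitudeMap(
        data=out,
        kind="mperaf",
        affine=peraf.affine,
        mask=peraf.mask.copy(),
        band=peraf.band,
        norm_mask_id=norm_mask_id,
        qc=peraf.qc,
    )


def peraf_pipeline(
    bold: BoldSeries,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    normalize: bool = True,
) -> AmplitudeMap:
    """detrend + band-pass -> PerAF -> (optionally) mPerAF."""
    filtered = detrend_bandpass(bold, low, high)
    peraf = compute_peraf(filtered)
    peraf.band = (low, high)
    if not normalize:
        return peraf
    return normalize_global_mean(peraf)
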