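"""BOLD time-series conditioning for registered rsfMRI data.

The pipeline order is trim -> nuisance regression -> spatial smoothing ->
band-pass, applied to already motion-corrected, template-registered data.
Every operation is linear in the data, touches only in-mask voxels, and is
recorded in the series' provenance list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

log = logging.getLogger(__name__)

#: FWHM of a Gaussian = SIGMA_PER_FWHM * sigma
SIGMA_PER_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class BoldSeries:
    """Masked 4D BOLD-like time series with voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Signal values. Outside-mask voxels are carried but never read or
        written by any operation.
    mask : ndarray of bool, shape (x, y, z)
        Brain mask; must be nonempty.
    voxel_size_mm : tuple of float
        Voxel edge lengths in mm, per axis.
    tr_s : float
        Repetition time in seconds.
    subject_id : str
    """

    data: np.ndarray
    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tr_s: float = 1.0
    subject_id: str = ""
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (x,y,z,t), got shape {self.data.shape}")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match spatial dims of data")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.isfinite(self.data[self.mask]).all():
            raise ValueError("non-finite values inside mask")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_s)

    def in_mask(self) -> np.ndarray:
        """Return the (n_voxels, t) array of in-mask time courses."""
        return self.data[self.mask]


@dataclass
class NuisanceSet:
    """Nuisance regressors: 6 rigid-motion traces plus mean ventricular signal."""

    motion: np.ndarray  # (t, 6): tx, ty, tz, rx, ry, rz
    ventricular: np.ndarray  # (t,)

    def __post_init__(self) -> None:
        self.motion = np.atleast_2d(np.asarray(self.motion, dtype=float))
        self.ventricular = np.asarray(self.ventricular, dtype=float).ravel()
        if self.motion.shape[1] != 6:
            raise ValueError(f"motion must have 6 columns, got {self.motion.shape[1]}")
        if self.motion.shape[0] != self.ventricular.shape[0]:
            raise ValueError("motion and ventricular lengths differ")

    @property
    def n_timepoints(self) -> int:
        return self.motion.shape[0]

    def trim(self, n_drop: int) -> "NuisanceSet":
        return NuisanceSet(self.motion[n_drop:], self.ventricular[n_drop:])

    def as_matrix(self) -> np.ndarray:
        """Regressor matrix (t, 7): 6 motion columns then ventricular."""
        return np.column_stack([self.motion, self.ventricular])


def trim_volumes(b: BoldSeries, n_drop: int) -> BoldSeries:
    """Drop the initial ``n_drop`` frames (signal-equilibration discard)."""
    if n_drop < 0:
        raise ValueError("n_drop must be nonnegative")
    if n_drop >= b.n_timepoints:
        raise ValueError(
            f"n_drop={n_drop} must be smaller than the series length {b.n_timepoints}"
        )
    return replace(
        b,
        data=b.data[..., n_drop:].copy(),
        provenance=b.provenance + [f"trim_volumes(n_drop={n_drop})"],
    )


def regress_nuisance(b: BoldSeries, nu: NuisanceSet) -> BoldSeries:
    """Residualize each in-mask voxel on [intercept, 6 motion, ventricular].

    Rank-deficient regressor matrices are handled by dropping collinear
    columns (QR pivoting on the centered regressors) with a logged warning;
    the intercept is always retained, so constant regressors are absorbed.
    """
    if nu.n_timepoints != b.n_timepoints:
        raise ValueError(
            f"nuisance length {nu.n_timepoints} != series length {b.n_timepoints}"
        )
    t = b.n_timepoints
    X = np.column_stack([np.ones(t), nu.as_matrix()])
    # Drop collinear columns so the OLS solution is the unique projection.
    q, r, piv = _qr_column_select(X)
    if len(piv) < X.shape[1]:
        dropped = sorted(set(range(X.shape[1])) - set(piv))
        log.warning("regress_nuisance: dropping collinear regressor columns %s", dropped)
        X = X[:, piv]
    Y = b.in_mask().T  # (t, n_voxels)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = b.data.copy()
    out[b.mask] = resid.T
    return replace(b, data=out, provenance=b.provenance + ["regress_nuisance"])


def _qr_column_select(X: np.ndarray, tol: float = 1e-10) -> tuple:
    """Pivoted-QR selection of a maximal independent column subset."""
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > tol * max(diag[0], 1.0)).sum()) if diag.size else 0
    keep = sorted(piv[:rank])
    return q, r, keep


def smooth_gaussian(b: BoldSeries, fwhm_mm: float) -> BoldSeries:
    """Mask-renormalized isotropic Gaussian smoothing of each frame.

    sigma = fwhm / (2 sqrt(2 ln 2)) per axis, converted from mm to voxels.
    The kernel average is taken over in-mask voxels only (the smoothed
    masked image is divided by the smoothed mask), so constants are
    conserved and edge voxels are not diluted by outside-mask zeros.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return replace(b, data=b.data.copy(), provenance=b.provenance + ["smooth_gaussian(fwhm=0)"])
    sigma_vox = [fwhm_mm / SIGMA_PER_FWHM / vs for vs in b.voxel_size_mm]
    m = b.mask.astype(float)
    # wide truncation: the discrete kernel matches the analytic Gaussian
    # to well below 1e-6 even in the tails
    trunc = 8.0
    norm = gaussian_filter(m, sigma_vox, mode="constant", truncate=trunc)
    out = b.data.copy()
    masked = np.where(b.mask[..., None], b.data, 0.0)
    for k in range(b.n_timepoints):
        sm = gaussian_filter(masked[..., k], sigma_vox, mode="constant",
                             truncate=trunc)
        frame = out[..., k]
        frame[b.mask] = sm[b.mask] / norm[b.mask]
    return replace(b, data=out, provenance=b.provenance + [f"smooth_gaussian(fwhm_mm={fwhm_mm})"])


def bandpass(b: BoldSeries, lo_hz: float, hi_hz: float) -> BoldSeries:
    """Ideal (hard) frequency-domain band-pass per voxel.

    DFT components with frequency in [lo_hz, hi_hz] are retained, all others
    — including DC — are zeroed, so the output is zero-mean per voxel.
    """
    nyq = b.nyquist_hz
    if not (0 <= lo_hz < hi_hz):
        raise ValueError(f"need 0 <= lo < hi, got lo={lo_hz}, hi={hi_hz}")
    if hi_hz > nyq:
        raise ValueError(
            f"hi_hz={hi_hz} exceeds the Nyquist frequency {nyq} Hz (TR={b.tr_s} s)"
        )
    t = b.n_timepoints
    freqs = np.fft.rfftfreq(t, d=b.tr_s)
    keep = (freqs >= lo_hz) & (freqs <= hi_hz)
    Y = b.in_mask()
    spec = np.fft.rfft(Y, axis=1)
    spec[:, ~keep] = 0.0
    out = b.data.copy()
    out[b.mask] = np.fft.irfft(spec, n=t, axis=1)
    return replace(b, data=out, provenance=b.provenance + [f"bandpass({lo_hz},{hi_hz})"])


def preprocess(
    b: BoldSeries,
    nu: NuisanceSet | None = None,
    n_drop: int = 50,
    fwhm_mm: float = 0.6,
    band: tuple[float, float] = (0.01, 0.1),
) -> BoldSeries:
    """Full conditioning chain: trim -> regress -> smooth -> bandpass.

    Defaults follow the reference protocol: drop 50 equilibration volumes,
    0.6 mm FWHM smoothing, 0.01–0.1 Hz band.
    """
    out = trim_volumes(b, n_drop) if n_drop else b
    if nu is not None:
        out = regress_nuisance(out, nu.trim(n_drop) if n_drop else nu)
    out = smooth_gaussian(out, fwhm_mm)
    out = bandpass(out, *band)
    return out
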