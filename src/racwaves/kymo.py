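"""Kymograph analytics: smoothing, autocorrelograms, correlations, PCA
phase alignment, phase portraits and spatial-noise spectra.

A kymograph is an intensity (or density) matrix ``I(Φ, t)`` sampled on a
uniform periodic angular grid ``Φ ∈ [0, 2π)`` and strictly increasing time
stamps.  The autocorrelogram

    ``A(ΔΦ, Δt) = ⟨δI(Φ+ΔΦ, t+Δt) δI(Φ, t)⟩_{Φ,t} / ⟨δI²⟩_{Φ,t}``

uses fluctuations ``δI = I − ⟨I⟩_Φ`` about the angular mean of each time
point; the angular lag wraps periodically while the temporal average is
truncated to the overlapping part of the record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import signal
from scipy.interpolate import make_smoothing_spline
from sklearn.decomposition import PCA

__all__ = [
    "Kymograph",
    "Autocorrelogram",
    "PhaseAlignment",
    "smooth_intensity",
    "autocorrelogram",
    "pearson_full",
    "sliding_pearson",
    "pca_align",
    "phase_portrait",
    "psd_noise",
    "interpolate_to_grid",
]


class DegenerateSignalError(ValueError):
    """The signal carries no angular structure (δI identically zero)."""


class AlignmentUnreliableWarning(UserWarning):
    pass


class NonClosingTrajectoryWarning(UserWarning):
    pass


@dataclass
class Kymograph:
    """Intensity matrix on an (n_t × m) time-by-angle grid."""

    values: np.ndarray          # (n_t, m)
    times: np.ndarray           # (n_t,), strictly increasing, s
    angles: np.ndarray          # (m,), uniform in [0, 2 pi)
    channel: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D (time x angle) matrix")
        n_t, m = self.values.shape
        if self.times.shape != (n_t,):
            raise ValueError("times length must match the number of rows")
        if self.angles.shape != (m,):
            raise ValueError("angles length must match the number of columns")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        step = 2.0 * np.pi / m
        if not np.allclose(np.diff(self.angles), step, rtol=1e-6, atol=1e-9):
            raise ValueError("angular grid must be uniform over [0, 2 pi)")

    @property
    def n_t(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.times)))

    @classmethod
    def from_matrix(cls, values, frame_interval: float = 1.0,
                    channel: str = "") -> "Kymograph":
        values = np.asarray(values, dtype=float)
        n_t, m = values.shape
        return cls(values, np.arange(n_t) * frame_interval,
                   np.arange(m) * 2.0 * np.pi / m, channel=channel)


@dataclass
class Autocorrelogram:
    """Normalized space-time autocorrelation A(ΔΦ, Δt)."""

    values: np.ndarray          # (n_dt, m) with A[lag 0] row index n_neg
    dphi: np.ndarray            # signed angular lags, (-pi, pi]
    dt: np.ndarray              # signed temporal lags, s

    def ridge_slope(self, max_lag: Optional[float] = None,
                    mode: Optional[int] = None) -> float:
        """Phase velocity dΦ/dt of the correlation ridge.

        The ridge position is read from the phase of the dominant angular
        harmonic ``B_n(Δt) = ⟨A(ΔΦ, Δt) e^{−inΔΦ}⟩_ΔΦ``: for a traveling
        ridge the phase advances linearly, while a standing pattern's
        ``B_n`` is real and merely flips sign, contributing (amplitude-
        weighted) zero net motion.  Per-lag phase increments are averaged
        with weights ``|B_n(Δt+δ) B_n(Δt)|`` so the ambiguous ±π jumps at
        the standing wave's nodes carry no weight; the result is the
        slope in rad/s over positive lags up to ``max_lag`` (default the
        full positive-lag range).
        """
        sel = self.dt >= 0
        if max_lag is not None:
            sel &= self.dt <= max_lag
        ts = self.dt[sel]
        if ts.size < 4:
            raise ValueError("too few temporal lags to estimate a ridge slope")
        A = self.values[sel]
        if mode is None:
            spec = np.abs(np.fft.fft(A[0]))
            half = A.shape[1] // 2
            mode = int(np.argmax(spec[1:half + 1])) + 1 if half >= 1 else 1
        B = A @ np.exp(-1j * mode * self.dphi) / self.dphi.size
        prod = B[1:] * np.conj(B[:-1])
        w = np.abs(prod)
        if w.sum() == 0:
            return 0.0
        dtheta = np.angle(prod)
        steps = np.diff(ts)
        slope_theta = float(np.sum(w * dtheta) / np.sum(w * steps))
        # harmonic phase theta = -omega * dt for a ridge moving at +omega/n
        return -slope_theta / mode

    def temporal_period(self) -> Optional[float]:
        """Temporal-lag first recurrence of A(0, Δt): the lag of the first
        local maximum after Δt = 0 (None when no recurrence exists)."""
        col = int(np.argmin(np.abs(self.dphi)))
        pos = self.dt >= 0
        a = self.values[pos, col]
        peaks, _ = signal.find_peaks(a)
        if peaks.size == 0:
            return None
        return float(self.dt[pos][peaks[0]])


def smooth_intensity(kymo: Kymograph, lam: Optional[float] = 1.0) -> Kymograph:
    """Cubic smoothing-spline fit along each axis of the kymograph.

    The angular axis is treated periodically (the record is padded with
    half a turn on each side before fitting and the central part kept).
    ``lam`` is the spline's roughness penalty; ``lam=0`` interpolates and
    returns the input unchanged.
    """
    I = kymo.values
    if not np.all(np.isfinite(I)):
        raise ValueError("kymograph contains non-finite values")
    if np.ptp(I) == 0.0:
        return Kymograph(I.copy(), kymo.times, kymo.angles, kymo.channel)
    if lam == 0:
        return Kymograph(I.copy(), kymo.times, kymo.angles, kymo.channel)
    n_t, m = I.shape
    pad = m // 2
    # spatial pass, periodic padding
    xpad = np.arange(-pad, m + pad, dtype=float)
    out = np.empty_like(I)
    for i in range(n_t):
        row = np.concatenate([I[i, m - pad:], I[i], I[i, :pad]])
        spl = make_smoothing_spline(xpad, row, lam=lam)
        out[i] = spl(np.arange(m, dtype=float))
    # temporal pass
    if n_t >= 4:
        for j in range(m):
            spl = make_smoothing_spline(kymo.times, out[:, j], lam=lam)
            out[:, j] = spl(kymo.times)
    return Kymograph(out, kymo.times, kymo.angles, kymo.channel)


def autocorrelogram(kymo: Kymograph, max_lag_frames: Optional[int] = None
                    ) -> Autocorrelogram:
    """Space-time autocorrelogram with angular-mean removal per time point,
    periodic angular wrap, and truncated temporal averaging."""
    I = kymo.values
    dI = I - I.mean(axis=1, keepdims=True)
    denom = np.mean(dI * dI)
    if denom <= 0 or not np.isfinite(denom):
        raise DegenerateSignalError(
            "signal has no angular structure; autocorrelogram undefined"
        )
    n_t, m = I.shape
    if max_lag_frames is None:
        max_lag_frames = n_t // 2
    max_lag_frames = min(max_lag_frames, n_t - 1)
    F = np.fft.fft(dI, axis=1)
    # circular cross-correlation over angle: C[t](k) = sum_phi dI(phi+k, t+l) dI(phi, t)
    pos = np.empty((max_lag_frames + 1, m))
    for l in range(max_lag_frames + 1):
        prod = np.fft.ifft(F[l:] * np.conj(F[: n_t - l]), axis=1).real
        pos[l] = prod.mean(axis=0) / m
    pos /= denom
    # assemble signed lags using A(-dphi, -dt) = A(dphi, dt)
    order = np.fft.fftshift(np.arange(m))          # map 0..m-1 -> signed order
    dphi = np.fft.fftshift(np.fft.fftfreq(m, d=1.0 / m)) * (2.0 * np.pi / m)
    pos_s = pos[:, order]
    # A(dphi, -dt) = A(-dphi, dt); negate each lag periodically (the -pi
    # column is its own mirror on an even grid)
    neg_s = pos[1:, (-order) % m][::-1]
    values = np.vstack([neg_s, pos_s])
    dts = np.concatenate([-np.arange(max_lag_frames, 0, -1), np.arange(max_lag_frames + 1)]) * kymo.dt
    return Autocorrelogram(values=values, dphi=dphi, dt=dts)


def _check_registered(k1: Kymograph, k2: Kymograph) -> None:
    if k1.values.shape != k2.values.shape:
        raise ValueError("kymographs must share a grid shape")
    if not (np.allclose(k1.times, k2.times) and np.allclose(k1.angles, k2.angles)):
        raise ValueError("kymographs must be co-registered on the same grid")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance channel: correlation undefined")
    return float(a @ b / (na * nb))


def pearson_full(kymo1: Kymograph, kymo2: Kymograph,
                 window: Optional[float] = 120.0) -> float:
    """Pearson correlation over all matrix elements within the first
    ``window`` seconds of the record (None = whole record)."""
    _check_registered(kymo1, kymo2)
    if window is None:
        sel = slice(None)
    else:
        sel = kymo1.times <= kymo1.times[0] + window
    return _pearson(kymo1.values[sel], kymo2.values[sel])


def sliding_pearson(kymo1: Kymograph, kymo2: Kymograph,
                    window: float = 10.0) -> Tuple[np.ndarray, np.ndarray]:
    """Per-window Pearson correlation over a sliding window (stride one
    frame).  Returns (window center times, r values)."""
    _check_registered(kymo1, kymo2)
    dt = kymo1.dt
    w = max(int(round(window / dt)), 2)
    n_t = kymo1.n_t
    if w > n_t:
        raise ValueError(
            f"window of {window} s ({w} frames) exceeds the record length"
        )
    centers = np.empty(n_t - w + 1)
    rs = np.empty(n_t - w + 1)
    for i in range(n_t - w + 1):
        rs[i] = _pearson(kymo1.values[i:i + w], kymo2.values[i:i + w])
        centers[i] = 0.5 * (kymo1.times[i] + kymo1.times[i + w - 1])
    return centers, rs


@dataclass
class PhaseAlignment:
    """Result of the two-channel PCA phase alignment."""

    Z: np.ndarray                   # standardized 2 n_t x m matrix
    projections: np.ndarray         # (m, 2): (c_1j, c_2j) per column
    phases: np.ndarray              # phi_j = atan2(c_2j, c_1j), (m,)
    period: float                   # T, s
    time_shifts: np.ndarray         # dt_j = -T phi_j / (2 pi), (m,)
    v1: np.ndarray                  # first principal axis, length 2 n_t
    v2: np.ndarray                  # second principal axis
    variance_fractions: np.ndarray  # all component variance ratios
    aligned_ch1: np.ndarray         # averaged channel profiles after shifting
    aligned_ch2: np.ndarray
    times: np.ndarray = field(default=None)


def _period_from_series(series: np.ndarray, times: np.ndarray) -> float:
    """Mean zero-crossing spacing of the mean-removed series (one crossing
    pair per period); spectral-peak fallback below 4 crossings."""
    s = series - series.mean()
    sign = np.sign(s)
    sign[sign == 0] = 1
    idx = np.where(np.diff(sign) != 0)[0]
    if idx.size >= 4:
        # linear interpolation of each crossing time
        tc = times[idx] - s[idx] * (times[idx + 1] - times[idx]) / (s[idx + 1] - s[idx])
        return 2.0 * float(np.mean(np.diff(tc)))
    dt = float(np.mean(np.diff(times)))
    freqs = np.fft.rfftfreq(s.size, d=dt)
    power = np.abs(np.fft.rfft(s)) ** 2
    k = int(np.argmax(power[1:])) + 1
    if freqs[k] == 0:
        raise ValueError("no oscillation detected; period undefined")
    return 1.0 / float(freqs[k])


def pca_align(kymo1: Kymograph, kymo2: Kymograph) -> PhaseAlignment:
    """Phase alignment of the angular positions of a two-channel record.

    The channels are concatenated vertically into a ``2 n_t × m`` matrix,
    each row standardized, and the m columns treated as samples in the
    2 n_t-dimensional time space.  The polar angle of each column in the
    plane of the first two principal components gives its oscillation
    phase ``φ_j``; the common period T is read from the first principal
    axis restricted to channel 1, and each column is shifted in time by
    ``Δt_j = −T φ_j / 2π`` before averaging into per-channel profiles.
    """
    _check_registered(kymo1, kymo2)
    X = np.vstack([kymo1.values, kymo2.values])
    sd = X.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("a constant row makes standardization impossible")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd
    m = Z.shape[1]
    pca = PCA(n_components=min(Z.shape))
    scores = pca.fit_transform(Z.T)          # (m, n_comp): projections c_kj
    projections = scores[:, :2]
    var = pca.explained_variance_ratio_
    if var[:2].sum() < 0.20:
        warnings.warn(
            "first two components carry less than 20% of the variance; "
            "phase alignment is unreliable",
            AlignmentUnreliableWarning,
        )
    phases = np.arctan2(projections[:, 1], projections[:, 0])
    v1 = pca.components_[0]
    v2 = pca.components_[1]
    n_t = kymo1.n_t
    period = _period_from_series(v1[:n_t], kymo1.times)
    shifts = -period * phases / (2.0 * np.pi)
    # shift each column by dt_j (circularly over an integer number of
    # periods) and average the per-channel profiles
    dt = kymo1.dt
    frames_per_T = period / dt
    aligned1 = np.zeros(n_t)
    aligned2 = np.zeros(n_t)
    idx = np.arange(n_t, dtype=float)
    for j in range(m):
        k = shifts[j] / dt
        src = np.mod(idx - k, frames_per_T)
        src = np.clip(src, 0, n_t - 1)
        aligned1 += np.interp(src, idx, kymo1.values[:, j])
        aligned2 += np.interp(src, idx, kymo2.values[:, j])
    aligned1 /= m
    aligned2 /= m
    return PhaseAlignment(
        Z=Z, projections=projections, phases=phases, period=float(period),
        time_shifts=shifts, v1=v1, v2=v2, variance_fractions=var,
        aligned_ch1=aligned1, aligned_ch2=aligned2, times=kymo1.times,
    )


def phase_portrait(ch1: np.ndarray, ch2: np.ndarray) -> dict:
    """Orientation of the closed (ch1, ch2) trajectory from the shoelace
    signed area: positive area = counterclockwise."""
    x = np.asarray(ch1, dtype=float)
    y = np.asarray(ch2, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length series of at least 3 points")
    gap = np.hypot(x[-1] - x[0], y[-1] - y[0])
    diam = np.hypot(np.ptp(x), np.ptp(y))
    if diam == 0:
        raise ValueError("degenerate trajectory (single point)")
    if gap > 0.10 * diam:
        warnings.warn(
            f"trajectory does not close (gap {gap / diam:.0%} of diameter)",
            NonClosingTrajectoryWarning,
        )
    area = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    return {
        "trajectory": np.column_stack([x, y]),
        "signed_area": area,
        "orientation": "counterclockwise" if area > 0 else "clockwise",
    }


def psd_noise(kymo: Kymograph, fc: float = 0.15,
              sample_length: Optional[float] = None) -> dict:
    """Spatial noise spectrum of a raw kymograph.

    Per the variance-stabilizing convention for count-like intensities the
    square root of the raw values is taken, a 4th-order high-pass
    Butterworth at ``fc`` cycles per grid step is applied along the
    angular axis with zero-phase forward-backward filtering, and the
    single-sided PSD ``(2/N)|FFT|²`` of each time point is averaged over
    the record.  Frequencies are reported per grid step and, when
    ``sample_length`` (grid step in μm) is given, per μm.
    """
    I = kymo.values
    if np.any(I < 0):
        raise ValueError("raw intensities must be non-negative")
    m = kymo.m
    if m < 8:
        raise ValueError("need at least 8 spatial points")
    root = np.sqrt(I)
    b, a = signal.butter(4, fc / 0.5, btype="highpass")
    filtered = signal.filtfilt(b, a, root, axis=1)
    spec = np.abs(np.fft.rfft(filtered, axis=1)) ** 2 / m * 2.0
    spec[:, 0] /= 2.0
    if m % 2 == 0:
        spec[:, -1] /= 2.0
    psd = spec.mean(axis=0)
    freq = np.fft.rfftfreq(m, d=1.0)
    out = {
        "freq_per_sample": freq,
        "psd": psd,
        "filtered": filtered,
        "cutoff_per_sample": fc,
    }
    if sample_length is not None:
        out["freq_per_um"] = freq / sample_length
        out["psd_per_um"] = psd * sample_length
        out["cutoff_per_um"] = fc / sample_length
    return out


def interpolate_to_grid(angles: np.ndarray, values: np.ndarray,
                        times: np.ndarray, m: int) -> Kymograph:
    """Periodic linear interpolation of per-frame irregular angular samples
    onto a uniform m-point grid.

    ``angles`` and ``values`` are (n_t, n_samples) arrays (angles may vary
    per frame); duplicate angles within a frame are rejected.
    """
    angles = np.mod(np.asarray(angles, dtype=float), 2.0 * np.pi)
    values = np.asarray(values, dtype=float)
    if angles.ndim == 1:
        angles = np.broadcast_to(angles, values.shape)
    if angles.shape != values.shape:
        raise ValueError("angles and values must have matching shapes")
    if angles.shape[1] < 4:
        raise ValueError("need at least 4 samples per frame")
    grid = np.arange(m) * 2.0 * np.pi / m
    out = np.empty((values.shape[0], m))
    for i in range(values.shape[0]):
        order = np.argsort(angles[i])
        a = angles[i, order]
        v = values[i, order]
        if np.any(np.diff(a) == 0):
            raise ValueError(f"duplicate angular positions in frame {i}")
        # periodic extension: one sample on each side across the seam
        a_ext = np.concatenate([[a[-1] - 2 * np.pi], a, [a[0] + 2 * np.pi]])
        v_ext = np.concatenate([[v[-1]], v, [v[0]]])
        out[i] = np.interp(grid, a_ext, v_ext)
    return Kymograph(out, np.asarray(times, dtype=float), grid)
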