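"""IR spectra from dipole-moment autocorrelation functions.

The spectrum is the Fourier transform of the dipole autocorrelation
C(τ) = ⟨μ(t)·μ(t+τ)⟩: the ACF is tapered with the classic three-term
Blackman window (a₀ = 0.42, a₁ = 0.5, a₂ = 0.08), extended symmetrically,
zero-padded, FFT'd, and the real part multiplied by the harmonic quantum
correction factor βħω/(1 − e^{−βħω}) with β = 1/(kB T).

Conventions (documented, not tunable hard-coded): the static mean dipole is
subtracted before correlating (suppresses the zero-frequency artifact); the
ACF estimator uses biased normalization (divide by N), which keeps it
positive semi-definite and |C(τ)| ≤ C(0); default maximum lag is a quarter
of the series with 4× zero-padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import C_CM_PER_FS, HC_OVER_KB_CM_K

__all__ = [
    "DipoleSeries",
    "Acf",
    "Spectrum",
    "SpectrumParams",
    "SpectroscopyError",
    "dipole_acf",
    "quantum_correction",
    "ir_spectrum",
    "peak_metrics",
]


class SpectroscopyError(ValueError):
    pass


@dataclass(frozen=True)
class DipoleSeries:
    """Time series of dipole 3-vectors sampled at a fixed interval (fs)."""

    values: np.ndarray  # (n, 3)
    timestep: float     # fs
    source: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 2:
            raise SpectroscopyError(
                f"dipole series must be (n >= 2, 3), got {v.shape}"
            )
        if self.timestep <= 0:
            raise SpectroscopyError(f"timestep must be > 0 fs, got {self.timestep}")
        if not np.all(np.isfinite(v)):
            raise SpectroscopyError("non-finite dipole components")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class Acf:
    """Autocorrelation ⟨μ(0)·μ(τ)⟩ on a uniform lag grid."""

    lags: np.ndarray    # fs
    values: np.ndarray  # units of μ²
    timestep: float     # fs


@dataclass(frozen=True)
class Spectrum:
    """Intensity on a uniform wavenumber grid (cm⁻¹)."""

    wavenumbers: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def grid_spacing(self) -> float:
        return float(self.wavenumbers[1] - self.wavenumbers[0])


@dataclass(frozen=True)
class SpectrumParams:
    """Windowing/correction parameters for the ACF → spectrum transform."""

    temperature: float = 300.0       # K
    max_lag: float | None = None     # fs; default: quarter of the series span
    zero_padding: int = 4            # FFT length multiplier
    window: str = "blackman"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise SpectroscopyError("temperature must be > 0 K")
        if self.zero_padding < 1:
            raise SpectroscopyError("zero-padding factor must be >= 1")


def dipole_acf(series: DipoleSeries, max_lag: float | None = None) -> Acf:
    """FFT-based estimator of C(τ) = ⟨μ(t)·μ(t+τ)⟩, mean removed.

    Biased normalization: the lag-τ sum over time origins is divided by the
    full series length N regardless of overlap.  ``max_lag`` (fs) defaults
    to a quarter of the series span.
    """
    n = series.n_samples
    dt = series.timestep
    span = (n - 1) * dt
    if max_lag is None:
        max_lag = span / 4.0
    if max_lag > span + 1e-9:
        raise SpectroscopyError(
            f"max_lag {max_lag} fs exceeds series span {span} fs"
        )
    n_lags = int(round(max_lag / dt))
    mu = series.values - series.values.mean(axis=0)
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    F = np.fft.rfft(mu, n=nfft, axis=0)
    acf_full = np.fft.irfft((F * F.conj()).sum(axis=1), n=nfft)[: n_lags + 1]
    acf = acf_full.real / n
    lags = np.arange(n_lags + 1) * dt
    return Acf(lags=lags, values=acf, timestep=dt)


def quantum_correction(
    wavenumber: np.ndarray | float, temperature: float
) -> np.ndarray | float:
    """Harmonic quantum correction x/(1 − e^{−x}) with x = hcν̃/(kB T).

    Continuous at ν̃ = 0 (factor → 1); ≥ 1 everywhere, increasing in ν̃ and
    decreasing in T.
    """
    if temperature <= 0:
        raise SpectroscopyError("temperature must be > 0 K")
    nu = np.asarray(wavenumber, dtype=float)
    if np.any(nu < 0):
        raise SpectroscopyError("wavenumber must be >= 0")
    x = HC_OVER_KB_CM_K * nu / temperature
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(x > 1e-10, x / (1.0 - np.exp(-x)), 1.0 + x / 2.0)
    return float(factor) if np.isscalar(wavenumber) else factor


def _one_sided_blackman(n_points: int) -> np.ndarray:
    """Decaying half of the classic Blackman window: w[0] = 1, w[-1] ≈ 0."""
    return np.blackman(2 * n_points - 1)[n_points - 1 :]


def ir_spectrum(acf: Acf, params: SpectrumParams = SpectrumParams()) -> Spectrum:
    """Spectrum of a windowed ACF with quantum correction.

    The one-sided ACF over [0, max lag] is tapered, reflected to an even
    signal, zero-padded by ``params.zero_padding``, and FFT'd; the intensity
    is the real part times the quantum correction per bin.  The wavenumber
    grid spacing is 1/(c·N·dt) for FFT length N.
    """
    c = np.asarray(acf.values, dtype=float)
    if not np.all(np.isfinite(c)):
        raise SpectroscopyError("NaN/Inf in ACF")
    n_lags = c.size - 1
    if params.max_lag is not None:
        keep = int(round(params.max_lag / acf.timestep))
        if keep > n_lags:
            raise SpectroscopyError("params.max_lag exceeds the ACF lag range")
        c = c[: keep + 1]
        n_lags = keep
    if n_lags < 1:
        raise SpectroscopyError("ACF must contain at least two lags")
    if params.window == "blackman":
        w = _one_sided_blackman(n_lags + 1)
    elif params.window in ("none", "rect", "boxcar"):
        w = np.ones(n_lags + 1)
    else:
        raise SpectroscopyError(f"unknown window {params.window!r}")
    cw = c * w

    nfft = params.zero_padding * 2 * n_lags
    f = np.zeros(nfft)
    f[: n_lags + 1] = cw
    f[-n_lags:] = cw[1:][::-1]  # even extension
    F = np.fft.rfft(f)
    wavenumbers = np.fft.rfftfreq(nfft, d=acf.timestep) / C_CM_PER_FS
    qc = quantum_correction(wavenumbers, params.temperature)
    intensity = F.real * qc
    return Spectrum(
        wavenumbers=wavenumbers,
        intensity=intensity,
        metadata={
            "window": params.window,
            "temperature_K": params.temperature,
            "resolution_cm-1": float(wavenumbers[1]),
            "n_lags": n_lags,
            "zero_padding": params.zero_padding,
        },
    )


def peak_metrics(
    spectrum: Spectrum, band: tuple[float, float]
) -> tuple[float, float]:
    """Peak position and FWHM (both cm⁻¹) of the maximum within a band.

    The argmax is refined by 3-point parabolic interpolation; the FWHM comes
    from linear interpolation of the half-maximum crossings on either side
    of the peak.  A peak whose half-maximum level never crosses within the
    grid, or a band with no interior maximum, raises SpectroscopyError.  A
    δ-like single-bin peak reports one grid spacing as its width.
    """
    lo, hi = band
    nu = spectrum.wavenumbers
    I = spectrum.intensity
    sel = np.flatnonzero((nu >= lo) & (nu <= hi))
    if sel.size < 3:
        raise SpectroscopyError("band contains fewer than 3 grid points")
    k = sel[np.argmax(I[sel])]
    if k == sel[0] or k == sel[-1]:
        raise SpectroscopyError("no interior maximum in the band")
    dnu = spectrum.grid_spacing
    y0, y1, y2 = I[k - 1], I[k], I[k + 1]
    denom = y0 - 2 * y1 + y2
    shift = 0.5 * (y0 - y2) / denom if abs(denom) > 0 else 0.0
    nu_max = nu[k] + shift * dnu
    peak_height = y1 - 0.25 * (y0 - y2) * shift if abs(denom) > 0 else y1
    half = peak_height / 2.0

    # walk outwards to the half-maximum crossings
    left = k
    while left > 0 and I[left] > half:
        left -= 1
    right = k
    while right < I.size - 1 and I[right] > half:
        right += 1
    if I[left] > half or I[right] > half:
        raise SpectroscopyError("half maximum not reached within the grid")
    if left == k and right == k:
        return float(nu_max), float(dnu)

    def _cross(i_lo: int, i_hi: int) -> float:
        y_lo, y_hi = I[i_lo], I[i_hi]
        if y_hi == y_lo:
            return float(nu[i_lo])
        frac = (half - y_lo) / (y_hi - y_lo)
        return float(nu[i_lo] + frac * (nu[i_hi] - nu[i_lo]))

    nu_left = _cross(left, left + 1)
    nu_right = _cross(right, right - 1)
    fwhm = abs(nu_right - nu_left)
    if fwhm == 0.0:
        fwhm = float(dnu)  # single-bin peak convention
    return float(nu_max), float(fwhm)
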