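"""Static linear-nonlinear (LN) gain model of the population input-output map.

The linear stage is estimated spectrally: the transfer function T_Nz is
the ratio of the cross power spectral density of the count series N and
the binary output z over the power spectral density of N.  Its inverse
DFT gives a raw impulse response C.  Because the pointwise nonlinearity
is a static logistic, Bussgang's theorem for Gaussian input says the
cross-correlation through the nonlinearity scales the autocovariance by
alpha = E[X g(X)]/var(X); dividing C by alpha corrects the filter, and
the gain series is z(t) = logistic((C' * N)(t)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.special import expit

from .coding import BinaryCode, CountSeries

__all__ = [
    "SpectralConfig",
    "GainModel",
    "GainSeries",
    "transfer_function_estimate",
    "bussgang_alpha",
    "fit_gain_model",
    "gain_series",
    "band_power",
    "DEFAULT_BANDS",
]

DEFAULT_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, np.inf),
}


@dataclass(frozen=True)
class SpectralConfig:
    """Welch settings used for every spectral estimate (series of ~100 samples)."""

    nperseg: int = 32
    overlap: float = 0.5
    window: str = "hann"

    def noverlap(self, nperseg: int) -> int:
        return int(round(self.overlap * nperseg))


@dataclass(frozen=True)
class GainModel:
    """Fitted LN-cascade linear stage.

    T_Nz is the complex transfer-function estimate per (one-sided)
    frequency bin, C its inverse DFT, alpha the Bussgang scale and
    C' = C/alpha the corrected filter.
    """

    freqs: np.ndarray
    T_Nz: np.ndarray
    C: np.ndarray
    alpha: float
    regularized: bool = False

    @property
    def C_corrected(self) -> np.ndarray:
        return self.C / self.alpha


@dataclass(frozen=True)
class GainSeries:
    """Logistic gain z(t) in (0, 1), plus the residual against an observed output."""

    z: np.ndarray
    residual: np.ndarray | None = None


def transfer_function_estimate(
    N: CountSeries | np.ndarray,
    z: BinaryCode | np.ndarray,
    spec: SpectralConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Welch transfer-function estimate T_Nz = P_Nz / P_NN.

    The binary output is mean-centered before estimation so its DC mass
    does not dominate the ratio.  Bins where N has (numerically) zero
    power are regularized with eps = 1e-12 * max power; the returned flag
    reports whether any bin needed it.

    Returns ``(freqs, T, regularized)`` with ``freqs`` in cycles per
    sample (multiply by 1/dt for Hz).
    """
    cfg = spec or SpectralConfig()
    n_vals = N.values if isinstance(N, CountSeries) else np.asarray(N, dtype=float)
    z_vals = z.bits.astype(float) if isinstance(z, BinaryCode) else np.asarray(z, dtype=float)
    if n_vals.size != z_vals.size:
        raise ValueError("N and z must have equal lengths")
    if n_vals.size < 32:
        raise ValueError("need at least 32 samples for a spectral estimate")
    nperseg = min(cfg.nperseg, n_vals.size)
    n_c = n_vals - n_vals.mean()
    z_c = z_vals - z_vals.mean()
    kw = dict(fs=1.0, window=cfg.window, nperseg=nperseg, noverlap=cfg.noverlap(nperseg))
    freqs, p_nz = signal.csd(n_c, z_c, **kw)
    _, p_nn = signal.welch(n_c, **kw)
    eps = 1e-12 * float(np.max(p_nn)) if np.max(p_nn) > 0 else 1e-30
    regularized = bool(np.any(p_nn <= eps))
    T = p_nz / (p_nn + eps)
    return freqs, T, regularized


def bussgang_alpha(X: np.ndarray, g=expit) -> float:
    """Bussgang scale alpha = Cov(X, g(X)) / Var(X).

    For zero-mean Gaussian X this is the factor by which the static
    nonlinearity g scales the autocovariance; with g the identity it is
    exactly 1, and in the small-signal limit it tends to g'(0).
    """
    X = np.asarray(X, dtype=float)
    var = float(np.var(X))
    if var <= 0:
        raise ValueError("Bussgang scale undefined for constant input")
    xc = X - X.mean()
    return float(np.mean(xc * g(X)) / var)


def fit_gain_model(
    N: CountSeries | np.ndarray,
    z: BinaryCode | np.ndarray,
    spec: SpectralConfig | None = None,
) -> GainModel:
    """Estimate the full LN linear stage: T_Nz, raw filter C, Bussgang alpha."""
    freqs, T, regularized = transfer_function_estimate(N, z, spec)
    C = np.fft.irfft(T, n=2 * (T.size - 1))
    n_vals = N.values if isinstance(N, CountSeries) else np.asarray(N, dtype=float)
    X = np.convolve(n_vals, C)[: n_vals.size]
    alpha = bussgang_alpha(X)
    return GainModel(freqs=freqs, T_Nz=T, C=C, alpha=alpha, regularized=regularized)


def gain_series(
    N: CountSeries | np.ndarray,
    model: GainModel,
    observed: BinaryCode | np.ndarray | None = None,
) -> GainSeries:
    """Gain z(t) = logistic((C' * N)(t)), full linear convolution truncated
    to the series length; strictly inside (0, 1)."""
    n_vals = N.values if isinstance(N, CountSeries) else np.asarray(N, dtype=float)
    X = np.convolve(n_vals, model.C_corrected)[: n_vals.size]
    zhat = expit(X)
    residual = None
    if observed is not None:
        obs = observed.bits.astype(float) if isinstance(observed, BinaryCode) else np.asarray(observed, dtype=float)
        residual = obs - zhat
    return GainSeries(z=zhat, residual=residual)


def band_power(
    z: GainSeries | np.ndarray,
    dt: float = 0.05,
    bands: dict[str, tuple[float, float]] | None = None,
    spec: SpectralConfig | None = None,
) -> dict[str, float]:
    """Integrated Welch power of the mean-removed gain over EEG-style bands.

    Bands extending past the Nyquist frequency (10 Hz at dt = 0.05 s) are
    truncated there; a band entirely above Nyquist is absent from the
    result.  Series shorter than 64 samples are zero-padded.
    """
    cfg = spec or SpectralConfig()
    vals = z.z if isinstance(z, GainSeries) else np.asarray(z, dtype=float)
    vals = vals - vals.mean()
    if vals.size < 64:
        vals = np.pad(vals, (0, 64 - vals.size))
    fs = 1.0 / dt
    nperseg = min(cfg.nperseg, vals.size)
    freqs, pxx = signal.welch(
        vals, fs=fs, window=cfg.window, nperseg=nperseg, noverlap=cfg.noverlap(nperseg)
    )
    nyq = fs / 2.0
    out: dict[str, float] = {}
    for name, (lo, hi) in (bands or DEFAULT_BANDS).items():
        if lo >= nyq:
            continue
        hi = min(hi, nyq)
        mask = (freqs >= lo) & (freqs <= hi)
        if mask.sum() < 2:
            # single-bin band: report the bin's power mass
            out[name] = float(pxx[mask].sum() * (freqs[1] - freqs[0])) if mask.any() else 0.0
        else:
            out[name] = float(np.trapezoid(pxx[mask], freqs[mask]))
    return out
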