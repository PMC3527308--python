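"""Continuous Morlet wavelet power spectrum (Torrence & Compo conventions).

The transform localises spectral power in time, so it can reveal, e.g., a
series whose dominant periodicity shifts from one year to two.  Conventions
follow the standard geophysical reference implementation: the series is
mean-removed and zero-padded to the next power of two; daughter wavelets
are built in the frequency domain from the analytic Morlet spectrum
(omega0 = 6) at scales s_j = s0 * 2^(j*dj); power is |W|^2; the Fourier
period is s * 4*pi / (omega0 + sqrt(2 + omega0^2)) ~ 1.033 s; and the cone
of influence (COI) marks where edge effects (e-folding time sqrt(2)*s)
corrupt the estimate.

Missing values are refused, not imputed — wavelet power is sensitive to the
imputation scheme, so that choice belongs to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WaveletResult", "morlet_cwt", "global_spectrum"]

OMEGA0 = 6.0
#: period / scale for the Morlet with omega0 = 6
FOURIER_FACTOR = 4 * np.pi / (OMEGA0 + np.sqrt(2 + OMEGA0**2))


@dataclass
class WaveletResult:
    power: np.ndarray     # scales x time, series-variance units
    periods: np.ndarray   # Fourier period per scale (same time units as dt)
    scales: np.ndarray
    coi: np.ndarray       # max trustworthy period per time point (0 at ends)
    times: np.ndarray     # sample times (k * dt)
    params: dict


def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1)).bit_length()


def morlet_daughter_spectra(n_fft: int, dt: float,
                            scales: np.ndarray) -> np.ndarray:
    """Analytic Morlet (omega0=6) daughter spectra sampled on the DFT grid.

    Rows are scales, columns DFT frequency bins; only positive frequencies
    are populated (the Morlet is analytic).  Normalised so each daughter has
    unit energy at every scale.
    """
    k = np.fft.fftfreq(n_fft, d=dt) * 2 * np.pi    # angular frequencies
    pos = k > 0
    psi = np.zeros((len(scales), n_fft))
    norm = np.sqrt(2 * np.pi * scales / dt) * np.pi**-0.25
    for j, s in enumerate(scales):
        psi[j, pos] = norm[j] * np.exp(-0.5 * (s * k[pos] - OMEGA0)**2)
    return psi


def morlet_cwt(y, dt: float, s0: float | None = None, dj: float = 0.25,
               J: int | None = None) -> WaveletResult:
    """Morlet continuous wavelet transform power of a gap-free series.

    Parameters
    ----------
    y : series values; must contain no missing values (interpolate or
        smooth first — the module will not choose an imputation for you).
    dt : sampling interval in years (1/12 for monthly data).
    s0 : smallest scale, default 2*dt.
    dj : scale resolution in octave fractions, default 0.25.
    J : number of scale steps; default spans from s0 to the series length.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("series contains missing values; interpolate or "
                         "smooth before the wavelet transform")
    n = len(y)
    if n < 16:
        raise ValueError(f"series too short for a wavelet spectrum "
                         f"({n} < 16 points)")
    if dt <= 0:
        raise ValueError("sampling interval dt must be positive")
    s0 = 2 * dt if s0 is None else float(s0)
    if J is None:
        J = int(np.floor(np.log2(n * dt / s0) / dj))
    scales = s0 * 2.0 ** (dj * np.arange(J + 1))

    n_fft = _next_pow2(n)
    x = np.zeros(n_fft)
    x[:n] = y - y.mean()
    xhat = np.fft.fft(x)
    psi = morlet_daughter_spectra(n_fft, dt, scales)
    W = np.fft.ifft(xhat[None, :] * psi, axis=1)[:, :n]
    power = np.abs(W) ** 2
    periods = FOURIER_FACTOR * scales
    # COI: the largest trustworthy period at each time = (distance to the
    # nearest edge) / sqrt(2) scales, expressed as a period; zero at the ends
    edge = np.minimum(np.arange(n), np.arange(n)[::-1]).astype(float)
    coi = FOURIER_FACTOR / np.sqrt(2) * dt * edge
    return WaveletResult(power=power, periods=periods, scales=scales,
                         coi=coi, times=np.arange(n) * dt,
                         params=dict(dt=dt, s0=s0, dj=dj, J=J,
                                     mother="morlet", omega0=OMEGA0,
                                     n=n, n_fft=n_fft))


def global_spectrum(result: WaveletResult) -> np.ndarray:
    """Time-averaged power per scale, using only points inside the cone of
    influence; scales with no interior point report 0."""
    out = np.zeros(len(result.periods))
    for j, period in enumerate(result.periods):
        inside = result.coi > period
        if inside.any():
            out[j] = result.power[j, inside].mean()
    return out
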