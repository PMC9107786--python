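"""Continuous wavelet smoothing of discrete phenological time series.

Field phenology records are discrete and frequently gappy; the diversity
measure downstream needs continuous-over-time curves. Each series is
decomposed with a continuous wavelet transform (analytic Morlet kernel by
default, center frequency omega0 = 6), a subset of scales selected by the
attenuation threshold tau is retained, and the smoothed curve is rebuilt
as the column-wise (over scales) sum of the real coefficient parts with
the standard 1/sqrt(scale) inverse-transform weights, plus the series
mean. Negative reconstructed values are clipped to zero because the
curves are intensities and the overlap distance is only bounded on
nonnegative curves.

tau semantics
-------------
tau controls how many fine scales survive: scales ``s >= s_max/(1+tau)``
are retained, where ``s_max`` is the coarsest analyzed scale. tau -> 0
keeps only the coarsest scale (a highly smoothed curve); tau -> infinity
keeps the whole ladder, and the reconstruction approaches the raw series.
tau = 2 is the conventional default.

The transform uses symmetric (reflection) padding of one series length on
each side, computed in the frequency domain, and is cropped back after.
The reconstruction factor is calibrated numerically from the mid-band
plateau of the summed kernel response on the same scale ladder, which
makes the full-ladder inverse transform accurate to about a percent
regardless of kernel choice or ladder density.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .io import CommunityPhenology, PhenologyCurve

__all__ = [
    "SmoothingConfig",
    "WaveletDecomposition",
    "decompose",
    "smooth_curve",
    "smooth_community",
    "LengthError",
    "ConfigError",
    "DegenerateCommunityError",
]

logger = logging.getLogger("phenodiv")

MORLET_OMEGA0 = 6.0
MIN_SERIES_LENGTH = 8

SUPPORTED_WAVELETS = ("morlet", "mexican_hat")


class LengthError(ValueError):
    """Series too short for multi-scale analysis."""


class ConfigError(ValueError):
    """Unsupported smoothing configuration."""


class DegenerateCommunityError(ValueError):
    """Community reduced below two usable species."""


@dataclass(frozen=True)
class SmoothingConfig:
    """Parameters of the wavelet smoothing stage.

    scaling_function : "morlet" (default) or "mexican_hat"
    tau : attenuation threshold, > 0; larger keeps more fine-scale detail
    scales_per_octave : density of the dyadic scale ladder
    """

    scaling_function: str = "morlet"
    tau: float = 2.0
    scales_per_octave: int = 12

    def __post_init__(self) -> None:
        if self.scaling_function not in SUPPORTED_WAVELETS:
            raise ConfigError(
                f"unsupported scaling function {self.scaling_function!r}; "
                f"supported: {', '.join(SUPPORTED_WAVELETS)}"
            )
        if not self.tau > 0:
            raise ConfigError(f"tau must be positive, got {self.tau}")
        if int(self.scales_per_octave) < 1:
            raise ConfigError("scales_per_octave must be a positive integer")


@dataclass(frozen=True)
class WaveletDecomposition:
    """Scale x time coefficient matrix of one curve's transform."""

    coefficients: np.ndarray  # (n_scales, n_times), complex
    scales: np.ndarray  # (n_scales,)

    def __post_init__(self) -> None:
        if self.coefficients.shape[0] != self.scales.size:
            raise ValueError("coefficient rows must match number of scales")


def _fourier_kernel(name: str, s_omega: np.ndarray) -> np.ndarray:
    """Fourier-domain mother wavelet evaluated at scale*angular-frequency."""
    if name == "morlet":
        out = np.zeros_like(s_omega)
        pos = s_omega > 0
        out[pos] = math.pi ** -0.25 * np.exp(-0.5 * (s_omega[pos] - MORLET_OMEGA0) ** 2)
        return out
    if name == "mexican_hat":
        # second-derivative-of-Gaussian kernel
        m = 2
        norm = 1.0 / math.sqrt(math.gamma(m + 0.5))
        return norm * s_omega**m * np.exp(-0.5 * s_omega**2)
    raise ConfigError(f"unsupported scaling function {name!r}")


#: extra octaves above the in-band top (series length) holding the
#: boundary-trend content of the even extension; always retained
TREND_OCTAVES = 2


def _scale_ladder(n: int, dt: float, per_octave: int) -> np.ndarray:
    """Dyadic ladder from 2*dt upward with `per_octave` scales per octave.

    The in-band part spans 2*dt .. n*dt; two further octaves of coarse
    "trend" scales are appended because the even (reflection) extension
    of the series is 2n-periodic, and representing its fundamental needs
    scales past the band top.
    """
    s0 = 2.0 * dt
    octaves = math.log2(n / 2.0) + TREND_OCTAVES
    j = np.arange(math.floor(octaves * per_octave) + 1)
    return s0 * 2.0 ** (j / per_octave)


def _cwt_padded(values: np.ndarray, dt: float, scales: np.ndarray, name: str) -> np.ndarray:
    """Transform of the demeaned series under symmetric (reflection)
    boundary handling; returns (n_scales, n) coefficients.

    The reflection is applied as an exact even-periodic extension of
    period 2n evaluated circularly, so the kernels see no window-edge
    leakage and the column-sum inverse is near-exact on the full ladder.
    """
    n = values.size
    x = values - values.mean()
    padded = np.concatenate([x, x[::-1]])
    xhat = np.fft.fft(padded)
    omega = 2.0 * math.pi * np.fft.fftfreq(2 * n, d=dt)
    coefs = np.empty((scales.size, n), dtype=complex)
    for k, s in enumerate(scales):
        kernel = math.sqrt(2.0 * math.pi * s / dt) * _fourier_kernel(name, s * omega)
        coefs[k] = np.fft.ifft(xhat * kernel)[:n]
    return coefs


def _reconstruction_gain(n: int, dt: float, scales: np.ndarray, name: str) -> float:
    """Mid-band gain of the summed kernel response, used to normalize the
    column-sum reconstruction.

    Summing kernel(s*omega)/sqrt(s) over a dense dyadic ladder gives a
    frequency response that is flat across the analyzed band; dividing
    the reconstruction by half that plateau (half, because only the real
    part of the analytic transform is kept) makes the full-ladder
    inverse accurate to ~1% for in-band signals. Evaluated at the
    geometric mid-band frequency, away from both band edges."""
    omega_star = 2.0 * math.pi / (math.sqrt(2.0 * n) * dt)
    total = 0.0
    for s in scales:
        total += (
            math.sqrt(2.0 * math.pi * s / dt)
            * float(_fourier_kernel(name, np.array([s * omega_star]))[0])
            / math.sqrt(s)
        )
    # analytic (one-sided) kernels contribute only half their plateau to
    # the real part; real two-sided kernels contribute it in full
    return total / 2.0 if name == "morlet" else total


def decompose(curve: PhenologyCurve, cfg: SmoothingConfig | None = None) -> WaveletDecomposition:
    """Full scale-by-time wavelet coefficient matrix of a raw curve.

    The scale ladder is dyadic with ``cfg.scales_per_octave`` rungs per
    octave: an in-band part spanning 2*step .. (series length)*step plus
    two octaves of coarser trend scales that carry the boundary-trend
    content of the reflected extension. Series shorter than 8 points
    cannot support multi-scale analysis and are rejected (25+ points are
    recommended in practice).
    """
    cfg = cfg or SmoothingConfig()
    if curve.stage != "raw":
        raise ValueError("decompose expects a raw curve")
    n = curve.values.size
    if n < MIN_SERIES_LENGTH:
        raise LengthError(f"series of length {n} is too short (need >= {MIN_SERIES_LENGTH})")
    dt = 1.0  # scales are handled in units of the grid step
    scales = _scale_ladder(n, dt, int(cfg.scales_per_octave))
    coefs = _cwt_padded(curve.values, dt, scales, cfg.scaling_function)
    return WaveletDecomposition(coefs, scales)


def _retained(scales: np.ndarray, tau: float, band_top: float) -> np.ndarray:
    """Low-pass scale selection: keep scales >= band_top/(1+tau).

    band_top is the coarsest in-band scale (series length x step); the
    trend scales above it always satisfy the cutoff. tau -> 0 keeps only
    the coarsest scales, tau -> infinity keeps the whole ladder."""
    cutoff = band_top / (1.0 + tau)
    return scales >= cutoff


def smooth_curve(
    curve: PhenologyCurve, cfg: SmoothingConfig | None = None, *, clip: bool = True
) -> PhenologyCurve:
    """Smooth one raw curve.

    Reconstruction sums Re(W(s, t))/sqrt(s) over the scales retained by
    tau, divides by the impulse-calibrated normalization of the *full*
    ladder, and restores the series mean. ``clip=False`` disables the
    nonnegativity clip (the reconstruction is then exactly linear in the
    input, which is useful for diagnostics).
    """
    cfg = cfg or SmoothingConfig()
    dec = decompose(curve, cfg)
    n = curve.values.size
    calib = _reconstruction_gain(n, 1.0, dec.scales, cfg.scaling_function)
    keep = _retained(dec.scales, cfg.tau, band_top=float(n))
    recon = (
        dec.coefficients[keep].real / np.sqrt(dec.scales[keep])[:, None]
    ).sum(axis=0) / calib
    out = recon + curve.values.mean()
    if clip:
        out = np.clip(out, 0.0, None)
    return PhenologyCurve(curve.species_id, out, stage="smoothed" if clip else "raw")


def smooth_community(
    comm: CommunityPhenology, cfg: SmoothingConfig | None = None
) -> CommunityPhenology:
    """Smooth every species' curve independently.

    All-zero species carry no phenological signal and are dropped with a
    warning; if fewer than two species remain the community cannot
    support a diversity computation and an error is raised.
    """
    cfg = cfg or SmoothingConfig()
    kept: list[PhenologyCurve] = []
    dropped: list[str] = []
    for c in comm.curves:
        if not np.any(c.values):
            dropped.append(c.species_id)
            continue
        kept.append(smooth_curve(c, cfg))
    if dropped:
        logger.warning("dropped %d all-zero species: %s", len(dropped), ", ".join(dropped))
    if len(kept) < 2:
        raise DegenerateCommunityError(
            f"only {len(kept)} non-zero species remain after smoothing; need >= 2"
        )
    return CommunityPhenology(comm.grid, tuple(kept), gap_report=dict(comm.gap_report))
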