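"""Stationary (undecimated) wavelet transform of the glottal waveform.

The decomposition follows the a-trous scheme with circular (periodic)
boundary handling: at level ``j`` the base analysis filters are upsampled
by ``2**(j-1)`` (zeros inserted between taps) and correlated circularly
with the running approximation.  Every sub-band therefore has as many
coefficients as the input signal, and the transform commutes with
circular shifts — the property that distinguishes the SWT from the
decimated DWT.

Analysis convention (fixed so results are reproducible): the output at
sample ``n`` is ``y[n] = sum_k f[k] * x[(n + k) mod L]`` (anti-causal
correlation).  Synthesis inverts it exactly via the conjugate quadrature
identity |L(w)|^2 + |H(w)|^2 = 2.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pywt

from .errors import ConfigError, ConsistencyError, DegenerateInputError

SUPPORTED_WAVELETS = ("haar",) + tuple(f"db{k}" for k in range(2, 13))


@dataclass(frozen=True)
class FilterPair:
    """Orthonormal analysis filter pair (lowpass LF_D, highpass HF_D)."""

    lowpass: np.ndarray
    highpass: np.ndarray
    name: str


@dataclass
class SubbandSet:
    """Approximation/detail coefficient arrays A1..AJ, D1..DJ.

    ``approx[j]``/``detail[j]`` (0-based list index, 1-based level) each hold
    exactly ``length`` coefficients — the undecimated transform preserves
    the signal length.  ``_padded_approx``/``_padded_detail`` retain the
    circularly-extended arrays needed for exact reconstruction when the
    input length was not a multiple of ``2**levels``.
    """

    approx: list
    detail: list
    levels: int
    length: int
    wavelet: str
    _padded_approx: list = None
    _padded_detail: list = None


def wavelet_filters(name: str) -> FilterPair:
    """Analysis filters for ``haar`` or ``db2``..``db12``.

    The lowpass is the orthonormal scaling filter in natural order; the
    highpass is its alternating-sign reversal, so the pair is a conjugate
    quadrature (orthonormal) filter bank.
    """
    if not re.fullmatch(r"haar|db([2-9]|1[0-2])", name):
        raise ConfigError(f"unknown wavelet: {name!r} (expected haar or db2..db12)")
    low = np.asarray(pywt.Wavelet(name).rec_lo, dtype=np.float64)
    k = np.arange(len(low))
    high = ((-1.0) ** k) * low[::-1]
    return FilterPair(lowpass=low, highpass=high, name=name)


def _upsampled(filt: np.ndarray, factor: int) -> np.ndarray:
    """Insert ``factor - 1`` zeros between taps (a-trous filter dilation)."""
    if factor == 1:
        return filt
    out = np.zeros((len(filt) - 1) * factor + 1)
    out[::factor] = filt
    return out


def _fold(filt: np.ndarray, L: int) -> np.ndarray:
    """Wrap filter taps onto a length-L circle (taps beyond L alias back)."""
    out = np.zeros(L)
    np.add.at(out, np.arange(len(filt)) % L, filt)
    return out


def _circular_correlate(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """y[n] = sum_k f[k] x[(n+k) mod L], evaluated in the Fourier domain."""
    L = len(x)
    return np.fft.irfft(np.fft.rfft(x) * np.conj(np.fft.rfft(_fold(filt, L))), n=L)


def _circular_convolve(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """y[n] = sum_k f[k] x[(n-k) mod L] (adjoint of the correlation)."""
    L = len(x)
    return np.fft.irfft(np.fft.rfft(x) * np.fft.rfft(_fold(filt, L)), n=L)


def swt_decompose(signal: np.ndarray, filters: FilterPair, levels: int = 4) -> SubbandSet:
    """Undecimated wavelet decomposition into A1..AJ, D1..DJ.

    The signal is padded by edge replication to the next multiple of
    ``2**levels`` (circular extension then behaves like a proper period);
    the stored sub-bands are truncated back to the original length.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size == 0:
        raise DegenerateInputError("cannot decompose an empty signal")
    if not 1 <= levels <= 5:
        raise ConfigError("levels must lie in 1..5")
    L = len(x)
    block = 2 ** levels
    if L < block:
        raise DegenerateInputError(f"signal length {L} shorter than 2**levels={block}")
    pad = (-L) % block
    xp = np.concatenate([x, np.full(pad, x[-1])]) if pad else x

    padded_a, padded_d = [], []
    approx = xp
    for j in range(1, levels + 1):
        lo = _upsampled(filters.lowpass, 2 ** (j - 1))
        hi = _upsampled(filters.highpass, 2 ** (j - 1))
        detail = _circular_correlate(approx, hi)
        approx = _circular_correlate(approx, lo)
        padded_a.append(approx)
        padded_d.append(detail)

    return SubbandSet(
        approx=[a[:L] for a in padded_a],
        detail=[d[:L] for d in padded_d],
        levels=levels,
        length=L,
        wavelet=filters.name,
        _padded_approx=padded_a,
        _padded_detail=padded_d,
    )


def swt_reconstruct(subbands: SubbandSet, filters: FilterPair) -> np.ndarray:
    """Invert :func:`swt_decompose`; exact to numerical precision.

    Uses the undecimated two-channel synthesis
    ``A_{j-1} = (conv(lo_j, A_j) + conv(hi_j, D_j)) / 2``.
    """
    if filters.name != subbands.wavelet:
        raise ConsistencyError(
            f"sub-bands were produced with {subbands.wavelet!r}, got filters for {filters.name!r}"
        )
    approx = subbands._padded_approx[-1]
    for j in range(subbands.levels, 0, -1):
        lo = _upsampled(filters.lowpass, 2 ** (j - 1))
        hi = _upsampled(filters.highpass, 2 ** (j - 1))
        detail = subbands._padded_detail[j - 1]
        if len(detail) != len(approx):
            raise ConsistencyError("band lengths inconsistent with levels")
        approx = 0.5 * (_circular_convolve(approx, lo) + _circular_convolve(detail, hi))
    return approx[: subbands.length]
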