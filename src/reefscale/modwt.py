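"""Maximal overlap discrete wavelet transform (MODWT) and its additive MRA.

The MODWT is the undecimated, shift-invariant variant of the discrete
wavelet transform.  Unlike the decimated DWT it is defined for signals of
arbitrary length, every coefficient band has the same length as the input,
and the multiresolution analysis (MRA) re-expresses the signal as an exact
sum of detail series (one per scale) plus one coarse smooth series:

    x[t] = smooth_J[t] + sum_{j=1..J} detail_j[t]

All transforms here use circular (periodic) boundary handling, which is the
textbook definition and what makes the additivity identity exact; an
optional reflection mode is provided for callers who prefer to avoid
wrap-around artifacts at segment ends.

Only the Daubechies family is supported (``db1`` = Haar through ``db10``).
Filters are constructed by spectral factorization of the Daubechies
half-band polynomial, then rescaled by 1/sqrt(2) so that the MODWT scaling
filter sums to one and the wavelet filter sums to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np

__all__ = [
    "WaveletSpec",
    "WaveletMRA",
    "daubechies_filters",
    "modwt_forward",
    "modwt_mra",
    "max_level",
]

_MAX_ORDER = 10


class LevelTooDeepError(ValueError):
    """Requested decomposition level exceeds what the signal length admits."""


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet family, order and decomposition depth for one analysis.

    Parameters
    ----------
    order : int
        Daubechies order; ``1`` is the Haar wavelet.  Filter length is
        ``2 * order``.
    levels : int
        Decomposition depth ``J``; a signal must be at least ``2**J``
        samples long to be decomposed.
    family : str
        Only ``"daubechies"`` is accepted.
    boundary : str
        ``"periodic"`` (default, standard MODWT) or ``"reflect"``.
    """

    order: int = 4
    levels: int = 4
    family: str = "daubechies"
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        if self.family != "daubechies":
            raise ValueError(f"unsupported wavelet family: {self.family!r}")
        if not 1 <= self.order <= _MAX_ORDER:
            raise ValueError(
                f"Daubechies order must be in [1, {_MAX_ORDER}], got {self.order}"
            )
        if self.levels < 1:
            raise ValueError(f"levels must be >= 1, got {self.levels}")
        if self.boundary not in ("periodic", "reflect"):
            raise ValueError(f"unknown boundary rule: {self.boundary!r}")

    @property
    def name(self) -> str:
        return f"db{self.order}"

    @property
    def min_signal_length(self) -> int:
        return 2 ** self.levels


@dataclass
class WaveletMRA:
    """Additive multiresolution components of one signal.

    ``details[j-1]`` holds the level-``j`` detail series; ``smooth`` holds
    the level-``J`` smooth.  All series share the input length and satisfy
    ``smooth + sum(details) == signal`` to floating-point accuracy.
    """

    details: list[np.ndarray]
    smooth: np.ndarray
    spec: WaveletSpec = field(default_factory=WaveletSpec)

    @property
    def local(self) -> np.ndarray:
        """Sum of all detail series (the fine-scale component)."""
        return np.sum(self.details, axis=0)

    def reconstruct(self) -> np.ndarray:
        return self.local + self.smooth


def daubechies_filters(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Return the MODWT (scaling, wavelet) filter pair for ``db{order}``.

    The standard orthonormal DWT filters are divided by sqrt(2), so the
    scaling filter sums to 1 and the wavelet filter sums to 0.  The wavelet
    filter is the quadrature mirror of the scaling filter:
    ``h[l] = (-1)**l * g[2*order - 1 - l]``.
    """
    g = _dwt_scaling_filter(order) / np.sqrt(2.0)
    L = 2 * order
    h = ((-1.0) ** np.arange(L)) * g[::-1]
    return g, h


def _dwt_scaling_filter(order: int) -> np.ndarray:
    """Extremal-phase Daubechies DWT scaling filter (sums to sqrt(2))."""
    if not 1 <= order <= _MAX_ORDER:
        raise ValueError(f"Daubechies order must be in [1, {_MAX_ORDER}], got {order}")
    if order == 1:
        return np.array([1.0, 1.0]) / np.sqrt(2.0)
    # Half-band polynomial P(y) = sum_k C(order-1+k, k) y^k, y = sin^2(w/2).
    p_coeffs = np.array([comb(order - 1 + k, k) for k in range(order)], dtype=float)
    y_roots = np.roots(p_coeffs[::-1])
    poly = np.array([1.0 + 0j])
    for _ in range(order):
        poly = np.convolve(poly, [1.0, 1.0])  # (1 + z)^order
    for y in y_roots:
        # y = (2 - z - 1/z)/4  =>  z^2 + (4y - 2) z + 1 = 0; keep |z| < 1.
        b = 4.0 * y - 2.0
        disc = np.sqrt(b * b - 4.0 + 0j)
        z = (-b + disc) / 2.0
        if abs(z) >= 1.0:
            z = (-b - disc) / 2.0
        poly = np.convolve(poly, [1.0, -z])
    g = np.real(poly)
    return g / g.sum() * np.sqrt(2.0)


def max_level(n: int) -> int:
    """Deepest admissible level for a length-``n`` signal (floor(log2 n))."""
    if n < 2:
        return 0
    return int(np.floor(np.log2(n)))


def _check_signal(signal: np.ndarray, spec: WaveletSpec) -> np.ndarray:
    x = np.asarray(signal, dtype=float)
    n = x.shape[-1]
    if n < spec.min_signal_length:
        raise LevelTooDeepError(
            f"signal length {n} admits at most level {max_level(n)}; "
            f"level {spec.levels} needs >= {spec.min_signal_length} samples"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    return x


def _reflect(x: np.ndarray) -> np.ndarray:
    return np.concatenate([x, x[..., ::-1]], axis=-1)


def _circular_filter(x: np.ndarray, taps: np.ndarray, step: int, sign: int) -> np.ndarray:
    """Circularly filter along the last axis with a level-``step`` upsampled
    filter: ``out[t] = sum_l taps[l] * x[(t + sign*step*l) mod N]``.

    ``sign=-1`` is the analysis (forward) direction, ``sign=+1`` synthesis.
    """
    n = x.shape[-1]
    out = np.zeros_like(x)
    idx = np.arange(n)
    for l, tap in enumerate(taps):
        out += tap * x[..., (idx + sign * step * l) % n]
    return out


def modwt_forward(
    signal: np.ndarray, spec: WaveletSpec
) -> tuple[list[np.ndarray], np.ndarray]:
    """Pyramid MODWT: return (``[W1..WJ]``, ``VJ``) coefficient bands.

    Accepts a 1-D signal or a batch with signals along the last axis; every
    output band has the input's shape.
    """
    x = _check_signal(signal, spec)
    reflected = spec.boundary == "reflect"
    if reflected:
        x = _reflect(x)
    g, h = daubechies_filters(spec.order)
    v = x
    details: list[np.ndarray] = []
    for j in range(1, spec.levels + 1):
        step = 2 ** (j - 1)
        details.append(_circular_filter(v, h, step, -1))
        v = _circular_filter(v, g, step, -1)
    if reflected:
        n = signal.shape[-1] if hasattr(signal, "shape") else len(signal)
        details = [w[..., :n] for w in details]
        v = v[..., :n]
    return details, v


def modwt_mra(signal: np.ndarray, spec: WaveletSpec) -> WaveletMRA:
    """Additive MRA: detail series D1..DJ and smooth SJ.

    Each band is obtained by inverting the transform with every other band
    zeroed, which for the MODWT reduces to cascaded synthesis filtering of
    that band alone.
    """
    x = _check_signal(signal, spec)
    reflected = spec.boundary == "reflect"
    work = _reflect(x) if reflected else x
    n = x.shape[-1]

    # Forward pass on the (possibly reflected) working signal.
    work_spec = WaveletSpec(order=spec.order, levels=spec.levels,
                            boundary="periodic")
    coeffs, v = modwt_forward(work, work_spec)
    g, h = daubechies_filters(spec.order)

    details: list[np.ndarray] = []
    for j, w in enumerate(coeffs, start=1):
        band = _circular_filter(w, h, 2 ** (j - 1), +1)
        for k in range(j - 1, 0, -1):
            band = _circular_filter(band, g, 2 ** (k - 1), +1)
        details.append(band[..., :n] if reflected else band)
    smooth = _circular_filter(v, g, 2 ** (spec.levels - 1), +1)
    for k in range(spec.levels - 1, 0, -1):
        smooth = _circular_filter(smooth, g, 2 ** (k - 1), +1)
    if reflected:
        smooth = smooth[..., :n]
    return WaveletMRA(details=details, smooth=smooth, spec=spec)


def coefficients_to_frame(details: Sequence[np.ndarray], smooth: np.ndarray):
    """Debug helper: coefficient bands as a pandas DataFrame (1-D input)."""
    import pandas as pd

    data = {f"W{j}": np.asarray(w) for j, w in enumerate(details, start=1)}
    data[f"V{len(details)}"] = np.asarray(smooth)
    return pd.DataFrame(data)
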