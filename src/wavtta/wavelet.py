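"""Multilevel 3D discrete wavelet analysis and synthesis.

The transform is separable: a 1-D orthonormal filter pair is applied along
each of the three axes with dyadic downsampling, which yields eight
sub-bands per level (the all-low ``LLL`` band plus seven mixed bands).
Deeper levels recursively decompose the low band only.

The 1-D transform is periodized, so every sub-band has ``ceil(n / 2)``
samples per axis and reconstruction is exact (the analysis operator is
orthogonal).  Odd-length axes are handled by duplicating the last sample
before the transform and cropping after the inverse, which keeps the
round trip exact for arbitrary extents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "WaveletFilters",
    "WaveletPyramid",
    "DecompositionError",
    "dwt3d_single_level",
    "multilevel_dwt",
    "idwt3d",
    "reconstruct",
    "SUBBAND_ORDER",
]

#: Fixed ordering of the seven high-frequency sub-bands: lexicographic over
#: (axis0, axis1, axis2) in {L, H}^3, excluding LLL.  'L' sorts before 'H'.
SUBBAND_ORDER: Tuple[str, ...] = ("LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

# Orthonormal Daubechies scaling (low-pass analysis) coefficients, sum = sqrt(2).
_DAUBECHIES_LOW = {
    "haar": (0.7071067811865476, 0.7071067811865476),
    "db1": (0.7071067811865476, 0.7071067811865476),
    "db2": (
        0.48296291314453414,
        0.8365163037378079,
        0.22414386804185735,
        -0.12940952255126037,
    ),
    "db3": (
        0.3326705529500825,
        0.8068915093110924,
        0.4598775021184914,
        -0.13501102001025458,
        -0.08544127388202666,
        0.03522629188570953,
    ),
    "db4": (
        0.23037781330889648,
        0.7148465705529154,
        0.6308807679298587,
        -0.027983769416859854,
        -0.18703481171909309,
        0.030841381835560763,
        0.032883011666885169,
        -0.010597401785069032,
    ),
}


class DecompositionError(ValueError):
    """Raised when a volume is too small for the requested decomposition."""


@dataclass(frozen=True)
class WaveletFilters:
    """An orthonormal analysis filter pair.

    Attributes
    ----------
    low_pass, high_pass:
        Equal, even-length 1-D coefficient sequences.  The high-pass filter
        satisfies the quadrature-mirror relation
        ``g[k] = (-1)**k * h[L - 1 - k]``.
    family_name:
        Human-readable family label (e.g. ``"db2"``).
    """

    low_pass: Tuple[float, ...]
    high_pass: Tuple[float, ...]
    family_name: str = "custom"

    def __post_init__(self) -> None:
        lo = np.asarray(self.low_pass, dtype=float)
        hi = np.asarray(self.high_pass, dtype=float)
        if lo.ndim != 1 or hi.ndim != 1 or lo.size != hi.size:
            raise ValueError("low_pass and high_pass must be 1-D of equal length")
        if lo.size == 0 or lo.size % 2:
            raise ValueError("filter length must be positive and even")
        qmf = (-1.0) ** np.arange(lo.size) * lo[::-1]
        if np.max(np.abs(hi - qmf)) > 1e-10:
            raise ValueError("high_pass violates the quadrature-mirror relation")

    def __len__(self) -> int:
        return len(self.low_pass)

    @classmethod
    def from_family(cls, family_name: str) -> "WaveletFilters":
        """Build the filter pair of a named Daubechies family member."""
        key = family_name.lower()
        if key not in _DAUBECHIES_LOW:
            raise ValueError(
                f"unknown wavelet family {family_name!r}; "
                f"choose one of {sorted(_DAUBECHIES_LOW)}"
            )
        lo = np.asarray(_DAUBECHIES_LOW[key])
        hi = (-1.0) ** np.arange(lo.size) * lo[::-1]
        return cls(tuple(lo), tuple(hi), family_name=key)


@dataclass
class WaveletPyramid:
    """Multilevel sub-band decomposition of a 3-D volume.

    ``low[n-1]`` is the level-``n`` all-low band; ``high[n-1]`` holds the
    seven level-``n`` mixed bands in :data:`SUBBAND_ORDER`.  Level ``n``
    bands are computed from the level ``n - 1`` low band only.
    """

    levels: int
    low: List[np.ndarray]
    high: List[Tuple[np.ndarray, ...]]
    input_shape: Tuple[int, int, int]
    filters: WaveletFilters
    #: shape of the low band fed into each level (shape_chain[0] == input_shape)
    shape_chain: List[Tuple[int, int, int]] = field(default_factory=list)

    def bands_at(self, level: int) -> Tuple[np.ndarray, ...]:
        """All eight level-``level`` sub-bands, low band first."""
        return (self.low[level - 1],) + tuple(self.high[level - 1])


# cache of per-(length, family) analysis matrices
_MATRIX_CACHE: Dict[Tuple[int, Tuple[float, ...]], Tuple[np.ndarray, np.ndarray]] = {}


def _analysis_matrices(n: int, filters: WaveletFilters) -> Tuple[np.ndarray, np.ndarray]:
    """Periodized analysis matrices (A_lo, A_hi) acting on length-``n + n % 2``."""
    key = (n, filters.low_pass)
    cached = _MATRIX_CACHE.get(key)
    if cached is not None:
        return cached
    n_ext = n + (n % 2)
    lo = np.asarray(filters.low_pass)
    hi = np.asarray(filters.high_pass)
    half = n_ext // 2
    a_lo = np.zeros((half, n_ext))
    a_hi = np.zeros((half, n_ext))
    for j in range(half):
        for m in range(lo.size):
            i = (2 * j + m) % n_ext
            a_lo[j, i] += lo[m]
            a_hi[j, i] += hi[m]
    _MATRIX_CACHE[key] = (a_lo, a_hi)
    return a_lo, a_hi


def _check_axis(n: int, filters: WaveletFilters, axis: int) -> None:
    if n + (n % 2) < len(filters):
        raise DecompositionError(
            f"axis {axis} has extent {n}, smaller than the support of the "
            f"length-{len(filters)} {filters.family_name!r} filters; "
            "the decomposition is too deep for this volume"
        )


def _dwt_axis(x: np.ndarray, filters: WaveletFilters, axis: int) -> Tuple[np.ndarray, np.ndarray]:
    n = x.shape[axis]
    _check_axis(n, filters, axis)
    a_lo, a_hi = _analysis_matrices(n, filters)
    moved = np.moveaxis(x, axis, 0)
    if n % 2:  # duplicate the last sample to an even extent
        moved = np.concatenate([moved, moved[-1:]], axis=0)
    lo = np.moveaxis(np.tensordot(a_lo, moved, axes=(1, 0)), 0, axis)
    hi = np.moveaxis(np.tensordot(a_hi, moved, axes=(1, 0)), 0, axis)
    return lo, hi


def _idwt_axis(
    lo: np.ndarray, hi: np.ndarray, filters: WaveletFilters, axis: int, n_out: int
) -> np.ndarray:
    a_lo, a_hi = _analysis_matrices(n_out, filters)
    lo_m = np.moveaxis(lo, axis, 0)
    hi_m = np.moveaxis(hi, axis, 0)
    rec = np.tensordot(a_lo.T, lo_m, axes=(1, 0)) + np.tensordot(a_hi.T, hi_m, axes=(1, 0))
    rec = rec[:n_out]  # crop the duplicated sample of odd extents
    return np.moveaxis(rec, 0, axis)


def dwt3d_single_level(
    volume: np.ndarray, filters: WaveletFilters
) -> Tuple[np.ndarray, Tuple[np.ndarray, ...]]:
    """One separable 3-D analysis step.

    Parameters
    ----------
    volume:
        3-D scalar field.
    filters:
        Orthonormal filter pair.

    Returns
    -------
    low:
        The ``LLL`` band, ceil-half extent per axis.
    high:
        The seven mixed bands in :data:`SUBBAND_ORDER`.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got ndim={vol.ndim}")
    for axis in range(3):
        _check_axis(vol.shape[axis], filters, axis)
    # transform axis by axis; 'parts' maps the L/H letter string to its band
    parts: Dict[str, np.ndarray] = {"": vol}
    for axis in range(3):
        new: Dict[str, np.ndarray] = {}
        for tag, band in parts.items():
            lo, hi = _dwt_axis(band, filters, axis)
            new[tag + "L"] = lo
            new[tag + "H"] = hi
        parts = new
    low = parts["LLL"]
    high = tuple(parts[tag] for tag in SUBBAND_ORDER)
    return low, high


def idwt3d(
    low: np.ndarray,
    high: Sequence[np.ndarray],
    filters: WaveletFilters,
    target_shape: Tuple[int, int, int],
) -> np.ndarray:
    """Inverse of :func:`dwt3d_single_level`.

    ``target_shape`` disambiguates the parity of each axis; every sub-band
    must have extent ``ceil(target / 2)`` per axis.
    """
    if len(high) != 7:
        raise ValueError(f"expected 7 high sub-bands, got {len(high)}")
    expected = tuple(-(-s // 2) for s in target_shape)
    bands = {"LLL": np.asarray(low, dtype=float)}
    for tag, band in zip(SUBBAND_ORDER, high):
        bands[tag] = np.asarray(band, dtype=float)
    for tag, band in bands.items():
        if band.shape != expected:
            raise ValueError(
                f"sub-band {tag} has shape {band.shape}, inconsistent with "
                f"target shape {tuple(target_shape)} (expected {expected})"
            )
    # invert axis 2, then 1, then 0
    for axis in (2, 1, 0):
        merged: Dict[str, np.ndarray] = {}
        prefixes = sorted({t[:axis] for t in bands})
        for prefix in prefixes:
            lo = bands[prefix + "L"]
            hi = bands[prefix + "H"]
            merged[prefix] = _idwt_axis(lo, hi, filters, axis, target_shape[axis])
        bands = merged
    return bands[""]


def _max_feasible_levels(shape: Tuple[int, ...], filters: WaveletFilters) -> int:
    """Deepest decomposition such that every level's input extent (rounded
    up to even) still covers the filter support on every axis."""
    feasible = 0
    extents = list(shape)
    while feasible < 4:
        if any(e + (e % 2) < len(filters) or e < 2 for e in extents):
            break
        feasible += 1
        extents = [-(-e // 2) for e in extents]
    return feasible


def multilevel_dwt(volume: np.ndarray, levels: int, filters: WaveletFilters) -> WaveletPyramid:
    """Recursive decomposition of the low band down to ``levels`` scales.

    Raises
    ------
    DecompositionError
        If any axis extent is below ``2 ** levels``; the message states the
        maximum feasible level.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got ndim={vol.ndim}")
    if not 1 <= levels <= 4:
        raise ValueError(f"levels must be in [1, 4], got {levels}")
    feasible = _max_feasible_levels(vol.shape, filters)
    if levels > feasible:
        raise DecompositionError(
            f"extents {vol.shape} with {filters.family_name!r} filters support "
            f"at most {feasible} level(s), requested {levels}"
        )
    lows: List[np.ndarray] = []
    highs: List[Tuple[np.ndarray, ...]] = []
    chain: List[Tuple[int, int, int]] = [vol.shape]
    current = vol
    for _ in range(levels):
        low, high = dwt3d_single_level(current, filters)
        lows.append(low)
        highs.append(high)
        current = low
        chain.append(low.shape)
    return WaveletPyramid(
        levels=levels,
        low=lows,
        high=highs,
        input_shape=vol.shape,
        filters=filters,
        shape_chain=chain[:-1],
    )


def reconstruct(pyramid: WaveletPyramid) -> np.ndarray:
    """Invert a full pyramid back to the original volume."""
    current = pyramid.low[-1]
    for level in range(pyramid.levels, 0, -1):
        target = pyramid.shape_chain[level - 1]
        current = idwt3d(current, pyramid.high[level - 1], pyramid.filters, target)
    return current
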