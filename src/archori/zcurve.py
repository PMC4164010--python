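"""Z-curve components and composition-disparity curves.

The Z-curve represents a DNA sequence as three cumulative integer walks:

* ``x`` — purine vs. pyrimidine (R − Y): A,G step +1; C,T step −1
* ``y`` — amino vs. keto (M − K): A,C step +1; G,T step −1
* ``z`` — weak vs. strong H-bond (W − S): A,T step +1; G,C step −1

Two linear combinations localise replication origins: the AT disparity
(x + y)/2, the cumulative excess of A over T, and the GC disparity
(x − y)/2, the cumulative excess of G over C.  A composition-skew switch
at an origin turns into a global extremum of these curves.  Disparities
are half-integers; they are held doubled internally so every comparison
is exact integer arithmetic.

Ambiguous (non-ACGT IUPAC) bases contribute nothing to any component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import UsageError
from .genome_io import AnnotatedGenome, shift_genome

_DX = np.zeros(256, dtype=np.int8)
_DY = np.zeros(256, dtype=np.int8)
_DZ = np.zeros(256, dtype=np.int8)
for _b, (_dx, _dy, _dz) in {"A": (1, 1, 1), "G": (1, -1, -1),
                            "C": (-1, 1, -1), "T": (-1, -1, 1)}.items():
    for _c in (_b, _b.lower()):
        _DX[ord(_c)], _DY[ord(_c)], _DZ[ord(_c)] = _dx, _dy, _dz

COMPONENTS = ("at", "gc", "ry", "mk")


@dataclass
class ZCurveProfile:
    """Cumulative Z-curve arrays of length n+1 with zero first entry."""

    n: int
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    @property
    def at2(self) -> np.ndarray:
        """Doubled AT disparity, exact integers (x + y)."""
        return self.x + self.y

    @property
    def gc2(self) -> np.ndarray:
        """Doubled GC disparity, exact integers (x − y)."""
        return self.x - self.y

    @property
    def at(self) -> np.ndarray:
        return self.at2 / 2.0

    @property
    def gc(self) -> np.ndarray:
        return self.gc2 / 2.0

    def curve(self, component: str) -> np.ndarray:
        """Integer-valued curve for a component name (disparities doubled)."""
        if component == "at":
            return self.at2
        if component == "gc":
            return self.gc2
        if component == "ry":
            return self.x
        if component == "mk":
            return self.y
        if component == "ws":
            return self.z
        raise UsageError(f"unknown Z-curve component {component!r}")


def compute_zcurve(sequence: str) -> ZCurveProfile:
    """Cumulative Z-curve of a nucleotide string (empty input is valid)."""
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    n = len(codes)
    x = np.zeros(n + 1, dtype=np.int64)
    y = np.zeros(n + 1, dtype=np.int64)
    z = np.zeros(n + 1, dtype=np.int64)
    if n:
        np.cumsum(_DX[codes], out=x[1:])
        np.cumsum(_DY[codes], out=y[1:])
        np.cumsum(_DZ[codes], out=z[1:])
    return ZCurveProfile(n=n, x=x, y=y, z=z)


def _smooth(curve: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return curve.astype(float)
    kernel = np.ones(window) / window
    return np.convolve(curve.astype(float), kernel, mode="same")


def find_extrema(profile: ZCurveProfile, component: str = "gc",
                 smoothing_window: int | None = None,
                 prominence: float | None = None,
                 include_local: bool = True,
                 flat_threshold: float = 0.0) -> dict:
    """Global and local extrema of a disparity curve.

    ``smoothing_window`` defaults to none below 1 Mb and n/1000 above;
    raw cumulative curves are already stable at typical genome sizes.
    Local extrema are peaks/troughs whose prominence exceeds ``prominence``
    (default: a tenth of the curve's range); on long curves they are read
    off a decimated copy (~5 kpoints) since origin-scale features span
    kilobases, while the global extrema always use the full curve.  Ties
    break toward the smallest coordinate.  A curve whose total range does
    not exceed ``flat_threshold`` (default 0, i.e. a constant curve) sets
    ``flat`` and reports both extrema at position 0; pass a null-walk
    calibrated threshold to test for *significant* drift instead.
    """
    curve = profile.curve(component)
    if smoothing_window is None:
        smoothing_window = 0 if profile.n < 1_000_000 else profile.n // 1000
    smoothed = _smooth(curve, smoothing_window)
    lo, hi = smoothed.min(), smoothed.max()
    if hi - lo <= flat_threshold:
        return {"component": component, "max_position": 0, "min_position": 0,
                "flat": True, "local_extrema": []}
    if prominence is None:
        prominence = (hi - lo) / 10.0
    local: list[tuple[int, str]] = []
    if include_local:
        stride = max(len(smoothed) // 5000, 1)
        coarse = smoothed[::stride]
        peaks_hi, _ = find_peaks(coarse, prominence=prominence)
        peaks_lo, _ = find_peaks(-coarse, prominence=prominence)
        local = sorted(
            [(int(p) * stride, "max") for p in peaks_hi]
            + [(int(p) * stride, "min") for p in peaks_lo]
        )
    return {
        "component": component,
        "max_position": int(np.argmax(smoothed)),
        "min_position": int(np.argmin(smoothed)),
        "flat": False,
        "local_extrema": local,
    }


def rotate_to_gc_max(genome: AnnotatedGenome) -> AnnotatedGenome:
    """Rotate a circular genome so the GC-disparity global maximum is at 0.

    Recomputing the profile on the returned genome places the maximum at
    the sequence boundary (index 0 or n).
    """
    if not genome.circular:
        raise UsageError("rotation is undefined for a linear genome")
    profile = compute_zcurve(genome.sequence)
    result = find_extrema(profile, "gc", smoothing_window=0)
    return shift_genome(genome, result["max_position"])
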