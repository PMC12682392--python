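"""CEST/APT quantification: B0-corrected MTRasym, ADC and net-enhancement maps.

The amide proton transfer-weighted (APTw) contrast is quantified as the
magnetization transfer ratio asymmetry at +/-3.5 ppm from water,

    MTRasym(3.5 ppm) [%] = (S(-3.5) - S(+3.5)) / S0 * 100,

where S0 is the unsaturated reference (acquired far off-resonance, nominally
-1540 ppm) and the saturated signals are taken from the Z-spectrum sampled at
the six nominal offsets {-4.3, -3.5, -2.7, +2.7, +3.5, +4.3} ppm, after
voxel-wise B0 correction.  B0 maps come from a multi-echo phase acquisition:
the per-voxel off-resonance frequency is the least-squares slope of unwrapped
phase versus echo time divided by 2*pi, converted to ppm with the scanner
proton frequency.

Companion maps: apparent diffusion coefficient (ADC) from a mono-exponential
fit of log-signal versus b-value, and early post-contrast net enhancement
(post minus pre).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GAMMA_MHZ_PER_T",
    "DEFAULT_FIELD_MHZ",
    "NOMINAL_OFFSETS_PPM",
    "ZSpectrum",
    "B0Map",
    "ParametricMap",
    "estimate_b0_shift",
    "correct_z_spectrum",
    "compute_mtrasym",
    "quantify_mtrasym_volume",
    "compute_adc_map",
    "compute_net_enhancement",
]

#: Proton gyromagnetic ratio, MHz per tesla.
GAMMA_MHZ_PER_T = 42.576
#: Proton resonance frequency at 3 T, MHz.
DEFAULT_FIELD_MHZ = 127.728
#: Nominal saturation-offset schedule, ppm (water = 0).
NOMINAL_OFFSETS_PPM = (-4.3, -3.5, -2.7, 2.7, 3.5, 4.3)

#: |shift| beyond this (ppm) marks a B0 estimate as unreliable.
B0_RELIABLE_PPM = 2.0


@dataclass(frozen=True)
class ZSpectrum:
    """Per-voxel saturated signal versus frequency offset, plus reference S0.

    Parameters
    ----------
    offsets_ppm : strictly increasing saturation offsets in ppm.
    signals : saturated signal per offset (arbitrary units; NaN = invalid).
    s0 : unsaturated reference signal, > 0.
    """

    offsets_ppm: np.ndarray
    signals: np.ndarray
    s0: float

    def __post_init__(self) -> None:
        offs = np.asarray(self.offsets_ppm, dtype=float)
        sig = np.asarray(self.signals, dtype=float)
        if offs.ndim != 1 or offs.size == 0:
            raise ValueError("offsets_ppm must be a nonempty 1-D sequence")
        if np.any(np.diff(offs) <= 0):
            raise ValueError("offsets_ppm must be strictly increasing")
        if sig.shape != offs.shape:
            raise ValueError("signals and offsets_ppm must have equal length")
        if not np.isfinite(self.s0) or self.s0 <= 0:
            raise ValueError("s0 must be a positive finite number")
        object.__setattr__(self, "offsets_ppm", offs)
        object.__setattr__(self, "signals", sig)

    def signal_at(self, offset_ppm: float, atol: float = 1e-9) -> float:
        """Signal at a sampled offset (exact match within *atol*)."""
        idx = np.flatnonzero(np.isclose(self.offsets_ppm, offset_ppm, atol=atol))
        if idx.size == 0:
            raise ValueError(f"offset {offset_ppm} ppm not sampled")
        return float(self.signals[idx[0]])


@dataclass(frozen=True)
class B0Map:
    """Per-voxel water-resonance offset in ppm.

    ``reliable`` flags voxels with |shift| < 2 ppm; larger apparent shifts are
    kept but marked untrustworthy rather than silently used.
    """

    shift_ppm: np.ndarray
    field_mhz: float = DEFAULT_FIELD_MHZ
    reliable: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shift = np.asarray(self.shift_ppm, dtype=float)
        object.__setattr__(self, "shift_ppm", shift)
        if self.reliable is None:
            object.__setattr__(
                self, "reliable", np.abs(shift) < B0_RELIABLE_PPM
            )


@dataclass(frozen=True)
class ParametricMap:
    """A 3-D scalar map with voxel spacing.

    kind is one of ``mtrasym_pct`` (%), ``adc_e3`` (x1e-3 mm^2/s) or
    ``net_enh`` (signal units).  NaN marks voxels whose input was invalid.
    """

    values: np.ndarray
    spacing_mm: tuple = (1.0, 1.0, 1.0)
    kind: str = "mtrasym_pct"

    KINDS = ("mtrasym_pct", "adc_e3", "net_enh")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}, got {self.kind!r}")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


# ---------------------------------------------------------------------------
# B0 estimation
# ---------------------------------------------------------------------------

def unwrap_phases(phases: np.ndarray, axis: int = -1) -> np.ndarray:
    """Unwrap phase samples along *axis* by adding multiples of 2*pi so that
    successive jumps never exceed pi."""
    return np.unwrap(np.asarray(phases, dtype=float), axis=axis)


def estimate_b0_shift(
    phases: np.ndarray,
    echo_times_s: Sequence[float],
    field_mhz: float = DEFAULT_FIELD_MHZ,
) -> B0Map:
    """Estimate the per-voxel B0 shift from multi-echo phase images.

    Parameters
    ----------
    phases : array, shape (..., n_echoes)
        Phase in radians at each echo time (possibly wrapped).
    echo_times_s : n_echoes echo times in seconds, strictly increasing.
    field_mhz : scanner proton frequency in MHz.

    Returns
    -------
    B0Map with shift_ppm = (slope of unwrapped phase vs TE / 2*pi) / field_mhz.
    """
    te = np.asarray(echo_times_s, dtype=float)
    ph = np.asarray(phases, dtype=float)
    if te.ndim != 1 or te.size < 3:
        raise ValueError("need at least 3 echo times")
    if np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be strictly increasing")
    if ph.shape[-1] != te.size:
        raise ValueError("last phase axis must match number of echoes")
    ph = unwrap_phases(ph, axis=-1)
    # least-squares slope along the echo axis
    t_c = te - te.mean()
    slope = np.tensordot(ph - ph.mean(axis=-1, keepdims=True), t_c, axes=([-1], [0]))
    slope = slope / np.dot(t_c, t_c)  # rad/s
    delta_f_hz = slope / (2.0 * np.pi)
    return B0Map(shift_ppm=delta_f_hz / field_mhz, field_mhz=field_mhz)


# ---------------------------------------------------------------------------
# Z-spectrum B0 correction
# ---------------------------------------------------------------------------

def _lagrange3(x: np.ndarray, y: np.ndarray, xt: float) -> float:
    """Evaluate the quadratic Lagrange interpolant of 3 points at xt."""
    (x0, x1, x2), (y0, y1, y2) = x, y
    l0 = (xt - x1) * (xt - x2) / ((x0 - x1) * (x0 - x2))
    l1 = (xt - x0) * (xt - x2) / ((x1 - x0) * (x1 - x2))
    l2 = (xt - x0) * (xt - x1) / ((x2 - x0) * (x2 - x1))
    return float(y0 * l0 + y1 * l1 + y2 * l2)


def correct_z_spectrum(z: ZSpectrum, shift_ppm: float) -> ZSpectrum:
    """B0-correct a Z-spectrum by resampling each branch at shifted offsets.

    The corrected signal at nominal offset w is the measured spectrum
    evaluated at (w + shift_ppm), interpolated separately on the negative and
    positive branches by 3-point (quadratic) Lagrange interpolation — exact
    for branch signals polynomial of degree <= 2.  A target offset falling
    outside its sampled branch yields NaN for that sample (voxel flagged
    invalid downstream), never an exception.
    """
    offs = z.offsets_ppm
    neg = offs < 0
    pos = offs > 0
    if neg.sum() < 3 or pos.sum() < 3:
        raise ValueError("need >=3 offsets on each side of 0 ppm")
    half_span = min(np.ptp(offs[neg]), np.ptp(offs[pos])) / 2.0
    if abs(shift_ppm) >= half_span:
        raise ValueError(
            f"|shift| = {abs(shift_ppm):.3g} ppm exceeds half the branch span "
            f"({half_span:.3g} ppm)"
        )
    if shift_ppm == 0.0:
        return ZSpectrum(offs.copy(), z.signals.copy(), z.s0)

    out = np.empty_like(z.signals)
    for branch in (neg, pos):
        bx = offs[branch]
        by = z.signals[branch]
        lo, hi = bx[0], bx[-1]
        for i, w in enumerate(bx):
            target = w + shift_ppm
            j = np.flatnonzero(branch)[i]
            if target < lo or target > hi:
                out[j] = np.nan
                continue
            # 3 nearest branch samples around the target
            order = np.argsort(np.abs(bx - target), kind="stable")[:3]
            order = np.sort(order)
            out[j] = _lagrange3(bx[order], by[order], target)
    return ZSpectrum(offs.copy(), out, z.s0)


def compute_mtrasym(z: ZSpectrum, offset_ppm: float = 3.5) -> float:
    """MTRasym at +/-offset_ppm as a percentage of S0 (may be negative).

    Returns NaN if either of the two required samples is NaN (invalid voxel).
    """
    if z.s0 <= 0:
        raise ValueError("s0 must be positive")
    s_neg = z.signal_at(-offset_ppm)
    s_pos = z.signal_at(+offset_ppm)
    return (s_neg - s_pos) / z.s0 * 100.0


def quantify_mtrasym_volume(
    offset_stack: np.ndarray,
    s0_volume: np.ndarray,
    offsets_ppm: Sequence[float] = NOMINAL_OFFSETS_PPM,
    b0: B0Map | None = None,
    spacing_mm: tuple = (1.0, 1.0, 1.0),
) -> ParametricMap:
    """Voxel-wise MTRasym map from an offset-series stack.

    Parameters
    ----------
    offset_stack : array, shape grid + (n_offsets,)
        Saturated signal volumes, one per offset in *offsets_ppm*.
    s0_volume : unsaturated reference volume, same grid.
    b0 : optional B0Map on the same grid; when given, each voxel's Z-spectrum
        is B0-corrected before the asymmetry is taken.  Voxels whose B0
        estimate is flagged unreliable, or whose shift pushes +/-3.5 ppm off
        its sampled branch, come out NaN.
    """
    offs = np.asarray(offsets_ppm, dtype=float)
    stack = np.asarray(offset_stack, dtype=float)
    s0 = np.asarray(s0_volume, dtype=float)
    if stack.shape[:-1] != s0.shape:
        raise ValueError("offset stack grid must match s0 volume")
    if stack.shape[-1] != offs.size:
        raise ValueError("offset stack depth must match offsets_ppm")
    out = np.full(s0.shape, np.nan)
    i_neg = int(np.flatnonzero(np.isclose(offs, -3.5))[0])
    i_pos = int(np.flatnonzero(np.isclose(offs, 3.5))[0])
    flat = stack.reshape(-1, offs.size)
    s0f = s0.reshape(-1)
    outf = out.reshape(-1)
    shifts = None
    if b0 is not None:
        if b0.shift_ppm.shape != s0.shape:
            raise ValueError("B0 map grid must match s0 volume")
        shifts = b0.shift_ppm.reshape(-1)
        reliable = b0.reliable.reshape(-1)
    for v in range(s0f.size):
        if s0f[v] <= 0 or not np.all(np.isfinite(flat[v])):
            continue
        zs = ZSpectrum(offs, flat[v], float(s0f[v]))
        if shifts is not None:
            if not reliable[v]:
                continue
            zs = correct_z_spectrum(zs, float(shifts[v]))
        s_neg, s_pos = zs.signals[i_neg], zs.signals[i_pos]
        if np.isfinite(s_neg) and np.isfinite(s_pos):
            outf[v] = (s_neg - s_pos) / s0f[v] * 100.0
    return ParametricMap(out, spacing_mm=spacing_mm, kind="mtrasym_pct")


# ---------------------------------------------------------------------------
# ADC and net enhancement
# ---------------------------------------------------------------------------

def compute_adc_map(
    signals: Sequence[np.ndarray],
    b_values: Sequence[float],
    spacing_mm: tuple = (1.0, 1.0, 1.0),
) -> ParametricMap:
    """Mono-exponential ADC map from DWI volumes at >=2 b-values.

    Per voxel, ADC is minus the least-squares slope of ln(S) versus b
    (s/mm^2), reported in units of 1e-3 mm^2/s.  Voxels with any non-positive
    or non-finite signal are NaN.
    """
    b = np.asarray(b_values, dtype=float)
    if b.ndim != 1 or np.unique(b).size < 2:
        raise ValueError("need at least 2 distinct b-values")
    vols = [np.asarray(v, dtype=float) for v in signals]
    if len(vols) != b.size:
        raise ValueError("number of volumes must match number of b-values")
    shape = vols[0].shape
    if any(v.shape != shape for v in vols):
        raise ValueError("all DWI volumes must share one grid")
    stack = np.stack(vols, axis=-1)
    valid = np.all(np.isfinite(stack) & (stack > 0), axis=-1)
    logs = np.where(stack > 0, np.log(np.where(stack > 0, stack, 1.0)), np.nan)
    b_c = b - b.mean()
    slope = np.tensordot(
        logs - np.nanmean(logs, axis=-1, keepdims=True), b_c, axes=([-1], [0])
    ) / np.dot(b_c, b_c)  # mm^2/s
    adc = np.where(valid, -slope * 1e3, np.nan)
    return ParametricMap(adc, spacing_mm=spacing_mm, kind="adc_e3")


def compute_net_enhancement(
    pre_volume: np.ndarray,
    post_volume: np.ndarray,
    spacing_mm: tuple = (1.0, 1.0, 1.0),
) -> ParametricMap:
    """Early post-contrast net enhancement: voxel-wise post minus pre."""
    pre = np.asarray(pre_volume, dtype=float)
    post = np.asarray(post_volume, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post volumes must share one grid")
    return ParametricMap(post - pre, spacing_mm=spacing_mm, kind="net_enh")
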