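"""Digital phantom: synthetic Z-spectra, field maps, DWI and contrast volumes.

The saturated signal is modelled as a superposition of Lorentzian saturation
pools on a unit baseline,

    Z(dw) = 1 - sum_k A_k * (w_k/2)^2 / ((w_k/2)^2 + (dw - d_k - b0)^2),

with pool centre d_k (ppm; water 0, amide +3.5, MT/NOE on the negative side),
peak depth A_k in [0, 1) and full width at half maximum w_k.  The Lorentzian
superposition is an approximation to the full exchange physics, but it has a
closed form at every offset, so every downstream quantity (MTRasym, its
dependence on pool amplitude, the effect of a B0 shift) has an analytic
ground truth.

A PhantomScene lays pools, ADC values and enhancement kinetics onto a 3-D
grid with an ellipsoidal tumor, an optional necrotic core and a smooth
polynomial B0 field, and emits every raw volume the quantification stage
consumes plus the ground-truth maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .cest import DEFAULT_FIELD_MHZ, NOMINAL_OFFSETS_PPM, ZSpectrum

__all__ = [
    "PoolSpec",
    "Ellipsoid",
    "RegionSpec",
    "PhantomScene",
    "lorentzian_z",
    "simulate_z_spectrum",
    "simulate_phantom_volumes",
    "simulate_reader_masks",
    "default_scene",
]


@dataclass(frozen=True)
class PoolSpec:
    """One Lorentzian saturation pool: centre (ppm), depth in [0,1), FWHM (ppm)."""

    center_ppm: float
    amplitude: float
    width_ppm: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude < 1.0:
            raise ValueError("amplitude must be in [0, 1)")
        if self.width_ppm <= 0:
            raise ValueError("width_ppm must be > 0")


#: Canonical pools. Widths are deliberately broad (direct saturation merged
#: with the semi-solid MT background; exchange-broadened amide) so the
#: spectrum is smooth at the 0.8 ppm offset spacing: 3-point quadratic
#: resampling then recovers MTRasym to < 0.1 pp for B0 shifts up to 0.5 ppm,
#: the accuracy contract of the correction stage.  Tumor MTRasym ~ 3.2%.
WATER_POOL = PoolSpec(center_ppm=0.0, amplitude=0.88, width_ppm=7.0)
AMIDE_POOL = PoolSpec(center_ppm=3.5, amplitude=0.035, width_ppm=4.5)


def lorentzian_z(
    pools: Sequence[PoolSpec], offsets_ppm: np.ndarray, b0_shift: float = 0.0
) -> np.ndarray:
    """Noise-free normalized Z-spectrum of a pool superposition (unit S0)."""
    dw = np.asarray(offsets_ppm, dtype=float)
    z = np.ones_like(dw)
    for p in pools:
        hw2 = (p.width_ppm / 2.0) ** 2
        z = z - p.amplitude * hw2 / (hw2 + (dw - p.center_ppm - b0_shift) ** 2)
    return z


def analytic_mtrasym(
    pools: Sequence[PoolSpec], offset_ppm: float = 3.5, b0_shift: float = 0.0
) -> float:
    """Closed-form MTRasym (%) of the pool model: Z(-dw) - Z(+dw), times 100."""
    z = lorentzian_z(pools, np.array([-offset_ppm, offset_ppm]), b0_shift)
    return float((z[0] - z[1]) * 100.0)


def simulate_z_spectrum(
    pools: Sequence[PoolSpec],
    offsets_ppm: Sequence[float] = NOMINAL_OFFSETS_PPM,
    b0_shift: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    s0: float = 1.0,
) -> ZSpectrum:
    """Sample one voxel's Z-spectrum from the Lorentzian pool model.

    Additive Gaussian noise (sd in units of S0) is applied to the saturated
    signals only; S0 is returned noiselessly so the MTRasym noise model stays
    analyzable.  *seed* is mandatory whenever noise_sd > 0.
    """
    offs = np.asarray(offsets_ppm, dtype=float)
    if offs.size == 0:
        raise ValueError("offsets_ppm must be nonempty")
    total = sum(p.amplitude for p in pools)
    if total >= 1.0:
        raise ValueError(f"sum of pool amplitudes must be < 1, got {total}")
    z = lorentzian_z(pools, offs, b0_shift)
    if noise_sd > 0:
        if seed is None:
            raise ValueError("seed is required for noisy simulation")
        rng = np.random.default_rng(seed)
        z = z + rng.normal(0.0, noise_sd, size=z.shape)
    return ZSpectrum(offs, z * s0, s0)


# ---------------------------------------------------------------------------
# Scene geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in voxel-index coordinates (0-based)."""

    center: tuple
    radii: tuple

    def mask(self, shape: tuple) -> np.ndarray:
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        acc = np.zeros(shape, dtype=float)
        for g, c, r in zip(grids, self.center, self.radii):
            acc = acc + ((g - c) / r) ** 2
        return acc <= 1.0


@dataclass(frozen=True)
class RegionSpec:
    """Tissue parameters for one scene region."""

    pools: tuple
    adc_e3: float          # ground-truth ADC, x1e-3 mm^2/s
    pre_signal: float      # pre-contrast T1w signal
    net_enhancement: float # post - pre at the early phase


@dataclass(frozen=True)
class PhantomScene:
    """Geometry + tissue parameters + B0 field for one synthetic acquisition.

    The necrotic core must lie inside the tumor; regions are otherwise
    disjoint by construction (background = everything outside the tumor).
    ``b0_coeffs`` are per-slice 2-D polynomial coefficients
    (c0, cx, cy, cxy, cxx, cyy) over normalized in-plane coordinates in
    [-1, 1], giving a smooth field in ppm.
    """

    shape: tuple = (24, 24, 6)
    tumor: Ellipsoid = Ellipsoid(center=(11.5, 11.5, 2.5), radii=(7.0, 7.0, 2.2))
    core: Ellipsoid | None = Ellipsoid(center=(11.5, 11.5, 2.5), radii=(2.5, 2.5, 1.0))
    background_region: RegionSpec = RegionSpec(
        pools=(WATER_POOL,), adc_e3=2.0, pre_signal=100.0, net_enhancement=5.0
    )
    tumor_region: RegionSpec = RegionSpec(
        pools=(WATER_POOL, AMIDE_POOL), adc_e3=0.9, pre_signal=120.0,
        net_enhancement=60.0,
    )
    core_region: RegionSpec = RegionSpec(
        pools=(PoolSpec(0.0, 0.80, 7.0),), adc_e3=2.6, pre_signal=110.0,
        net_enhancement=2.0,
    )
    b0_coeffs: tuple = (0.05, 0.15, -0.10, 0.08, 0.0, 0.0)
    noise_sd: float = 0.0
    seed: int = 0
    offsets_ppm: tuple = NOMINAL_OFFSETS_PPM
    echo_times_s: tuple = (0.002, 0.003, 0.004)
    b_values: tuple = (0.0, 500.0, 1000.0)
    field_mhz: float = DEFAULT_FIELD_MHZ
    spacing_mm: tuple = (1.5, 1.5, 3.0)

    def masks(self) -> tuple:
        """(tumor-minus-core, core, background) boolean masks; disjoint."""
        tumor = self.tumor.mask(self.shape)
        if self.core is not None:
            core = self.core.mask(self.shape)
            if np.any(core & ~tumor):
                raise ValueError("necrotic core must lie inside the tumor")
        else:
            core = np.zeros(self.shape, dtype=bool)
        return tumor & ~core, core, ~tumor

    def b0_field(self) -> np.ndarray:
        nx, ny, _ = self.shape
        x = np.linspace(-1.0, 1.0, nx)[:, None]
        y = np.linspace(-1.0, 1.0, ny)[None, :]
        c0, cx, cy, cxy, cxx, cyy = self.b0_coeffs
        plane = c0 + cx * x + cy * y + cxy * x * y + cxx * x**2 + cyy * y**2
        return np.repeat(plane[:, :, None], self.shape[2], axis=2)


def default_scene(**overrides) -> PhantomScene:
    """The stock scene used throughout the tests and the demo pipeline."""
    return PhantomScene(**overrides)


def simulate_phantom_volumes(scene: PhantomScene) -> dict:
    """Render every raw volume of one synthetic acquisition, plus ground truth.

    Returns a dict with keys: ``offset_stack`` (grid + n_offsets), ``s0``,
    ``phases`` (grid + n_echoes), ``echo_times_s``, ``dwi`` (list of volumes),
    ``b_values``, ``pre``, ``post``, ``truth_mtrasym`` (%), ``truth_adc``
    (x1e-3), ``b0_ppm``, ``mask_tumor`` (solid tumor incl. core),
    ``mask_core``, ``mask_solid`` (tumor minus core).  Deterministic given
    ``scene`` (which carries the seed).
    """
    solid, core, background = scene.masks()
    rng = np.random.default_rng(scene.seed)
    offs = np.asarray(scene.offsets_ppm, dtype=float)
    b0 = scene.b0_field()
    s0_val = 1000.0
    shape = scene.shape

    offset_stack = np.empty(shape + (offs.size,))
    truth_mtr = np.empty(shape)
    truth_adc = np.empty(shape)
    pre = np.empty(shape)
    post = np.empty(shape)
    dwi = [np.empty(shape) for _ in scene.b_values]

    regions = (
        (solid, scene.tumor_region),
        (core, scene.core_region),
        (background, scene.background_region),
    )
    for mask, reg in regions:
        idx = np.flatnonzero(mask.ravel())
        if idx.size == 0:
            continue
        # Z-spectrum per voxel: pool model at the voxel's local B0 offset
        dw = offs[None, :] - b0.ravel()[idx][:, None]
        z = np.ones_like(dw)
        for p in reg.pools:
            hw2 = (p.width_ppm / 2.0) ** 2
            z = z - p.amplitude * hw2 / (hw2 + (dw - p.center_ppm) ** 2)
        offset_stack.reshape(-1, offs.size)[idx] = z * s0_val
        truth_mtr.ravel()[idx] = analytic_mtrasym(reg.pools)
        truth_adc.ravel()[idx] = reg.adc_e3
        pre.ravel()[idx] = reg.pre_signal
        post.ravel()[idx] = reg.pre_signal + reg.net_enhancement
        for k, b in enumerate(scene.b_values):
            dwi[k].ravel()[idx] = reg.pre_signal * np.exp(-b * reg.adc_e3 * 1e-3)

    if scene.noise_sd > 0:
        offset_stack += rng.normal(0, scene.noise_sd * s0_val, offset_stack.shape)
        for k in range(len(dwi)):
            dwi[k] = dwi[k] + rng.normal(0, scene.noise_sd * 100.0, shape)

    # multi-echo phase evolution of the local off-resonance
    delta_f_hz = b0 * scene.field_mhz
    te = np.asarray(scene.echo_times_s)
    phases = 2.0 * np.pi * delta_f_hz[..., None] * te[None, None, None, :]
    phases = np.angle(np.exp(1j * phases))  # wrap into (-pi, pi]

    return {
        "offset_stack": offset_stack,
        "s0": np.full(shape, s0_val),
        "phases": phases,
        "echo_times_s": te,
        "dwi": dwi,
        "b_values": np.asarray(scene.b_values),
        "pre": pre,
        "post": post,
        "truth_mtrasym": truth_mtr,
        "truth_adc": truth_adc,
        "b0_ppm": b0,
        "mask_tumor": solid | core,
        "mask_core": core,
        "mask_solid": solid,
        "spacing_mm": scene.spacing_mm,
        "field_mhz": scene.field_mhz,
    }


# ---------------------------------------------------------------------------
# Reader-mask perturbation
# ---------------------------------------------------------------------------

def simulate_reader_masks(
    mask: np.ndarray, jitter_vox: int, seed: int
) -> tuple:
    """Two reader-style variants of a mask, perturbed at the boundary.

    Each variant independently flips voxels in the inner and outer boundary
    shells (up to *jitter_vox* layers deep, flip probability 0.3), emulating
    two observers tracing the same lesion.  jitter_vox = 0 returns two exact
    copies.  Deterministic given (mask, seed).
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("mask is empty")
    if jitter_vox < 0:
        raise ValueError("jitter_vox must be >= 0")
    if jitter_vox == 0:
        return m.copy(), m.copy()
    eroded = ndimage.binary_erosion(m, iterations=jitter_vox)
    if not eroded.any():
        raise ValueError("jitter_vox exceeds the object size")
    dilated = ndimage.binary_dilation(m, iterations=jitter_vox)
    inner_shell = m & ~eroded
    outer_shell = dilated & ~m
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(2):
        v = m.copy()
        v[inner_shell] = rng.random(int(inner_shell.sum())) >= 0.3
        v[outer_shell] = rng.random(int(outer_shell.sum())) < 0.3
        out.append(v)
    return out[0], out[1]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient of two boolean masks."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("both masks are empty")
    return 2.0 * float((a & b).sum()) / float(denom)
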