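"""Synthetic template and micrograph generation.

Density volumes are rendered from atomic models with an isotropic-Gaussian
atom model: each atom contributes a 3D Gaussian whose integrated weight is
its atomic number and whose variance follows the Debye-Waller relation
sigma^2 = (B + B_extra) / (8 pi^2).  Projections are central Fourier slices,
contrast is modulated by a standard weak-phase CTF, and micrographs are
sums of planted, CTF-filtered projections in white Gaussian noise with an
optional smooth non-uniform background (emulating the variable background
of cellular specimens).  Every random quantity derives from an explicit
seed, so a micrograph and its ground-truth pose table are exactly
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import gemmi
import numpy as np
from numpy.fft import fft2, fftn, fftshift, ifft2, ifftshift
from scipy.ndimage import map_coordinates
from scipy.special import erf

from .model_io import AtomicModel, atomic_number

__all__ = [
    "DensityVolume",
    "Image2D",
    "CTFParams",
    "GroundTruth",
    "simulate_volume",
    "project",
    "rotation_matrix_zyz",
    "apply_ctf",
    "ctf_2d",
    "electron_wavelength",
    "synth_micrograph",
    "synthetic_model",
    "amplitude_for_peak_snr",
    "read_mrc",
    "write_mrc",
    "read_volume",
    "write_volume",
    "read_image",
    "write_image",
]

# minimum Gaussian width in voxels; the voxel-cell integration keeps the
# mass exact for any width, but much below half a voxel the density is
# effectively a delta and Fourier-slice projections alias badly
_MIN_SIGMA_VOX = 0.5


@dataclass
class DensityVolume:
    """Cubic grid of real densities. ``data[x, y, z]``, pixel size in Angstrom."""

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError("volume must be a cubic 3D grid")
        if self.data.shape[0] % 2 != 0:
            raise ValueError("box size must be even")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("densities must be finite")

    @property
    def box_size(self) -> int:
        return self.data.shape[0]


@dataclass
class Image2D:
    """Square grid of real values. ``data[x, y]``, pixel size in Angstrom."""

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError("image must be square")
        if self.data.shape[0] % 2 != 0:
            raise ValueError("image edge must be even")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image values must be finite")

    @property
    def size(self) -> int:
        return self.data.shape[0]


@dataclass
class CTFParams:
    """Contrast transfer function parameters (underfocus positive).

    defocus in Angstrom, voltage in kV, spherical aberration in mm,
    amplitude contrast as a fraction in [0, 1].
    """

    defocus: float = 10000.0
    voltage: float = 300.0
    cs: float = 2.7
    amplitude_contrast: float = 0.07
    astigmatism: float = 0.0
    astigmatism_angle: float = 0.0  # degrees

    def __post_init__(self) -> None:
        if self.voltage <= 0:
            raise ValueError("voltage must be > 0")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude contrast must be in [0, 1]")

    def with_defocus(self, defocus: float) -> "CTFParams":
        return CTFParams(
            defocus,
            self.voltage,
            self.cs,
            self.amplitude_contrast,
            self.astigmatism,
            self.astigmatism_angle,
        )


@dataclass
class GroundTruth:
    """Planted-particle bookkeeping for a synthetic micrograph."""

    x: np.ndarray  # (n,) pixels
    y: np.ndarray
    euler: np.ndarray  # (n, 3) degrees, intrinsic ZYZ (phi, theta, psi)
    defocus: np.ndarray  # (n,) Angstrom
    scale: np.ndarray  # (n,) amplitude scale
    noise_sigma: float
    background: str
    seed: int

    @property
    def n_particles(self) -> int:
        return len(self.x)

    def save(self, path: str | Path) -> None:
        header = "x y phi theta psi defocus scale"
        rows = np.column_stack([self.x, self.y, self.euler, self.defocus, self.scale])
        np.savetxt(
            path,
            rows,
            header=header
            + f"\nnoise_sigma={self.noise_sigma} background={self.background} seed={self.seed}",
            fmt="%.6f",
        )

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        meta = {"noise_sigma": 0.0, "background": "none", "seed": 0}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") and "noise_sigma" in line:
                    for tok in line[1:].split():
                        k, _, v = tok.partition("=")
                        if k in meta:
                            meta[k] = type(meta[k])(v)
        rows = np.loadtxt(path, ndmin=2)
        if rows.size == 0:
            rows = np.zeros((0, 7))
        return cls(
            x=rows[:, 0],
            y=rows[:, 1],
            euler=rows[:, 2:5],
            defocus=rows[:, 5],
            scale=rows[:, 6],
            noise_sigma=float(meta["noise_sigma"]),
            background=str(meta["background"]),
            seed=int(meta["seed"]),
        )


def simulate_volume(
    model: AtomicModel,
    pixel_size: float,
    box_size: int,
    extra_b: float = 0.0,
    center: bool = True,
) -> DensityVolume:
    """Render an atomic model as a Gaussian-atom density volume.

    Each atom's Gaussian is integrated exactly over voxel cells (erf
    differences per axis), so the voxel sum equals the sum of atomic numbers
    of in-box atoms up to the >=4 sigma truncation.  With ``center=True`` the
    model's centre of mass is moved to the box centre, as for a matching
    template; with ``center=False`` atom coordinates map directly to voxel
    coordinates via ``pos / pixel_size``.
    """
    if box_size % 2 != 0:
        raise ValueError("box_size must be even")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if model.n_atoms == 0:
        raise ValueError("model has no atoms")
    n = box_size
    pos_vox = model.positions / pixel_size
    if center:
        pos_vox = pos_vox - model.center_of_mass() / pixel_size + n / 2.0
    data = np.zeros((n, n, n))
    n_clipped = 0
    for i in range(model.n_atoms):
        u = pos_vox[i]
        if np.any(u < 0) or np.any(u >= n):
            n_clipped += 1
            continue
        z_weight = atomic_number(model.elements[i])
        sigma = math.sqrt(max(model.b_factors[i] + extra_b, 0.0) / (8 * math.pi**2))
        sigma_vox = max(sigma / pixel_size, _MIN_SIGMA_VOX)
        r = max(int(math.ceil(4 * sigma_vox)), 2)
        axes = []
        slices = []
        ok = True
        for d in range(3):
            lo = max(int(math.floor(u[d])) - r, 0)
            hi = min(int(math.floor(u[d])) + r + 1, n)
            if lo >= hi:
                ok = False
                break
            edges = np.arange(lo, hi + 1) - 0.5
            cdf = 0.5 * erf((edges - u[d]) / (sigma_vox * math.sqrt(2)))
            axes.append(np.diff(cdf))
            slices.append(slice(lo, hi))
        if not ok:
            continue
        blob = z_weight * axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
        data[slices[0], slices[1], slices[2]] += blob
    vol = DensityVolume(data=data, pixel_size=pixel_size)
    vol.n_clipped_atoms = n_clipped  # type: ignore[attr-defined]
    return vol


def rotation_matrix_zyz(phi: float, theta: float, psi: float) -> np.ndarray:
    """Intrinsic ZYZ rotation matrix from Euler angles in degrees."""
    def rz(a: float) -> np.ndarray:
        c, s = math.cos(a), math.sin(a)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def ry(a: float) -> np.ndarray:
        c, s = math.cos(a), math.sin(a)
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

    p, t, q = (math.radians(v) for v in (phi, theta, psi))
    return rz(p) @ ry(t) @ rz(q)


# Fourier-slice operations use a 2x zero-padded (oversampled) transform so
# that linear interpolation on the Fourier grid stays accurate.
OVERSAMPLE = 2


def centered_fft3(data: np.ndarray, oversample: int = OVERSAMPLE) -> np.ndarray:
    """3D FFT with both origins at the centre voxel, optionally zero-padded.

    With ``oversample`` > 1 the real-space array is symmetrically padded to
    ``oversample * n`` before the transform, which samples the FT on a grid
    ``oversample`` times finer and makes linear slice interpolation accurate.
    """
    n = data.shape[0]
    if oversample > 1:
        w = (oversample - 1) * n // 2
        data = np.pad(data, w)
    return fftshift(fftn(ifftshift(data)))


def _central_slice(vol_ft: np.ndarray, rot: np.ndarray, box: int) -> np.ndarray:
    """Sample the central plane perpendicular to the rotated z axis.

    ``rot`` rotates the object; the slice samples ``rot.T @ (kx, ky, 0)``
    (scaled by the FT's oversampling factor, inferred from its shape) on the
    centered 3D FT with linear interpolation; out-of-grid samples are zero.
    Returns a ``box x box`` centered 2D FT.
    """
    os_factor = vol_ft.shape[0] // box
    c_big = vol_ft.shape[0] // 2
    c = box // 2
    k = np.arange(box) - c
    kx, ky = np.meshgrid(k, k, indexing="ij")
    plane = np.stack([kx, ky, np.zeros_like(kx)], axis=0).reshape(3, -1)
    coords = rot.T @ (os_factor * plane) + c_big
    re = map_coordinates(vol_ft.real, coords, order=1, mode="constant", cval=0.0)
    im = map_coordinates(vol_ft.imag, coords, order=1, mode="constant", cval=0.0)
    return (re + 1j * im).reshape(box, box)


def project(
    volume: DensityVolume,
    euler: tuple[float, float, float] = (0.0, 0.0, 0.0),
    shift: tuple[float, float] = (0.0, 0.0),
    vol_ft: np.ndarray | None = None,
) -> Image2D:
    """Line-integral projection of the rotated volume along the beam (z) axis.

    Implemented by central-slice extraction from the volume's centered FT
    (projection theorem) with linear interpolation; ``shift`` moves the
    projection by (sx, sy) pixels via a Fourier phase ramp.  Pass a
    precomputed ``vol_ft`` (from :func:`centered_fft3`) when projecting the
    same volume many times.
    """
    n = volume.box_size
    if abs(shift[0]) >= n / 2 or abs(shift[1]) >= n / 2:
        raise ValueError("shift must be smaller than half the box")
    if vol_ft is None:
        vol_ft = centered_fft3(volume.data)
    rot = rotation_matrix_zyz(*euler)
    sl = _central_slice(vol_ft, rot, n)
    if shift != (0.0, 0.0):
        k = np.arange(n) - n // 2
        phase = np.exp(
            -2j * math.pi * (k[:, None] * shift[0] + k[None, :] * shift[1]) / n
        )
        sl = sl * phase
    proj = fftshift(ifft2(ifftshift(sl))).real
    return Image2D(data=proj, pixel_size=volume.pixel_size)


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom for voltage in kV."""
    v = voltage_kv * 1e3
    return 12.2639 / math.sqrt(v * (1.0 + 0.97845e-6 * v))


def ctf_2d(size: int, pixel_size: float, ctf: CTFParams) -> np.ndarray:
    """Evaluate CTF(k) on the unshifted FFT frequency grid of a square image.

    CTF(k) = -[ w cos(chi) + sqrt(1 - w^2) sin(chi) ],
    chi(k) = pi lambda df k^2 - (pi/2) Cs lambda^3 k^4, underfocus positive.
    """
    lam = electron_wavelength(ctf.voltage)
    freqs = np.fft.fftfreq(size, d=pixel_size)
    kx, ky = np.meshgrid(freqs, freqs, indexing="ij")
    k2 = kx**2 + ky**2
    if ctf.astigmatism != 0.0:
        ang = np.arctan2(ky, kx) - math.radians(ctf.astigmatism_angle)
        df = ctf.defocus + ctf.astigmatism * np.cos(2 * ang)
    else:
        df = ctf.defocus
    cs_A = ctf.cs * 1e7  # mm -> Angstrom
    chi = math.pi * lam * df * k2 - 0.5 * math.pi * cs_A * lam**3 * k2**2
    w = ctf.amplitude_contrast
    return -(w * np.cos(chi) + math.sqrt(1.0 - w**2) * np.sin(chi))


def apply_ctf(image: Image2D, ctf: CTFParams) -> Image2D:
    """Multiply the image FT by the CTF; output is real."""
    h = ctf_2d(image.size, image.pixel_size, ctf)
    out = ifft2(fft2(image.data) * h).real
    return Image2D(data=out, pixel_size=image.pixel_size)


def _random_orientations(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform orientations: phi, psi uniform; cos(theta) uniform."""
    phi = rng.uniform(0.0, 360.0, n)
    theta = np.degrees(np.arccos(rng.uniform(-1.0, 1.0, n)))
    psi = rng.uniform(0.0, 360.0, n)
    return np.column_stack([phi, theta, psi])


def _place_particles(
    rng: np.random.Generator, n: int, image_size: int, box_size: int
) -> np.ndarray:
    """Non-overlapping particle centres (Chebyshev spacing >= box_size)."""
    margin = box_size / 2.0
    lo, hi = margin, image_size - margin
    if hi <= lo:
        raise ValueError("particles do not fit in the frame")
    placed: list[tuple[float, float]] = []
    max_attempts = 2000 * max(n, 1)
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} non-overlapping particles in {image_size} px"
            )
        x, y = rng.uniform(lo, hi), rng.uniform(lo, hi)
        if all(max(abs(x - px), abs(y - py)) >= box_size for px, py in placed):
            placed.append((x, y))
    return np.array(placed).reshape(-1, 2)


def synth_micrograph(
    volume: DensityVolume,
    n_particles: int,
    image_size: int,
    noise_sigma: float,
    defocus_range: tuple[float, float] = (10000.0, 10000.0),
    background: Literal["none", "gradient", "blobs"] = "none",
    seed: int = 0,
    ctf: CTFParams | None = None,
    amplitude: float = 1.0,
) -> tuple[Image2D, GroundTruth]:
    """Plant CTF-filtered projections at random poses in Gaussian noise.

    Orientations are uniform over SO(3), defocus uniform in
    ``defocus_range``, positions uniform with a half-box margin and
    non-overlapping boxes.  ``background`` adds a smooth non-uniform field
    (a planar ramp or broad Gaussian blobs with amplitudes of order
    ``noise_sigma``) that deliberately violates the white-Gaussian noise
    assumption of the matched-filter threshold model.  The same seed
    reproduces the micrograph bit for bit.
    """
    rng = np.random.default_rng(seed)
    box = volume.box_size
    if n_particles > 0 and image_size < 2 * box:
        raise ValueError("image too small for the template box")
    base_ctf = ctf if ctf is not None else CTFParams()
    xy = _place_particles(rng, n_particles, image_size, box)
    eulers = _random_orientations(rng, n_particles)
    defoci = rng.uniform(defocus_range[0], defocus_range[1], n_particles)
    scales = np.full(n_particles, float(amplitude))
    canvas = np.zeros((image_size, image_size))
    vol_ft = centered_fft3(volume.data) if n_particles else None
    for i in range(n_particles):
        x, y = xy[i]
        ix, iy = int(round(x)), int(round(y))
        fx, fy = x - ix, y - iy
        proj = project(volume, tuple(eulers[i]), shift=(fx, fy), vol_ft=vol_ft)
        proj = apply_ctf(proj, base_ctf.with_defocus(defoci[i]))
        x0, y0 = ix - box // 2, iy - box // 2
        canvas[x0 : x0 + box, y0 : y0 + box] += scales[i] * proj.data
    # Smooth background field s(x) in [-1, 1].  It enters both additively
    # (scaled by noise_sigma) and as a modulation of the local noise power,
    # emulating variable specimen thickness: thicker regions scatter more,
    # raising background and noise together.  Either effect violates the
    # stationary white-Gaussian assumption behind the erfc threshold model.
    field = np.zeros((image_size, image_size))
    if background == "gradient":
        ax = np.linspace(-1.0, 1.0, image_size)
        field = 0.6 * ax[:, None] + 0.4 * ax[None, :]
    elif background == "blobs":
        ax = np.arange(image_size)
        for _ in range(6):
            cx, cy = rng.uniform(0, image_size, 2)
            amp = rng.uniform(-1.0, 1.0)
            s = image_size / 6.0
            field += amp * np.exp(
                -((ax[:, None] - cx) ** 2 + (ax[None, :] - cy) ** 2) / (2 * s**2)
            )
        peak = np.abs(field).max()
        if peak > 0:
            field /= peak
    elif background != "none":
        raise ValueError(f"unknown background {background!r}")
    canvas += 1.5 * noise_sigma * field
    if noise_sigma > 0:
        sigma_local = noise_sigma * (1.0 + 0.4 * field)
        canvas = canvas + sigma_local * rng.standard_normal(canvas.shape)
    truth = GroundTruth(
        x=xy[:, 0] if n_particles else np.zeros(0),
        y=xy[:, 1] if n_particles else np.zeros(0),
        euler=eulers.reshape(-1, 3),
        defocus=defoci,
        scale=scales,
        noise_sigma=noise_sigma,
        background=background,
        seed=seed,
    )
    return Image2D(data=canvas, pixel_size=volume.pixel_size), truth


def amplitude_for_peak_snr(
    volume: DensityVolume,
    ctf: CTFParams,
    noise_sigma: float,
    target_snr: float,
    n_orientations: int = 8,
    seed: int = 7,
) -> float:
    """Particle amplitude that yields an expected matched-filter peak of
    ``target_snr`` against white noise of standard deviation ``noise_sigma``.

    The expected calibrated score at the true pose is a * ||P|| / sigma,
    where P is the zero-mean CTF-filtered projection; the norm is averaged
    over random orientations.
    """
    rng = np.random.default_rng(seed)
    eulers = _random_orientations(rng, n_orientations)
    vol_ft = centered_fft3(volume.data)
    norms = []
    for e in eulers:
        p = apply_ctf(project(volume, tuple(e), vol_ft=vol_ft), ctf).data
        norms.append(np.linalg.norm(p - p.mean()))
    return target_snr * noise_sigma / float(np.mean(norms))


def synthetic_model(
    n_chains: int = 2,
    n_residues: int = 20,
    seed: int = 0,
    step: float = 3.8,
    confine_radius: float | None = None,
) -> AtomicModel:
    """Random-walk polymer stand-in for a macromolecule.

    Each residue carries four heavy atoms (N, CA, C, O) jittered around a
    backbone position; successive backbone positions are ``step`` Angstrom
    apart and the walk is confined to a compact sphere so the model projects
    to an asymmetric, globular blob.
    """
    rng = np.random.default_rng(seed)
    if confine_radius is None:
        confine_radius = 1.2 * step * (n_residues * n_chains) ** (1.0 / 3.0)
    elements: list[str] = []
    positions: list[np.ndarray] = []
    b_factors: list[float] = []
    chain_ids: list[str] = []
    residue_indices: list[int] = []
    atom_names: list[str] = []
    residue_names: list[str] = []
    atom_set = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]
    for c in range(n_chains):
        cid = chr(ord("A") + c)
        pos = rng.uniform(-0.3, 0.3, 3) * confine_radius
        for r in range(1, n_residues + 1):
            while True:
                d = rng.normal(size=3)
                cand = pos + step * d / np.linalg.norm(d)
                if np.linalg.norm(cand) <= confine_radius:
                    break
            pos = cand
            for name, elem in atom_set:
                elements.append(elem)
                positions.append(pos + rng.normal(scale=0.8, size=3))
                b_factors.append(rng.uniform(10.0, 30.0))
                chain_ids.append(cid)
                residue_indices.append(r)
                atom_names.append(name)
                residue_names.append("GLY")
    return AtomicModel(
        elements=elements,
        positions=np.array(positions),
        b_factors=np.array(b_factors),
        chain_ids=chain_ids,
        residue_indices=np.array(residue_indices),
        atom_names=atom_names,
        residue_names=residue_names,
        source_id=f"synthetic(seed={seed})",
    )


# ---------------------------------------------------------------------------
# MRC I/O (mode 2, 32-bit real) via gemmi's CCP4/MRC map support


def write_mrc(path: str | Path, data: np.ndarray, pixel_size: float) -> None:
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise ValueError("expected 2D or 3D data")
    grid = gemmi.FloatGrid(*data.shape)
    grid.set_unit_cell(
        gemmi.UnitCell(
            data.shape[0] * pixel_size,
            data.shape[1] * pixel_size,
            data.shape[2] * pixel_size,
            90,
            90,
            90,
        )
    )
    np.asarray(grid)[:] = data
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header(2, True)
    m.write_ccp4_map(str(path))


def read_mrc(path: str | Path) -> tuple[np.ndarray, float]:
    m = gemmi.read_ccp4_map(str(path))
    data = np.array(m.grid, dtype=np.float64)
    pixel = m.grid.unit_cell.a / m.grid.nu
    return data, pixel


def write_volume(volume: DensityVolume, path: str | Path) -> None:
    write_mrc(path, volume.data, volume.pixel_size)


def read_volume(path: str | Path) -> DensityVolume:
    data, pixel = read_mrc(path)
    return DensityVolume(data=data, pixel_size=pixel)


def write_image(image: Image2D, path: str | Path) -> None:
    write_mrc(path, image.data, image.pixel_size)


def read_image(path: str | Path) -> Image2D:
    data, pixel = read_mrc(path)
    if data.ndim == 3:
        data = data[:, :, 0]
    return Image2D(data=data, pixel_size=pixel)
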