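"""3D reconstruction from detected targets and resolution estimation.

Each boxed particle is treated as a CTF-modulated central slice of the 3D
object's Fourier transform: its (residual-shift-corrected) 2D FT is
multiplied by the CTF and spread into a 3D Fourier accumulator at its Euler
orientation with trilinear interpolation, while CTF^2 accumulates into a
weight volume.  Per-voxel Wiener-style normalization (CTF^2 sum plus a
small constant) yields the map.  Half-maps from even/odd particle indices
give a deterministic Fourier shell correlation, with the 0.143 criterion
for the resolution estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.fft import fft2, fftshift, ifftn, ifftshift

from .matcher import Target
from .simulate import (
    CTFParams,
    DensityVolume,
    Image2D,
    ctf_2d,
    rotation_matrix_zyz,
    read_mrc,
    write_mrc,
)

__all__ = [
    "ParticleStack",
    "Reconstruction",
    "FSCCurve",
    "extract_particles",
    "concat_stacks",
    "reconstruct_3d",
    "accumulate_insertions",
    "fsc",
    "resolution_at_threshold",
]


@dataclass
class ParticleStack:
    """Boxed particles with their alignment parameters."""

    boxes: np.ndarray  # (m, box, box)
    eulers: np.ndarray  # (m, 3) degrees
    shifts: np.ndarray  # (m, 2) residual sub-pixel shifts
    defoci: np.ndarray  # (m,)
    pixel_size: float
    source_ids: list[str]

    def __post_init__(self) -> None:
        self.boxes = np.asarray(self.boxes, dtype=np.float64)
        self.eulers = np.asarray(self.eulers, dtype=np.float64).reshape(-1, 3)
        self.shifts = np.asarray(self.shifts, dtype=np.float64).reshape(-1, 2)
        self.defoci = np.asarray(self.defoci, dtype=np.float64).ravel()
        m = len(self.boxes)
        if not (len(self.eulers) == len(self.shifts) == len(self.defoci) == m):
            raise ValueError("one parameter row per box required")

    @property
    def n_particles(self) -> int:
        return len(self.boxes)

    @property
    def box_size(self) -> int:
        return self.boxes.shape[1] if self.n_particles else 0

    def save(self, mrc_path: str | Path, params_path: str | Path) -> None:
        write_mrc(mrc_path, np.moveaxis(self.boxes, 0, 2), self.pixel_size)
        rows = np.column_stack([self.eulers, self.shifts, self.defoci])
        np.savetxt(params_path, rows, header="phi theta psi sx sy defocus", fmt="%.6f")

    @classmethod
    def load(cls, mrc_path: str | Path, params_path: str | Path) -> "ParticleStack":
        data, pixel = read_mrc(mrc_path)
        boxes = np.moveaxis(data, 2, 0)
        rows = np.loadtxt(params_path, ndmin=2)
        return cls(
            boxes=boxes,
            eulers=rows[:, 0:3],
            shifts=rows[:, 3:5],
            defoci=rows[:, 5],
            pixel_size=pixel,
            source_ids=[str(mrc_path)] * len(boxes),
        )


@dataclass
class Reconstruction:
    full: DensityVolume
    half_a: DensityVolume
    half_b: DensityVolume
    n_particles_used: int


@dataclass
class FSCCurve:
    """Per-shell spatial frequency (1/A) and correlation."""

    freqs: np.ndarray
    correlations: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.correlations = np.asarray(self.correlations, dtype=np.float64)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("shell frequencies must be strictly increasing")

    @property
    def resolution_0143(self) -> float | None:
        return resolution_at_threshold(self, 0.143)

    def save(self, path: str | Path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.freqs, self.correlations]),
            header="frequency_1_per_A correlation",
            fmt="%.6f",
        )


def extract_particles(
    image: Image2D, targets: list[Target], box_size: int
) -> ParticleStack:
    """Box out targets centered on their rounded positions.

    The sub-pixel residual of each position is stored as the particle's
    shift.  Targets whose box would leave the image are skipped (their count
    is recorded on the returned stack as ``n_skipped``).
    """
    if box_size % 2 != 0:
        raise ValueError("box_size must be even")
    n = image.size
    if box_size > n:
        raise ValueError("box larger than image")
    boxes, eulers, shifts, defoci = [], [], [], []
    n_skipped = 0
    for t in targets:
        ix, iy = int(round(t.x)), int(round(t.y))
        x0, y0 = ix - box_size // 2, iy - box_size // 2
        if x0 < 0 or y0 < 0 or x0 + box_size > n or y0 + box_size > n:
            n_skipped += 1
            continue
        boxes.append(image.data[x0 : x0 + box_size, y0 : y0 + box_size].copy())
        eulers.append(t.euler)
        shifts.append((t.x - ix, t.y - iy))
        defoci.append(t.defocus)
    if not boxes:
        warnings.warn("no in-bounds targets; stack is empty")
    stack = ParticleStack(
        boxes=np.array(boxes).reshape(-1, box_size, box_size),
        eulers=np.array(eulers).reshape(-1, 3),
        shifts=np.array(shifts).reshape(-1, 2),
        defoci=np.array(defoci),
        pixel_size=image.pixel_size,
        source_ids=["image"] * len(boxes),
    )
    stack.n_skipped = n_skipped  # type: ignore[attr-defined]
    return stack


def concat_stacks(stacks: list[ParticleStack]) -> ParticleStack:
    stacks = [s for s in stacks if s.n_particles > 0]
    if not stacks:
        raise ValueError("no particles to concatenate")
    if len({s.box_size for s in stacks}) != 1:
        raise ValueError("all stacks must share a box size")
    return ParticleStack(
        boxes=np.concatenate([s.boxes for s in stacks]),
        eulers=np.concatenate([s.eulers for s in stacks]),
        shifts=np.concatenate([s.shifts for s in stacks]),
        defoci=np.concatenate([s.defoci for s in stacks]),
        pixel_size=stacks[0].pixel_size,
        source_ids=sum([s.source_ids for s in stacks], []),
    )


def accumulate_insertions(
    stack: ParticleStack,
    indices: np.ndarray | None = None,
    ctf_base: CTFParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Insert the selected particles into a 3D Fourier accumulator.

    Returns (numerator, weights): the CTF-multiplied centered slice sum and
    the CTF^2 sum, both on a 2x-oversampled centered 3D Fourier grid (the
    same oversampling the projector uses), before normalization.  Insertion
    uses trilinear spreading.
    """
    from .simulate import OVERSAMPLE

    box = stack.box_size
    n = box
    big = OVERSAMPLE * n
    c_big = big // 2
    base = ctf_base if ctf_base is not None else CTFParams()
    if indices is None:
        indices = np.arange(stack.n_particles)
    num = np.zeros((big, big, big), dtype=np.complex128)
    wt = np.zeros((big, big, big))
    k = np.arange(n) - n // 2
    kx, ky = np.meshgrid(k, k, indexing="ij")
    plane = np.stack([kx, ky, np.zeros_like(kx)], axis=0).reshape(3, -1).astype(float)
    for i in indices:
        data = stack.boxes[i]
        ft = fftshift(fft2(ifftshift(data)))
        sx, sy = stack.shifts[i]
        if sx != 0.0 or sy != 0.0:
            phase = np.exp(2j * math.pi * (kx * sx + ky * sy) / n)
            ft = ft * phase
        ctf = fftshift(ctf_2d(n, stack.pixel_size, base.with_defocus(stack.defoci[i])))
        vals = (ctf * ft).ravel()
        w2 = (ctf * ctf).ravel()
        rot = rotation_matrix_zyz(*stack.eulers[i])
        q = rot.T @ (OVERSAMPLE * plane) + c_big
        q0 = np.floor(q).astype(int)
        frac = q - q0
        for corner in range(8):
            d = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
            idx = q0 + d[:, None]
            w = np.prod(
                np.where(d[:, None] == 1, frac, 1.0 - frac), axis=0
            )
            ok = np.all((idx >= 0) & (idx < big), axis=0)
            if not ok.any():
                continue
            np.add.at(num, (idx[0, ok], idx[1, ok], idx[2, ok]), w[ok] * vals[ok])
            np.add.at(wt, (idx[0, ok], idx[1, ok], idx[2, ok]), w[ok] * w2[ok])
    return num, wt


def _normalize(num: np.ndarray, wt: np.ndarray, wiener_fraction: float, pixel: float) -> DensityVolume:
    from .simulate import OVERSAMPLE

    eps = wiener_fraction * float(wt[wt > 0].mean()) if np.any(wt > 0) else 1.0
    vol_ft = num / (wt + eps)
    big = num.shape[0]
    box = big // OVERSAMPLE
    vol = fftshift(ifftn(ifftshift(vol_ft))).real * OVERSAMPLE**3
    lo = (big - box) // 2
    vol = vol[lo : lo + box, lo : lo + box, lo : lo + box]
    return DensityVolume(data=np.ascontiguousarray(vol), pixel_size=pixel)


def reconstruct_3d(
    stack: ParticleStack,
    box_size: int | None = None,
    wiener_fraction: float = 0.01,
    ctf_base: CTFParams | None = None,
) -> Reconstruction:
    """Reconstruct full and even/odd half maps from a particle stack.

    The Wiener constant added to the CTF^2 weights is ``wiener_fraction``
    of their mean over populated voxels.  The half-set split is by particle
    index parity (deterministic given the stack order).
    """
    if stack.n_particles == 0:
        raise ValueError("empty particle stack")
    if box_size is not None and box_size != stack.box_size:
        raise ValueError("reconstruction box must match the stack box")
    even = np.arange(0, stack.n_particles, 2)
    odd = np.arange(1, stack.n_particles, 2)
    num_a, wt_a = accumulate_insertions(stack, even, ctf_base)
    if len(odd):
        num_b, wt_b = accumulate_insertions(stack, odd, ctf_base)
    else:
        num_b, wt_b = np.zeros_like(num_a), np.zeros_like(wt_a)
    full = _normalize(num_a + num_b, wt_a + wt_b, wiener_fraction, stack.pixel_size)
    half_a = _normalize(num_a, wt_a, wiener_fraction, stack.pixel_size)
    half_b = _normalize(num_b, wt_b, wiener_fraction, stack.pixel_size)
    return Reconstruction(
        full=full, half_a=half_a, half_b=half_b, n_particles_used=stack.n_particles
    )


def _shell_indices_3d(n: int) -> np.ndarray:
    k = np.arange(n) - n // 2
    r = np.sqrt(
        k[:, None, None] ** 2 + k[None, :, None] ** 2 + k[None, None, :] ** 2
    )
    return np.minimum(np.round(r).astype(int), n // 2)


def fsc(map_a: DensityVolume, map_b: DensityVolume) -> FSCCurve:
    """Fourier shell correlation between two maps (shell width 1 voxel)."""
    if map_a.box_size != map_b.box_size or map_a.pixel_size != map_b.pixel_size:
        raise ValueError("maps must share box and pixel size")
    n = map_a.box_size
    fa = fftshift(np.fft.fftn(ifftshift(map_a.data)))
    fb = fftshift(np.fft.fftn(ifftshift(map_b.data)))
    r = _shell_indices_3d(n)
    nshell = n // 2 + 1
    cross = np.bincount(r.ravel(), weights=(fa * np.conj(fb)).real.ravel(), minlength=nshell)
    pa = np.bincount(r.ravel(), weights=(np.abs(fa) ** 2).ravel(), minlength=nshell)
    pb = np.bincount(r.ravel(), weights=(np.abs(fb) ** 2).ravel(), minlength=nshell)
    denom = np.sqrt(pa * pb)
    corr = np.where(denom > 0, cross / np.maximum(denom, 1e-300), 0.0)
    shells = np.arange(1, nshell)  # skip DC
    freqs = shells / (n * map_a.pixel_size)
    return FSCCurve(freqs=freqs, correlations=np.clip(corr[1:], -1.0, 1.0))


def resolution_at_threshold(curve: FSCCurve, threshold: float = 0.143) -> float | None:
    """Resolution (A) at the first crossing below the threshold.

    Linearly interpolates between the bracketing shells; returns None when
    the curve never drops below the threshold.
    """
    c = curve.correlations
    f = curve.freqs
    if len(c) == 0:
        raise ValueError("empty FSC curve")
    below = np.nonzero(c < threshold)[0]
    if len(below) == 0:
        return None
    i = below[0]
    if i == 0:
        return float(1.0 / f[0])
    frac = (c[i - 1] - threshold) / (c[i - 1] - c[i])
    f_cross = f[i - 1] + frac * (f[i] - f[i - 1])
    return float(1.0 / f_cross)
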