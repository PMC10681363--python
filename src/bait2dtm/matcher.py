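"""Whitened 2D template matching.

The search cross-correlates a 3D template's CTF-modulated projections with a
spectrally whitened micrograph over a grid of orientations and defocus
offsets.  Scores are calibrated so that pure-noise locations are standard
normal ("2DTM SNR"): the image is whitened and rescaled to unit real-space
variance, and each projection is filtered with the same whitening filter,
made zero-mean, and normalized to unit Euclidean norm before correlation.
The per-pixel maximum over the grid, together with its argmax orientation
and defocus, forms the SNR map from which targets are extracted by greedy
thresholded peak picking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.fft import fft2, fftshift, ifft2, ifftshift

from . import noise_model
from .simulate import (
    CTFParams,
    DensityVolume,
    Image2D,
    _central_slice,
    centered_fft3,
    ctf_2d,
    rotation_matrix_zyz,
)

__all__ = [
    "SearchGrid",
    "SNRMap",
    "Target",
    "WhiteningFilter",
    "whiten",
    "count_search_locations",
    "match_template_2d",
    "find_peaks",
    "refine_target",
    "auto_threshold",
    "save_targets",
    "load_targets",
]


@dataclass
class SearchGrid:
    """Orientation/defocus search grid.

    Orientations are rings of constant out-of-plane angle theta spaced by
    ``out_of_plane_step``; each ring carries ~ round(phi_range sin(theta) /
    step) azimuth samples, and the in-plane angle psi is sampled uniformly
    at ``in_plane_step``.  Cn symmetry restricts phi to [0, 360/n); Dn
    additionally restricts theta to [0, 90].
    """

    in_plane_step: float
    out_of_plane_step: float
    symmetry: str = "C1"
    defocus_offsets: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if self.in_plane_step <= 0 or self.out_of_plane_step <= 0:
            raise ValueError("angular steps must be > 0")
        if not self.defocus_offsets:
            raise ValueError("need at least one defocus offset")
        self.defocus_offsets = tuple(float(d) for d in self.defocus_offsets)

    @staticmethod
    def defocus_offsets_from_range(defocus_range: float, defocus_step: float) -> tuple[float, ...]:
        """Offsets -range ... +range inclusive with the given step."""
        if defocus_range == 0:
            return (0.0,)
        k = int(round(defocus_range / defocus_step))
        return tuple(defocus_step * i for i in range(-k, k + 1))

    @property
    def orientations(self) -> np.ndarray:
        """(n, 3) array of (phi, theta, psi) in degrees."""
        sym = self.symmetry.strip().upper()
        if len(sym) < 2 or sym[0] not in "CD" or not sym[1:].isdigit():
            raise ValueError(f"unsupported symmetry {sym!r}")
        fold = int(sym[1:])
        theta_max = 90.0 if sym[0] == "D" else 180.0
        phi_range = 360.0 / fold
        thetas = np.arange(0.0, theta_max + 1e-9, self.out_of_plane_step)
        psis = np.arange(0.0, 360.0, self.in_plane_step)
        rows = []
        for theta in thetas:
            n_phi = max(1, int(round(phi_range * math.sin(math.radians(theta)) / self.out_of_plane_step)))
            for phi in (phi_range * np.arange(n_phi) / n_phi):
                for psi in psis:
                    rows.append((phi, theta, psi))
        return np.array(rows)

    @property
    def n_orientations(self) -> int:
        return len(self.orientations)


@dataclass
class Target:
    """One detected particle: position, pose, defocus and calibrated score."""

    x: float
    y: float
    euler: tuple[float, float, float]
    defocus: float
    snr: float
    near_edge: bool = False


@dataclass
class SNRMap:
    """Per-pixel best calibrated score with its argmax grid indices."""

    best_score: np.ndarray
    best_orientation_index: np.ndarray
    best_defocus_index: np.ndarray
    grid: SearchGrid
    ctf_base: CTFParams
    pixel_size: float
    template_box: int
    n_exceedances: int | None = None  # locations above exceedance_threshold

    @property
    def size(self) -> int:
        return self.best_score.shape[0]


@dataclass
class WhiteningFilter:
    """Radial whitening weights, one per integer Fourier shell of the image."""

    profile: np.ndarray
    size: int

    def weights_2d(self) -> np.ndarray:
        """Weights on the unshifted FFT grid of the image."""
        r = _shell_indices(self.size)
        return self.profile[r]


def _shell_indices(n: int) -> np.ndarray:
    f = np.fft.fftfreq(n) * n
    r = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2)
    return np.minimum(np.round(r).astype(int), n // 2)


# PSD smoothing (in shells) used when whitening for matched filtering; see
# the whiten docstring.  Exact flattening (0) is the default for the public
# whiten operation, but it couples the filter to the same fluctuations a
# matched filter scores against and deflates the far tail of the score
# distribution; a mildly smoothed estimate restores Gaussian tails.
MATCH_PSD_SMOOTHING = 1.5


def whiten(image: Image2D, psd_smoothing: float = 0.0) -> tuple[Image2D, WhiteningFilter]:
    """Flatten the image's radial power spectrum and rescale to unit variance.

    The FT is divided by the square root of the radially averaged power
    spectrum (the DC weight is zero, removing the mean), so that shell
    powers of the output are flat and, for Gaussian noise input, the output
    is white with unit variance.

    With ``psd_smoothing`` > 0 the radial spectrum is smoothed across shells
    (Gaussian, that many shells wide, in the log domain) before inversion.
    Exact division (the default) flattens every shell exactly, but a shell
    estimate made from the very fluctuations a matched filter will score
    suppresses its own high-score events and deflates the far tail of the
    calibrated score distribution; the matcher therefore whitens internally
    with ``MATCH_PSD_SMOOTHING`` shells of smoothing, which restores
    standard-normal tails (at the price of shell powers flat only to within
    the spectral estimate's sampling noise).
    """
    from scipy.ndimage import gaussian_filter1d

    data = image.data
    if np.ptp(data) == 0:
        raise ValueError("cannot whiten a constant image (zero spectrum)")
    n = image.size
    ft = fft2(data)
    power = np.abs(ft) ** 2
    r = _shell_indices(n)
    counts = np.bincount(r.ravel(), minlength=n // 2 + 1)
    sums = np.bincount(r.ravel(), weights=power.ravel(), minlength=n // 2 + 1)
    psd = sums / np.maximum(counts, 1)
    nz = psd > 0
    if psd_smoothing > 0 and nz[1:].all():
        log_psd = np.log(psd[1:])
        psd[1:] = np.exp(gaussian_filter1d(log_psd, psd_smoothing, mode="nearest"))
    profile = np.zeros_like(psd)
    profile[nz] = 1.0 / np.sqrt(psd[nz])
    profile[0] = 0.0  # remove DC
    out = ifft2(ft * profile[r]).real
    sd = out.std()
    if sd == 0:
        raise ValueError("whitening produced a constant image")
    out = out / sd
    return Image2D(data=out, pixel_size=image.pixel_size), WhiteningFilter(profile, n)


def count_search_locations(image_size: int, grid: SearchGrid) -> int:
    """Pixels x orientations x defocus offsets."""
    return int(image_size) ** 2 * grid.n_orientations * len(grid.defocus_offsets)


def auto_threshold(image_size: int, grid: SearchGrid, n_expected: float = 1.0) -> float:
    """Threshold admitting ``n_expected`` false positives per image."""
    return noise_model.threshold_for_expected_count(
        count_search_locations(image_size, grid), n_expected
    )


def _embedded_projection(
    slice_ctf: np.ndarray, box: int, n: int
) -> np.ndarray:
    """Real-space projection from a centered Fourier slice, embedded in an
    n x n frame with the projection centre at pixel (0, 0)."""
    proj = fftshift(ifft2(ifftshift(slice_ctf))).real
    frame = np.zeros((n, n))
    frame[:box, :box] = proj
    return np.roll(frame, (-(box // 2), -(box // 2)), axis=(0, 1))


def match_template_2d(
    image: Image2D,
    template: DensityVolume,
    grid: SearchGrid,
    ctf_base: CTFParams,
    whiten_input: bool = True,
    whitening_filter: WhiteningFilter | None = None,
    exceedance_threshold: float | None = None,
) -> SNRMap:
    """Exhaustive whitened matched-filter search over the grid.

    For every orientation and defocus offset the template's central-slice
    projection is CTF-modulated, whitened with the image's filter, zero-mean
    unit-norm normalized, and circularly cross-correlated with the whitened
    image by FFT.  Per pixel the maximum score over the grid is retained;
    ties go to the lowest orientation index, then the lowest defocus index.

    With ``exceedance_threshold`` set, the total number of (pixel,
    orientation, defocus) locations scoring above it is counted on the fly
    (the quantity the Gaussian false-positive model predicts) and stored on
    the returned map.
    """
    n = image.size
    box = template.box_size
    if box > n:
        raise ValueError("template larger than image")
    if template.pixel_size != image.pixel_size:
        raise ValueError("template and image pixel sizes differ")
    if whiten_input:
        img_w, filt = whiten(image, psd_smoothing=MATCH_PSD_SMOOTHING)
    else:
        if whitening_filter is None:
            raise ValueError("pre-whitened input requires the whitening filter")
        img_w, filt = image, whitening_filter
    import scipy.fft as sfft

    # whitening weights on the rfft2 half grid
    f = np.fft.fftfreq(n) * n
    fr = np.arange(n // 2 + 1)
    r_half = np.minimum(
        np.round(np.sqrt(f[:, None] ** 2 + fr[None, :] ** 2)).astype(int), n // 2
    )
    w2d = filt.profile[r_half].astype(np.float32)
    img_ft = sfft.rfft2(img_w.data.astype(np.float32))
    vol_ft = centered_fft3(template.data)
    orientations = grid.orientations
    best = np.full((n, n), -np.inf, dtype=np.float32)
    best_oi = np.zeros((n, n), dtype=np.int32)
    best_di = np.zeros((n, n), dtype=np.int32)
    ctfs = [
        ctf_2d(box, template.pixel_size, ctf_base.with_defocus(ctf_base.defocus + off))
        for off in grid.defocus_offsets
    ]
    # CTF grids are on the unshifted box FFT grid; slices are centered
    ctfs = [fftshift(c) for c in ctfs]
    n_exceed = 0
    for oi, euler in enumerate(orientations):
        rot = rotation_matrix_zyz(*euler)
        sl = _central_slice(vol_ft, rot, box)
        for di in range(len(grid.defocus_offsets)):
            t_frame = _embedded_projection(sl * ctfs[di], box, n).astype(np.float32)
            t_ft = sfft.rfft2(t_frame)
            t_ft *= w2d
            t_ft[0, 0] = 0.0
            # real-space sum of squares from the half grid (self-conjugate
            # columns ky=0 and ky=n/2 are stored once)
            p = np.abs(t_ft) ** 2
            total = 2.0 * p.sum() - p[:, 0].sum() - p[:, -1].sum()
            norm = math.sqrt(float(total) / (n * n))
            if norm == 0:
                continue
            scores = sfft.irfft2(img_ft * np.conj(t_ft), s=(n, n)) / np.float32(norm)
            if exceedance_threshold is not None:
                n_exceed += int((scores > exceedance_threshold).sum())
            improved = scores > best
            if improved.any():
                best[improved] = scores[improved]
                best_oi[improved] = oi
                best_di[improved] = di
    return SNRMap(
        best_score=best.astype(np.float64),
        best_orientation_index=best_oi,
        best_defocus_index=best_di,
        grid=grid,
        ctf_base=ctf_base,
        pixel_size=image.pixel_size,
        template_box=box,
        n_exceedances=n_exceed if exceedance_threshold is not None else None,
    )


def find_peaks(
    snr_map: SNRMap, threshold: float, exclusion_radius: float | None = None
) -> list[Target]:
    """Greedy peak extraction above a threshold.

    Peaks are accepted in descending score order; each accepted peak
    suppresses every pixel within ``exclusion_radius`` (default: half the
    template box).  Targets within half a template box of the image border
    are flagged ``near_edge`` (correlation is circular), not dropped.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if exclusion_radius is None:
        exclusion_radius = snr_map.template_box / 2.0
    if exclusion_radius < 1:
        raise ValueError("exclusion_radius must be >= 1")
    n = snr_map.size
    scores = snr_map.best_score
    xs, ys = np.nonzero(scores > threshold)
    if len(xs) == 0:
        return []
    vals = scores[xs, ys]
    order = np.lexsort((ys, xs, -vals))  # descending score, deterministic ties
    xs, ys, vals = xs[order], ys[order], vals[order]
    acc_x: list[int] = []
    acc_y: list[int] = []
    targets: list[Target] = []
    r2 = exclusion_radius**2
    half_box = snr_map.template_box / 2.0
    grid_orient = snr_map.grid.orientations
    offsets = snr_map.grid.defocus_offsets
    for x, y, v in zip(xs, ys, vals):
        if acc_x:
            dx = np.array(acc_x) - x
            dy = np.array(acc_y) - y
            if np.any(dx * dx + dy * dy <= r2):
                continue
        acc_x.append(int(x))
        acc_y.append(int(y))
        oi = int(snr_map.best_orientation_index[x, y])
        di = int(snr_map.best_defocus_index[x, y])
        near_edge = (
            min(x, n - 1 - x) < half_box or min(y, n - 1 - y) < half_box
        )
        targets.append(
            Target(
                x=float(x),
                y=float(y),
                euler=tuple(grid_orient[oi]),
                defocus=snr_map.ctf_base.defocus + offsets[di],
                snr=float(v),
                near_edge=near_edge,
            )
        )
    return targets


def _box_whitening_weights(filt: WhiteningFilter, box: int) -> np.ndarray:
    """Image whitening profile resampled onto the box-size FFT grid."""
    f = np.fft.fftfreq(box) * filt.size  # shells of the image grid
    r = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2)
    idx = np.minimum(np.round(r).astype(int), len(filt.profile) - 1)
    return filt.profile[idx]


def _whitened_patch(
    vol_ft: np.ndarray,
    euler: tuple[float, float, float],
    ctf_centered: np.ndarray,
    w_box: np.ndarray,
) -> np.ndarray:
    """Zero-mean unit-norm whitened template patch for local rescoring."""
    box = w_box.shape[0]
    sl = _central_slice(vol_ft, rotation_matrix_zyz(*euler), box)
    proj = fftshift(ifft2(ifftshift(sl * ctf_centered))).real
    t_ft = fft2(proj) * w_box
    t_ft[0, 0] = 0.0
    patch = ifft2(t_ft).real
    norm = np.linalg.norm(patch)
    return patch / norm if norm > 0 else patch


def refine_target(
    image: Image2D,
    template: DensityVolume,
    target: Target,
    steps: tuple[float, float, float] = (0.5, 2.0, 0.0),
    n_steps: int = 1,
    whitened: tuple[Image2D, WhiteningFilter] | None = None,
    ctf_base: CTFParams | None = None,
) -> Target:
    """Local grid refinement of one detected target.

    ``steps`` = (angle step deg, shift search radius px, defocus step A);
    each Euler angle is searched over +- ``n_steps`` fine steps, positions
    over integer shifts within the radius with parabolic sub-pixel
    interpolation, defocus over +- ``n_steps`` steps (skipped when the step
    is 0).  Scoring matches the full search (whitened, zero-mean, unit-norm
    template; the whitening filter is resampled onto the template box).  If
    no candidate beats the input score the input target is returned
    unchanged, so the refined SNR never decreases.
    """
    d_ang, shift_r, d_def = steps
    if whitened is None:
        whitened = whiten(image, psd_smoothing=MATCH_PSD_SMOOTHING)
    img_w, filt = whitened
    n = img_w.size
    box = template.box_size
    vol_ft = centered_fft3(template.data)
    w_box = _box_whitening_weights(filt, box)
    sr = int(math.ceil(shift_r))
    ix, iy = int(round(target.x)), int(round(target.y))
    wh = box // 2 + sr
    rows = np.arange(ix - wh, ix + wh) % n
    cols = np.arange(iy - wh, iy + wh) % n
    window = img_w.data[np.ix_(rows, cols)]
    ang_offsets = [d_ang * k for k in range(-n_steps, n_steps + 1)] if d_ang > 0 else [0.0]
    def_offsets = [d_def * k for k in range(-n_steps, n_steps + 1)] if d_def > 0 else [0.0]
    best = None  # (score, euler, defocus, px, py, corr_surface)
    phi0, theta0, psi0 = target.euler
    from scipy.signal import fftconvolve

    base = ctf_base if ctf_base is not None else CTFParams()
    for dd in def_offsets:
        ctf_c = fftshift(
            ctf_2d(box, template.pixel_size, base.with_defocus(target.defocus + dd))
        )
        for dphi in ang_offsets:
            for dtheta in ang_offsets:
                for dpsi in ang_offsets:
                    euler = (phi0 + dphi, theta0 + dtheta, psi0 + dpsi)
                    patch = _whitened_patch(vol_ft, euler, ctf_c, w_box)
                    corr = fftconvolve(window, patch[::-1, ::-1], mode="valid")
                    px, py = np.unravel_index(np.argmax(corr), corr.shape)
                    score = corr[px, py]
                    if best is None or score > best[0]:
                        best = (score, euler, target.defocus + dd, px, py, corr)
    score, euler, defocus, px, py, corr = best
    if score <= target.snr:
        return target
    # parabolic sub-pixel interpolation on the correlation surface
    def parafit(c: np.ndarray, i: int, j: int, axis: int) -> float:
        if axis == 0:
            if i == 0 or i == c.shape[0] - 1:
                return 0.0
            a, b, cc = c[i - 1, j], c[i, j], c[i + 1, j]
        else:
            if j == 0 or j == c.shape[1] - 1:
                return 0.0
            a, b, cc = c[i, j - 1], c[i, j], c[i, j + 1]
        denom = a - 2 * b + cc
        return 0.5 * (a - cc) / denom if denom != 0 else 0.0

    fx = parafit(corr, px, py, 0)
    fy = parafit(corr, px, py, 1)
    new_x = ix + (px - sr) + fx
    new_y = iy + (py - sr) + fy
    return Target(
        x=float(new_x),
        y=float(new_y),
        euler=euler,
        defocus=float(defocus),
        snr=float(score),
        near_edge=target.near_edge,
    )


def save_targets(targets: list[Target], path: str | Path) -> None:
    rows = np.array(
        [[t.x, t.y, *t.euler, t.defocus, t.snr] for t in targets]
    ).reshape(-1, 7)
    np.savetxt(path, rows, header="x y phi theta psi defocus snr", fmt="%.6f")


def load_targets(path: str | Path) -> list[Target]:
    rows = np.loadtxt(path, ndmin=2)
    if rows.size == 0:
        return []
    return [
        Target(x=r[0], y=r[1], euler=(r[2], r[3], r[4]), defocus=r[5], snr=r[6])
        for r in rows
    ]
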