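"""MR/CT preprocessing: bias-field correction, Nyul–Udupa intensity
standardization to [0, 4095], Otsu body masking, background filling,
three-channel stacking, patch extraction and augmentation.

Coordinate convention: axis order (slice, row, col), 0-based indices, voxel
centers at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import DegenerateHistogramError, GeometryError, SamplingError
from .volume import BodyMask, ImageVolume, MultiSequenceVolume

STANDARD_RANGE = (0.0, 4095.0)
# robust landmark percentiles: p1, deciles, p99
LANDMARK_PERCENTILES = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 99.0)

MR_BACKGROUND = 0.0
CT_BACKGROUND = -1000.0


# ---------------------------------------------------------------------------
# bias-field correction
# ---------------------------------------------------------------------------

def _poly_design(shape, mask_idx, order: int) -> np.ndarray:
    coords = [
        (np.asarray(idx, dtype=float) / max(n - 1, 1)) * 2.0 - 1.0
        for idx, n in zip(mask_idx, shape)
    ]
    cols = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                cols.append(coords[0] ** i * coords[1] ** j * coords[2] ** k)
    return np.stack(cols, axis=1)


def correct_bias_field(
    mr: ImageVolume,
    mask: BodyMask,
    order: int = 3,
    iterations: int = 2,
    return_field: bool = False,
):
    """Remove a smooth multiplicative intensity field from an MR volume.

    The log-bias is estimated as a least-squares polynomial of total degree
    ``order`` fitted to the masked log-image, iterated with outlier
    down-weighting so sharp anatomy contributes less than the smooth trend.
    The output is rescaled so the masked mean intensity is preserved exactly.
    Any estimator honoring this contract (e.g. a full N4 implementation) can
    be swapped in behind the same signature.
    """
    mask.check_geometry(mr)
    m = mask.data
    vals = np.asarray(mr.data, dtype=float)[m]
    if vals.size == 0:
        raise ValueError("empty mask")
    if np.any(vals <= 0):
        raise ValueError("MR intensities must be strictly positive inside the mask")

    logv = np.log(vals)
    idx = np.nonzero(m)
    X = _poly_design(mr.shape, idx, order)
    w = np.ones_like(logv)
    coef = None
    for _ in range(max(1, iterations)):
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], logv * sw, rcond=None)
        resid = logv - X @ coef
        scale = 1.4826 * np.median(np.abs(resid - np.median(resid))) + 1e-12
        w = 1.0 / (1.0 + (resid / (2.5 * scale)) ** 2)

    full_idx = np.indices(mr.shape).reshape(3, -1)
    Xf = _poly_design(mr.shape, full_idx, order)
    log_field = (Xf @ coef).reshape(mr.shape)
    log_field -= log_field[m].mean()
    fld = np.exp(log_field)
    out = np.asarray(mr.data, dtype=float) / fld
    # enforce exact masked-mean preservation
    gain = vals.mean() / out[m].mean()
    out *= gain
    fld = fld / gain
    corrected = mr.with_data(out)
    if return_field:
        return corrected, fld
    return corrected


# ---------------------------------------------------------------------------
# Nyul–Udupa intensity standardization
# ---------------------------------------------------------------------------

@dataclass
class IntensityStandardizer:
    """Histogram-landmark intensity standardizer (Nyul–Udupa).

    ``standard_landmarks`` are the learned landmark positions on the fixed
    [0, 4095] scale, one per percentile in ``percentiles``.
    """

    percentiles: tuple = LANDMARK_PERCENTILES
    standard_landmarks: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.standard_landmarks is not None

    def to_dict(self) -> dict:
        return {
            "percentiles": list(self.percentiles),
            "standard_landmarks": [float(v) for v in self.standard_landmarks],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IntensityStandardizer":
        return cls(
            percentiles=tuple(d["percentiles"]),
            standard_landmarks=np.asarray(d["standard_landmarks"], dtype=float),
        )


def _volume_landmarks(vol: ImageVolume, mask: BodyMask, percentiles) -> np.ndarray:
    mask.check_geometry(vol)
    vals = np.asarray(vol.data, dtype=float)[mask.data]
    if vals.size == 0:
        raise DegenerateHistogramError("empty mask")
    lm = np.percentile(vals, percentiles)
    if lm[-1] <= lm[0]:
        raise DegenerateHistogramError("constant image: p99 <= p1")
    return lm


def fit_intensity_standardizer(
    training: list[tuple[ImageVolume, BodyMask]],
    percentiles=LANDMARK_PERCENTILES,
) -> IntensityStandardizer:
    """Learn the standard intensity scale from training volumes.

    Each volume's landmark percentiles are mapped by the affine transform
    taking its [p1, p99] onto [0, 4095]; the standard landmarks are the mean
    of those mapped landmarks (made strictly increasing when phantom-like
    histograms produce ties).
    """
    if not training:
        raise ValueError("need at least one training volume")
    lo, hi = STANDARD_RANGE
    mapped = []
    for vol, mask in training:
        lm = _volume_landmarks(vol, mask, percentiles)
        mapped.append(lo + (lm - lm[0]) / (lm[-1] - lm[0]) * (hi - lo))
    std = np.mean(mapped, axis=0)
    # strictly increasing (piecewise-constant inputs can tie deciles)
    eps = 1e-6 * (hi - lo)
    for i in range(1, len(std)):
        if std[i] <= std[i - 1]:
            std[i] = std[i - 1] + eps
    return IntensityStandardizer(tuple(percentiles), std)


def apply_intensity_standardizer(
    mr: ImageVolume, mask: BodyMask, std: IntensityStandardizer
) -> ImageVolume:
    """Map a volume onto the standard scale by piecewise-linear interpolation
    between its own landmarks and the learned ones; output clipped to
    [0, 4095]. Linear extrapolation (end-segment slope) beyond the landmarks,
    then clipping."""
    if not std.fitted:
        raise RuntimeError("standardizer has not been fitted")
    lm = _volume_landmarks(mr, mask, std.percentiles)
    # collapse duplicate input landmarks, keeping the mean target
    xs, ys = [], []
    i = 0
    target = np.asarray(std.standard_landmarks, dtype=float)
    while i < len(lm):
        j = i
        while j + 1 < len(lm) and lm[j + 1] == lm[i]:
            j += 1
        xs.append(lm[i])
        ys.append(target[i : j + 1].mean())
        i = j + 1
    xs, ys = np.asarray(xs), np.asarray(ys)
    x = np.asarray(mr.data, dtype=float)
    out = np.interp(x, xs, ys)
    if len(xs) > 1:
        lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        below = x < xs[0]
        above = x > xs[-1]
        out[below] = ys[0] + (x[below] - xs[0]) * lo_slope
        out[above] = ys[-1] + (x[above] - xs[-1]) * hi_slope
    out = np.clip(out, *STANDARD_RANGE)
    return mr.with_data(out)


# ---------------------------------------------------------------------------
# body masking and background filling
# ---------------------------------------------------------------------------

def compute_body_mask(
    image: ImageVolume,
    sigma_mm: float | None = None,
    morph_radius: int = 2,
) -> BodyMask:
    """Gaussian blur -> Otsu threshold (256-bin) -> binary closing -> hole
    fill -> keep the largest connected component.

    ``sigma_mm`` is the blur width in mm; ``None`` uses one voxel per axis.
    """
    data = np.asarray(image.data, dtype=float)
    if np.unique(data).size < 2:
        raise DegenerateHistogramError("constant image cannot be thresholded")
    if sigma_mm is None:
        sigma_vox = (1.0, 1.0, 1.0)
    else:
        sigma_vox = tuple(sigma_mm / s for s in image.spacing)
    blurred = ndimage.gaussian_filter(data, sigma=sigma_vox)
    thr = threshold_otsu(blurred, nbins=256)
    mask = blurred > thr
    if morph_radius > 0:
        struct = _ball(morph_radius, image.spacing)
        mask = ndimage.binary_closing(mask, structure=struct)
    mask = ndimage.binary_fill_holes(mask)
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return BodyMask(mask, image.spacing, image.origin)


def _ball(radius_vox: int, spacing) -> np.ndarray:
    # isotropic in-plane ball, spacing-scaled in z so thick slices close less
    rz = max(1, int(round(radius_vox * spacing[1] / spacing[0])))
    zz, yy, xx = np.meshgrid(
        np.arange(-rz, rz + 1) / max(rz, 1),
        np.arange(-radius_vox, radius_vox + 1) / radius_vox,
        np.arange(-radius_vox, radius_vox + 1) / radius_vox,
        indexing="ij",
    )
    return zz**2 + yy**2 + xx**2 <= 1.0


def otsu_threshold_bruteforce(values: np.ndarray, nbins: int = 256):
    """Exhaustive between-class-variance search over histogram thresholds.

    Independent reference for the Otsu step; O(nbins^2), test-sized inputs.
    Returns (threshold, best_variance, variance_at(t)) where the last item
    evaluates the between-class variance of an arbitrary threshold on the
    same histogram.
    """
    hist, edges = np.histogram(values.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = hist.sum()

    def variance_of_cut(cut: int) -> float:
        w0 = hist[:cut].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            return -1.0
        m0 = (hist[:cut] * centers[:cut]).sum() / w0
        m1 = (hist[cut:] * centers[cut:]).sum() / w1
        return float(w0 * w1 * (m0 - m1) ** 2)

    def variance_at(threshold: float) -> float:
        cut = int(np.searchsorted(centers, threshold, side="right"))
        return variance_of_cut(cut)

    best_t, best_var = centers[0], -1.0
    for cut in range(1, nbins):
        var = variance_of_cut(cut)
        if var > best_var:
            best_var = var
            best_t = centers[cut - 1]
    return float(best_t), best_var, variance_at


def fill_background(
    ct: ImageVolume, mr: MultiSequenceVolume, mask: BodyMask
) -> tuple[ImageVolume, MultiSequenceVolume]:
    """Outside the body mask, set CT to -1000 HU and all MR channels to 0."""
    mask.check_geometry(ct)
    mask.check_geometry(mr)
    bg = ~mask.data
    ct_out = np.asarray(ct.data, dtype=float).copy()
    ct_out[bg] = CT_BACKGROUND
    mr_out = np.asarray(mr.data, dtype=float).copy()
    mr_out[:, bg] = MR_BACKGROUND
    return ct.with_data(ct_out), mr.with_data(mr_out)


def stack_sequences(t1: ImageVolume, t2: ImageVolume, flair: ImageVolume) -> MultiSequenceVolume:
    """Combine the three sequences into one 3-channel volume (T1w, T2w, FLAIR)."""
    t1.check_geometry(t2)
    t1.check_geometry(flair)
    return MultiSequenceVolume(
        np.stack([t1.data, t2.data, flair.data]), t1.spacing, t1.origin
    )


def unstack_sequences(mr: MultiSequenceVolume) -> tuple[ImageVolume, ImageVolume, ImageVolume]:
    return tuple(mr.channel(name) for name in MultiSequenceVolume.CHANNELS)


# ---------------------------------------------------------------------------
# patch extraction and augmentation
# ---------------------------------------------------------------------------

@dataclass
class PatchPair:
    """Aligned multi-channel MR patch and CT patch from one axial position."""

    mr: np.ndarray  # (3, side, side)
    ct: np.ndarray  # (side, side)
    slice_index: int = -1
    row0: int = -1
    col0: int = -1

    def __post_init__(self):
        if self.mr.shape[1:] != self.ct.shape:
            raise ValueError("MR and CT patches must share their side length")

    @property
    def side(self) -> int:
        return self.ct.shape[0]


def sample_patches(
    mr: MultiSequenceVolume,
    ct: ImageVolume,
    mask: BodyMask,
    n: int,
    side: int = 128,
    min_body_fraction: float = 0.5,
    seed: int = 0,
) -> list[PatchPair]:
    """Draw ``n`` aligned MR/CT patch pairs, uniform over admissible positions.

    A position is admissible when the patch lies fully inside the slice and
    its body-voxel fraction is at least ``min_body_fraction``. Deterministic
    for a fixed seed (sampling with replacement).
    """
    ct.check_geometry(mr)
    ct.check_geometry(mask)
    nz, ny, nx = ct.shape
    if side > ny or side > nx:
        raise ValueError(f"patch side {side} exceeds slice dimensions ({ny}, {nx})")
    if not 0.0 <= min_body_fraction <= 1.0:
        raise ValueError("min_body_fraction must be in [0, 1]")
    if n == 0:
        return []

    admissible = []  # (slice, row0, col0) triples
    need = min_body_fraction * side * side
    for z in range(nz):
        ii = np.zeros((ny + 1, nx + 1))
        ii[1:, 1:] = np.cumsum(np.cumsum(mask.data[z].astype(float), axis=0), axis=1)
        sums = (
            ii[side:, side:] - ii[:-side, side:] - ii[side:, :-side] + ii[:-side, :-side]
        )
        rows, cols = np.nonzero(sums >= need - 1e-9)
        if rows.size:
            admissible.append(
                np.column_stack([np.full(rows.size, z), rows, cols])
            )
    if not admissible:
        raise SamplingError(
            f"no patch position satisfies body fraction >= {min_body_fraction}"
        )
    positions = np.concatenate(admissible, axis=0)
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(positions), size=n)
    pairs = []
    for z, r, c in positions[picks]:
        pairs.append(
            PatchPair(
                mr=np.asarray(mr.data[:, z, r : r + side, c : c + side], dtype=float).copy(),
                ct=np.asarray(ct.data[z, r : r + side, c : c + side], dtype=float).copy(),
                slice_index=int(z),
                row0=int(r),
                col0=int(c),
            )
        )
    return pairs


@dataclass
class AugmentParams:
    """Random geometric augmentation: horizontal flips, shifts, zooms, rotations."""

    flip_p: float = 0.5
    max_shift_frac: float = 0.10
    zoom_range: tuple = (0.9, 1.1)
    max_rot_deg: float = 10.0


def augment_pair(pair: PatchPair, params: AugmentParams | None = None, seed: int = 0) -> PatchPair:
    """Apply one random transform, identically to the MR channels and the CT.

    Exposed voxels are filled with the background values (MR 0, CT -1000);
    bilinear interpolation for both modalities. Degenerate parameters give the
    exact identity; a flip alone is an exact array reversal (involution).
    """
    params = params or AugmentParams()
    rng = np.random.default_rng(seed)
    mr = pair.mr
    ct = pair.ct
    if rng.random() < params.flip_p:
        mr = mr[:, :, ::-1]
        ct = ct[:, ::-1]

    side = pair.side
    rot = rng.uniform(-params.max_rot_deg, params.max_rot_deg) if params.max_rot_deg else 0.0
    zmin, zmax = params.zoom_range
    zoom = rng.uniform(zmin, zmax) if (zmin, zmax) != (1.0, 1.0) else 1.0
    shift = (
        rng.uniform(-params.max_shift_frac, params.max_shift_frac, size=2) * side
        if params.max_shift_frac
        else np.zeros(2)
    )
    if rot == 0.0 and zoom == 1.0 and not shift.any():
        return PatchPair(np.ascontiguousarray(mr), np.ascontiguousarray(ct),
                         pair.slice_index, pair.row0, pair.col0)

    th = np.deg2rad(rot)
    lin = (np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]) / zoom)
    center = (side - 1) / 2.0
    offset = np.array([center, center]) - lin @ np.array([center, center]) - lin @ shift
    ct_t = ndimage.affine_transform(
        np.asarray(ct, dtype=float), lin, offset=offset, order=1, cval=CT_BACKGROUND
    )
    mr_t = np.stack(
        [
            ndimage.affine_transform(
                np.asarray(chan, dtype=float), lin, offset=offset, order=1, cval=MR_BACKGROUND
            )
            for chan in mr
        ]
    )
    return PatchPair(mr_t, ct_t, pair.slice_index, pair.row0, pair.col0)
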