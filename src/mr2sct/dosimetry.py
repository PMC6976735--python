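"""Dosimetric QA: HU -> relative-electron-density conversion, equivalent path
length (EPL) ray tracing with a 180-beam sweep, 2D gamma analysis, DVH
metrics and the paired statistical comparison.

Gantry angles follow IEC 61217: 0 deg is a beam from anterior, increasing
clockwise viewed from the couch foot; image rows (y) increase posteriorly.
Rays are traced in the axial plane of the isocenter slice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import NoEntryError
from .volume import BodyMask, DoseGrid, ImageVolume

# ---------------------------------------------------------------------------
# HU -> relative electron density
# ---------------------------------------------------------------------------

DEFAULT_CALIBRATION_ANCHORS = ((-1000.0, 0.0), (0.0, 1.0), (1000.0, 1.52), (3000.0, 2.5))


@dataclass
class DensityCalibration:
    """Piecewise-linear HU -> relative electron density (RED) curve.

    Anchors must be strictly increasing in HU with nonnegative, nondecreasing
    RED, and include (-1000, 0.0) and (0, 1.0) so air and water are pinned.
    """

    hu: np.ndarray = field(default_factory=lambda: np.array([a[0] for a in DEFAULT_CALIBRATION_ANCHORS]))
    red: np.ndarray = field(default_factory=lambda: np.array([a[1] for a in DEFAULT_CALIBRATION_ANCHORS]))

    def __post_init__(self):
        self.hu = np.asarray(self.hu, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if self.hu.shape != self.red.shape or self.hu.ndim != 1 or self.hu.size < 2:
            raise ValueError("calibration needs matching 1D HU/RED arrays, >= 2 anchors")
        if not np.all(np.diff(self.hu) > 0):
            raise ValueError("calibration HU values must be strictly increasing")
        if np.any(self.red < 0) or np.any(np.diff(self.red) < 0):
            raise ValueError("RED must be nonnegative and nondecreasing")
        for ahu, ared in ((-1000.0, 0.0), (0.0, 1.0)):
            i = np.searchsorted(self.hu, ahu)
            if i >= self.hu.size or self.hu[i] != ahu or self.red[i] != ared:
                raise ValueError(f"calibration must contain the anchor ({ahu}, {ared})")

    @classmethod
    def from_csv(cls, path) -> "DensityCalibration":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"hu": self.hu, "red": self.red}).to_csv(path, index=False)


def hu_to_red(hu, cal: DensityCalibration | None = None) -> np.ndarray:
    """Interpolate RED from HU; clipped to 0 below the first anchor and to the
    last RED above the last anchor."""
    cal = cal or DensityCalibration()
    return np.interp(np.asarray(hu, dtype=float), cal.hu, cal.red, left=0.0, right=float(cal.red[-1]))


# ---------------------------------------------------------------------------
# beam geometry and angle enumeration
# ---------------------------------------------------------------------------

@dataclass
class BeamGeometry:
    """A beam central axis through the isocenter at a given gantry angle."""

    isocenter_mm: tuple
    gantry_deg: float = 0.0

    def __post_init__(self):
        self.isocenter_mm = tuple(float(v) for v in self.isocenter_mm)
        self.gantry_deg = float(self.gantry_deg) % 360.0

    def source_direction(self) -> np.ndarray:
        """Unit vector (z, y, x) from the isocenter toward the source."""
        th = math.radians(self.gantry_deg)
        return np.array([0.0, -math.cos(th), math.sin(th)])


def enumerate_beam_angles(start_deg: float, end_deg: float, step_deg: float) -> list[float]:
    """Angles start, start+step, ... modulo 360 up to end_deg inclusive."""
    if step_deg <= 0:
        raise ValueError("step must be positive")
    arc = (end_deg - start_deg) % 360.0
    n_steps = arc / step_deg
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"step {step_deg} does not divide the arc {arc}")
    return [(start_deg + i * step_deg) % 360.0 for i in range(int(round(n_steps)) + 1)]


# ---------------------------------------------------------------------------
# equivalent path length (Siddon-type exact voxel traversal)
# ---------------------------------------------------------------------------

def _ray_segments(shape, spacing, iso_mm, direction):
    """Exact voxel-boundary segments of the ray iso + t*direction, t >= 0.

    Returns (t0, t1, voxel_index) triples out to the grid boundary. Voxel i
    covers [(i-0.5)*sp, (i+0.5)*sp] along each axis (centers at i*sp).
    """
    iso = np.asarray(iso_mm, dtype=float)
    u = np.asarray(direction, dtype=float)
    sp = np.asarray(spacing, dtype=float)
    n = np.asarray(shape)
    t_exit = np.inf
    ts = []
    for a in range(3):
        if abs(u[a]) < 1e-12:
            continue
        lo = -0.5 * sp[a]
        hi = (n[a] - 0.5) * sp[a]
        t_hi = ((hi if u[a] > 0 else lo) - iso[a]) / u[a]
        t_exit = min(t_exit, t_hi)
        # all interior boundary crossings
        bounds = (np.arange(n[a] + 1) - 0.5) * sp[a]
        t_all = (bounds - iso[a]) / u[a]
        ts.append(t_all[(t_all > 1e-12) & (t_all <= t_hi + 1e-12)])
    if not np.isfinite(t_exit) or t_exit <= 0:
        raise NoEntryError("ray does not traverse the grid")
    ts = np.unique(np.concatenate([np.concatenate(ts), [t_exit]]))
    ts = ts[(ts > 1e-12) & (ts <= t_exit + 1e-12)]
    edges = np.concatenate([[0.0], ts])
    t0, t1 = edges[:-1], edges[1:]
    mids = iso[None, :] + 0.5 * (t0 + t1)[:, None] * u[None, :]
    idx = np.floor(mids / sp[None, :] + 0.5).astype(int)
    idx = np.clip(idx, 0, (n - 1)[None, :])
    keep = t1 - t0 > 1e-12
    return t0[keep], t1[keep], idx[keep]


def compute_epl(
    ct: ImageVolume,
    mask: BodyMask,
    beam: BeamGeometry,
    cal: DensityCalibration | None = None,
    return_entry: bool = False,
):
    """Physical depth and equivalent path length from the body surface to the
    isocenter along the beam central axis.

    The ray is cast from the isocenter toward the source; the entry point is
    the outer face of the outermost body-mask voxel it crosses. The EPL is
    the exact voxel-boundary line integral of RED(CT) from that entry point
    to the isocenter.
    """
    ct.check_geometry(mask)
    cal = cal or DensityCalibration()
    sp = np.asarray(ct.spacing)
    iso = np.asarray(beam.isocenter_mm, dtype=float)
    iso_idx = tuple(np.floor(iso / sp + 0.5).astype(int))
    if not all(0 <= i < n for i, n in zip(iso_idx, ct.shape)):
        raise ValueError("isocenter outside the image grid")
    if not mask.data[iso_idx]:
        raise ValueError("isocenter must lie inside the body mask")
    t0, t1, idx = _ray_segments(ct.shape, ct.spacing, iso, beam.source_direction())
    vox = tuple(idx.T)
    masked = mask.data[vox]
    if not masked.any():
        raise NoEntryError("ray does not intersect the body mask")
    last = np.max(np.nonzero(masked))
    t_entry = float(t1[last])
    red = hu_to_red(np.asarray(ct.data, dtype=float)[vox], cal)
    seg_len = np.minimum(t1, t_entry) - np.minimum(t0, t_entry)
    epl = float(np.sum(red * seg_len))
    if return_entry:
        return t_entry, epl, iso + t_entry * beam.source_direction()
    return t_entry, epl


@dataclass
class EPLSweepResult:
    table: pd.DataFrame  # angle_deg, depth_mm, epl_a, epl_b, diff_mm
    mean_diff: float
    sd_diff: float
    min_diff: float
    max_diff: float
    frac_within_5mm: float


def epl_sweep(
    ct_a: ImageVolume,
    ct_b: ImageVolume,
    mask: BodyMask,
    isocenter_mm,
    angles: list[float],
    cal: DensityCalibration | None = None,
) -> EPLSweepResult:
    """Per-angle EPL difference (b - a) over a beam-angle sweep, with the
    mean +/- SD, range, and the fraction of beams within +/-5 mm."""
    ct_a.check_geometry(ct_b)
    rows = []
    for ang in angles:
        beam = BeamGeometry(isocenter_mm, ang)
        depth, epl_a = compute_epl(ct_a, mask, beam, cal)
        _, epl_b = compute_epl(ct_b, mask, beam, cal)
        rows.append(
            {
                "angle_deg": ang,
                "depth_mm": depth,
                "epl_a": epl_a,
                "epl_b": epl_b,
                "diff_mm": epl_b - epl_a,
            }
        )
    df = pd.DataFrame(rows)
    d = df["diff_mm"].to_numpy()
    return EPLSweepResult(
        table=df,
        mean_diff=float(d.mean()),
        sd_diff=float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        min_diff=float(d.min()),
        max_diff=float(d.max()),
        frac_within_5mm=float(np.mean(np.abs(d) <= 5.0)),
    )


# ---------------------------------------------------------------------------
# 2D gamma analysis
# ---------------------------------------------------------------------------

@dataclass
class GammaCriteria:
    dose_percent: float  # dose-difference criterion, % of the normalization dose
    dta_mm: float  # distance-to-agreement criterion

    def __str__(self):
        return f"{self.dose_percent:g}%/{self.dta_mm:g}mm"


STANDARD_CRITERIA = (GammaCriteria(3, 3), GammaCriteria(2, 2), GammaCriteria(1, 1))

_PASS_TOL = 1e-6  # boundary passes (gamma exactly 1) count as passing


@dataclass
class GammaResult:
    gamma_map: np.ndarray
    pass_rate: float  # % of evaluated points with gamma <= 1
    criteria: GammaCriteria
    n_evaluated: int


def gamma_2d(
    ref: np.ndarray,
    eval_: np.ndarray,
    spacing_mm: tuple,
    criteria: GammaCriteria,
    norm_dose: float,
    mask: np.ndarray | None = None,
    low_dose_cutoff_frac: float = 0.0,
    upsample: int = 3,
    search_factor: float = 3.0,
) -> GammaResult:
    """Global 2D gamma: for each reference point, the minimum over a search
    disc (radius ``search_factor`` x DTA) of

        sqrt( (dose difference / (dd% x D_norm))^2 + (distance / DTA)^2 ),

    with the evaluated distribution bilinearly upsampled ``upsample``-fold.
    Points below ``low_dose_cutoff_frac`` x D_norm in the reference (or
    outside ``mask``) are excluded from the pass rate.
    """
    ref = np.asarray(ref, dtype=float)
    ev = np.asarray(eval_, dtype=float)
    if ref.shape != ev.shape or ref.ndim != 2:
        raise ValueError("ref and eval must be 2D arrays of identical shape")
    if norm_dose <= 0:
        raise ValueError("normalization dose must be positive")
    u = max(1, int(upsample))
    sy, sx = (float(s) for s in spacing_mm)
    h, w = ref.shape
    hf, wf = (h - 1) * u + 1, (w - 1) * u + 1
    yy, xx = np.meshgrid(np.arange(hf) / u, np.arange(wf) / u, indexing="ij")
    evf = ndimage.map_coordinates(ev, [yy, xx], order=1, mode="nearest")

    dd = criteria.dose_percent / 100.0 * norm_dose
    radius = search_factor * criteria.dta_mm
    ry = int(math.floor(radius / (sy / u)))
    rx = int(math.floor(radius / (sx / u)))
    gamma2 = np.full((h, w), np.inf)
    for dy in range(-ry, ry + 1):
        dmy = dy * sy / u
        for dx in range(-rx, rx + 1):
            dist2 = dmy**2 + (dx * sx / u) ** 2
            if dist2 > radius**2 + 1e-12:
                continue
            i0 = max(0, math.ceil(-dy / u))
            i1 = min(h - 1, math.floor((hf - 1 - dy) / u))
            j0 = max(0, math.ceil(-dx / u))
            j1 = min(w - 1, math.floor((wf - 1 - dx) / u))
            if i0 > i1 or j0 > j1:
                continue
            shifted = evf[i0 * u + dy : i1 * u + dy + 1 : u, j0 * u + dx : j1 * u + dx + 1 : u]
            cand = ((shifted - ref[i0 : i1 + 1, j0 : j1 + 1]) / dd) ** 2 + dist2 / criteria.dta_mm**2
            np.minimum(gamma2[i0 : i1 + 1, j0 : j1 + 1], cand, out=gamma2[i0 : i1 + 1, j0 : j1 + 1])
    gamma = np.sqrt(gamma2)

    evaluated = np.ones_like(ref, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if low_dose_cutoff_frac > 0:
        evaluated &= ref >= low_dose_cutoff_frac * norm_dose
    n_eval = int(evaluated.sum())
    passed = gamma[evaluated] <= 1.0 + _PASS_TOL
    pass_rate = 100.0 * float(passed.mean()) if n_eval else float("nan")
    gamma_out = np.where(evaluated, gamma, np.nan)
    return GammaResult(gamma_out, pass_rate, criteria, n_eval)


def gamma_suite(
    ref, eval_, spacing_mm, norm_dose, criteria_list=STANDARD_CRITERIA, **kwargs
) -> dict:
    """Gamma results for several criteria on the same dose pair."""
    return {str(c): gamma_2d(ref, eval_, spacing_mm, c, norm_dose, **kwargs) for c in criteria_list}


# ---------------------------------------------------------------------------
# DVH metrics
# ---------------------------------------------------------------------------

@dataclass
class DVHMetrics:
    d2: float  # Gy, dose exceeded by 2% of the structure volume
    d50: float
    d98: float
    v95: float  # % of structure receiving >= 95% of the prescription
    dmax: float
    dmean: float

    def to_dict(self) -> dict:
        return {
            "D2%": self.d2,
            "D50%": self.d50,
            "D98%": self.d98,
            "V95%": self.v95,
            "Dmax": self.dmax,
            "Dmean": self.dmean,
        }


def dvh_metrics(dose: DoseGrid, structure: BodyMask, prescription: float | None = None) -> DVHMetrics:
    """D2%/D50%/D98% (linear interpolation on sorted voxel doses), V95%,
    maximum and mean dose over a structure."""
    dose.check_geometry(structure)
    if not structure.data.any():
        raise ValueError("empty structure")
    rx = dose.prescription if prescription is None else prescription
    vals = dose.data[structure.data]
    d2, d50, d98 = np.percentile(vals, [98.0, 50.0, 2.0])
    return DVHMetrics(
        d2=float(d2),
        d50=float(d50),
        d98=float(d98),
        v95=100.0 * float(np.mean(vals >= 0.95 * rx)),
        dmax=float(vals.max()),
        dmean=float(vals.mean()),
    )


# ---------------------------------------------------------------------------
# paired statistics
# ---------------------------------------------------------------------------

@dataclass
class PairedComparison:
    differences: np.ndarray  # b - a
    test: str  # 'paired-t' | 'wilcoxon' | 'degenerate'
    statistic: float
    p_value: float
    shapiro_p: float | None
    degenerate: bool = False


def wilcoxon_signed_rank(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Exact null distribution for n <= 25 nonzero differences, normal
    approximation with continuity correction above. Zero differences are
    discarded (standard signed-rank convention).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    method = "exact" if d.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    except ValueError:
        res = stats.wilcoxon(d, alternative="two-sided", method="approx", correction=True)
    return float(res.statistic), float(res.pvalue)


def paired_compare(a, b, alpha: float = 0.05) -> PairedComparison:
    """Compare paired measurements: Shapiro–Wilk normality check on the
    differences selects the paired t-test (normal) or the Wilcoxon
    signed-rank test (non-normal). All-zero differences are degenerate and
    report p = 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length 1D samples with n >= 3")
    d = b - a
    if np.all(d == 0):
        return PairedComparison(d, "degenerate", 0.0, 1.0, None, degenerate=True)
    if np.ptp(d) == 0:
        shapiro_p = 0.0  # constant nonzero differences: trivially non-normal
    else:
        shapiro_p = float(stats.shapiro(d).pvalue)
    if shapiro_p >= alpha:
        res = stats.ttest_rel(b, a)
        return PairedComparison(d, "paired-t", float(res.statistic), float(res.pvalue), shapiro_p)
    statistic, p = wilcoxon_signed_rank(d)
    return PairedComparison(d, "wilcoxon", statistic, p, shapiro_p)


# ---------------------------------------------------------------------------
# toy 2D dose engine (QA demonstrations on phantoms)
# ---------------------------------------------------------------------------

def simple_dose_2d(
    ct_slice: np.ndarray,
    spacing_mm: tuple,
    gantry_angles_deg: list[float],
    prescription: float,
    cal: DensityCalibration | None = None,
    mu_per_mm: float = 0.005,
    sigma_mm: float = 25.0,
) -> np.ndarray:
    """Water-equivalent-depth pencil-beam toy model on one axial slice.

    For each beam the RED map is rotated so the beam travels down the rows,
    attenuated exponentially in cumulative water-equivalent depth, weighted by
    a Gaussian lateral profile about the central axis, and rotated back. The
    sum is normalized to the prescription at the slice center (the isocenter).
    Intended for QA demonstrations — differences between a real and a
    synthetic CT propagate into dose through the density map — not for
    clinical dose calculation.
    """
    cal = cal or DensityCalibration()
    red = hu_to_red(np.asarray(ct_slice, dtype=float), cal)
    sy, sx = (float(s) for s in spacing_mm)
    h, w = red.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    total = np.zeros_like(red)
    lateral = np.exp(-(((np.arange(w) - cx) * sx) ** 2) / (2 * sigma_mm**2))
    for ang in gantry_angles_deg:
        red_rot = ndimage.rotate(red, -ang, reshape=False, order=1, mode="constant", cval=0.0)
        wed = np.cumsum(red_rot, axis=0) * sy
        contrib = np.exp(-mu_per_mm * wed) * lateral[None, :]
        total += ndimage.rotate(contrib, ang, reshape=False, order=1, mode="constant", cval=0.0)
    iso_val = total[int(round(cy)), int(round(cx))]
    if iso_val <= 0:
        iso_val = total.max()
    return prescription * total / iso_val
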