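"""Seeded digital head phantoms: tissue label maps, CT in HU, multi-sequence MR,
and analytic dose grids.

The phantom emulates an axial head acquisition: nested ellipsoids for scalp,
skull and brain, an ellipsoidal CSF ventricle, an off-center spherical lesion
and an optional metal clip. Every stage downstream (preprocessing, cGAN
training, sCT assembly, image QA and dosimetric QA) is exercisable on these
volumes without any external data.

Tissue labels:
    0 background air, 1 scalp/soft tissue, 2 skull bone, 3 brain parenchyma,
    4 CSF/ventricle, 5 lesion, 6 metal clip.

Because each tissue has a distinct mean intensity in each MR sequence, the CT
number is (with noise and texture off) a deterministic function of the MR
triple — the property that makes small-scale generator training meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MissingContrastError
from .volume import DoseGrid, ImageVolume, MultiSequenceVolume

LABELS = {
    "background": 0,
    "scalp": 1,
    "bone": 2,
    "brain": 3,
    "csf": 4,
    "lesion": 5,
    "metal": 6,
}


@dataclass
class TissueLabelVolume:
    """Integer tissue label grid with voxel spacing."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D grid")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.labels.shape

    def body_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class ContrastModel:
    """Per-tissue image formation model.

    ``hu_means`` maps label -> CT number; ``mr_means`` maps sequence name
    ('t1', 't2', 'flair') -> {label: mean intensity}. ``noise_sigma`` is the
    Rician noise scale per sequence (image units); ``bias_amplitude`` scales a
    smooth multiplicative field exp(a * P(x)) with P a low-order polynomial in
    normalized coordinates; ``bias_order`` is its total degree.
    ``texture_sigma`` adds Gaussian HU texture inside the body on the CT.
    """

    hu_means: dict = field(default_factory=lambda: dict(DEFAULT_HU))
    mr_means: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MR.items()})
    noise_sigma: dict = field(default_factory=lambda: {"t1": 15.0, "t2": 15.0, "flair": 15.0})
    bias_amplitude: float = 0.15
    bias_order: int = 2
    texture_sigma: float = 0.0

    def __post_init__(self):
        for lab, hu in self.hu_means.items():
            if not -1000.0 <= hu <= 3100.0:
                raise ValueError(f"HU mean for label {lab} outside [-1000, 3100]: {hu}")
        for seq, table in self.mr_means.items():
            for lab, mean in table.items():
                if lab != 0 and mean <= 0:
                    raise ValueError(f"MR mean for body label {lab}/{seq} must be > 0")
        for seq, s in self.noise_sigma.items():
            if s < 0:
                raise ValueError(f"noise sigma for {seq} must be >= 0")


# Plausible defaults; configurable, not taken from any patient cohort.
DEFAULT_HU = {0: -1000.0, 1: 40.0, 2: 900.0, 3: 30.0, 4: 10.0, 5: 35.0, 6: 3000.0}

DEFAULT_MR = {
    # T1w: fat-bright scalp, gray/white matter mid, CSF dark.
    "t1": {0: 0.0, 1: 700.0, 2: 250.0, 3: 600.0, 4: 200.0, 5: 450.0, 6: 100.0},
    # T2w: CSF bright.
    "t2": {0: 0.0, 1: 500.0, 2: 200.0, 3: 450.0, 4: 900.0, 5: 700.0, 6: 80.0},
    # FLAIR: CSF suppressed, lesion bright.
    "flair": {0: 0.0, 1: 550.0, 2: 150.0, 3: 500.0, 4: 120.0, 5: 800.0, 6: 60.0},
}


@dataclass
class AnatomyParams:
    """Fractional ellipsoid geometry of the head phantom.

    Semiaxis fractions are relative to the half-extent of the grid per axis
    (z, y, x). ``jitter`` perturbs sizes/positions by up to that relative
    amount, seeded, so subjects differ.
    """

    head_frac: tuple = (0.92, 0.88, 0.84)
    skull_outer_frac: tuple = (0.82, 0.78, 0.74)
    skull_inner_frac: tuple = (0.72, 0.68, 0.64)
    ventricle_frac: tuple = (0.22, 0.16, 0.20)
    lesion_radius_frac: float = 0.12
    lesion_offset_frac: tuple = (0.10, 0.18, 0.15)
    include_metal: bool = False
    metal_radius_frac: float = 0.035
    metal_offset_frac: tuple = (0.0, -0.55, 0.30)
    jitter: float = 0.05


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    r2 = (
        ((zz - center[0]) / semiaxes[0]) ** 2
        + ((yy - center[1]) / semiaxes[1]) ** 2
        + ((xx - center[2]) / semiaxes[2]) ** 2
    )
    return r2 <= 1.0


def generate_head_phantom(
    shape=(24, 96, 96),
    spacing=(2.5, 1.0, 1.0),
    anatomy: AnatomyParams | None = None,
    contrast: ContrastModel | None = None,
    seed: int = 0,
) -> tuple[TissueLabelVolume, ImageVolume]:
    """Build a labeled head phantom and its HU volume.

    Deterministic for a fixed seed. The HU volume assigns each label its
    ContrastModel mean, plus optional Gaussian texture inside the body when
    ``contrast.texture_sigma > 0``.
    """
    shape = tuple(int(n) for n in shape)
    if any(n < 32 for n in shape[1:]) or shape[0] < 1:
        raise ValueError(f"in-plane shape must be >= 32 voxels, got {shape}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive, got {spacing}")
    anatomy = anatomy or AnatomyParams()
    contrast = contrast or ContrastModel()
    rng = np.random.default_rng(seed)

    half = np.array(shape, dtype=float) / 2.0
    center = half - 0.5

    def jit(frac_tuple):
        frac = np.asarray(frac_tuple, dtype=float)
        return frac * (1.0 + anatomy.jitter * rng.uniform(-1, 1, size=frac.shape))

    labels = np.zeros(shape, dtype=np.int16)
    head = _ellipsoid(shape, center, jit(anatomy.head_frac) * half)
    sk_out = _ellipsoid(shape, center, jit(anatomy.skull_outer_frac) * half)
    sk_in = _ellipsoid(shape, center, jit(anatomy.skull_inner_frac) * half)
    labels[head] = LABELS["scalp"]
    labels[sk_out] = LABELS["bone"]
    labels[sk_in] = LABELS["brain"]

    vent = _ellipsoid(shape, center, jit(anatomy.ventricle_frac) * half)
    labels[vent & sk_in] = LABELS["csf"]

    les_off = jit(anatomy.lesion_offset_frac) * half
    les_r = anatomy.lesion_radius_frac * float(min(half[1:])) * (
        1.0 + anatomy.jitter * rng.uniform(-1, 1)
    )
    lesion = _ellipsoid(shape, center + les_off, (les_r * spacing[1] / spacing[0], les_r, les_r))
    labels[lesion & (labels == LABELS["brain"])] = LABELS["lesion"]

    if anatomy.include_metal:
        met_off = np.asarray(anatomy.metal_offset_frac) * half
        met_r = max(1.5, anatomy.metal_radius_frac * float(min(shape[1:])))
        metal = _ellipsoid(
            shape, center + met_off, (met_r * spacing[1] / spacing[0], met_r, met_r)
        )
        labels[metal & (labels > 0)] = LABELS["metal"]

    missing = set(np.unique(labels)) - set(contrast.hu_means)
    if missing:
        raise MissingContrastError(f"labels without HU entry: {sorted(missing)}")
    lut = np.full(int(labels.max()) + 1, -1000.0)
    for lab, hu in contrast.hu_means.items():
        if lab <= labels.max():
            lut[lab] = hu
    hu = lut[labels]
    if contrast.texture_sigma > 0:
        tex = rng.normal(0.0, contrast.texture_sigma, size=shape)
        hu = hu + tex * (labels > 0)

    label_vol = TissueLabelVolume(labels, spacing)
    return label_vol, ImageVolume(hu.astype(np.float64), spacing)


def sample_bias_field(
    shape, amplitude: float, order: int, rng: np.random.Generator
) -> np.ndarray:
    """Smooth strictly positive multiplicative field exp(a * P(x)).

    P is a random polynomial of total degree <= ``order`` in coordinates
    normalized to [-1, 1], rescaled to unit max magnitude so that ``amplitude``
    directly bounds log-field excursion.
    """
    coords = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1) for n in shape]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    poly = np.zeros(shape)
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                if i == j == k == 0:
                    continue
                poly += rng.normal() * (zz**i) * (yy**j) * (xx**k)
    peak = np.abs(poly).max()
    if peak > 0:
        poly /= peak
    return np.exp(amplitude * poly)


def simulate_mr(
    label_vol: TissueLabelVolume,
    model: ContrastModel | None = None,
    seed: int = 0,
    return_fields: bool = False,
):
    """Simulate the three MR sequences from a tissue label map.

    Per sequence: image = bias_field x tissue mean, degraded by Rician noise
    (magnitude of a complex Gaussian — the physics of MR magnitude images).
    Background keeps the noise floor. Deterministic for a fixed seed.
    """
    model = model or ContrastModel()
    labels = label_vol.labels
    present = np.unique(labels)
    rng = np.random.default_rng(seed)
    channels, fields = [], {}
    for seq in MultiSequenceVolume.CHANNELS:
        table = model.mr_means.get(seq)
        if table is None:
            raise MissingContrastError(f"no contrast table for sequence {seq}")
        missing = [int(lab) for lab in present if lab not in table]
        if missing:
            raise MissingContrastError(f"labels without {seq} contrast entry: {missing}")
        lut = np.zeros(int(labels.max()) + 1)
        for lab, mean in table.items():
            if lab <= labels.max():
                lut[lab] = mean
        signal = lut[labels]
        bias = sample_bias_field(labels.shape, model.bias_amplitude, model.bias_order, rng)
        img = signal * bias
        sigma = model.noise_sigma.get(seq, 0.0)
        if sigma > 0:
            n1 = rng.normal(0.0, sigma, size=labels.shape)
            n2 = rng.normal(0.0, sigma, size=labels.shape)
            img = np.sqrt((img + n1) ** 2 + n2**2)
        channels.append(img)
        fields[seq] = bias
    mr = MultiSequenceVolume(np.stack(channels), label_vol.spacing, label_vol.origin)
    if return_fields:
        return mr, fields
    return mr


@dataclass
class BeamSpec:
    """One beam of the analytic dose model.

    ``gantry_deg`` follows IEC 61217 (0° from anterior, clockwise seen from
    the couch foot); ``sigma_mm`` is the Gaussian lateral profile width
    (None or inf = flat beam); ``mu_per_mm`` the exponential depth-attenuation
    coefficient; ``weight`` the relative beam weight.
    """

    gantry_deg: float = 0.0
    sigma_mm: float | None = 30.0
    mu_per_mm: float = 0.005
    weight: float = 1.0


def beam_direction(gantry_deg: float) -> np.ndarray:
    """Unit vector (z, y, x) from the radiation source toward the isocenter.

    Rows (y) increase toward posterior, so gantry 0° (anterior source) travels
    in +y; gantry 90° enters from the patient-left (+x) side.
    """
    th = np.deg2rad(gantry_deg % 360.0)
    return np.array([0.0, np.cos(th), -np.sin(th)])


def analytic_dose_grid(
    geometry: ImageVolume | TissueLabelVolume,
    beams: list[BeamSpec],
    prescription: float,
    isocenter_mm=None,
) -> DoseGrid:
    """Superpose Gaussian-profile beams with exponential depth attenuation.

    The field is normalized so the isocenter receives the prescription dose
    (falls back to max-normalization if the isocenter dose is zero); doubling
    the prescription therefore doubles every voxel.
    """
    if not beams:
        raise ValueError("beam_spec must contain at least one beam")
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    shape = geometry.shape
    spacing = np.asarray(geometry.spacing, dtype=float)
    if isocenter_mm is None:
        isocenter_mm = (np.array(shape, dtype=float) - 1.0) / 2.0 * spacing
    isocenter_mm = np.asarray(isocenter_mm, dtype=float)

    zz, yy, xx = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    pts = np.stack([zz, yy, xx])  # mm coordinates, (3, z, y, x)
    total = np.zeros(shape)
    for beam in beams:
        u = beam_direction(beam.gantry_deg)
        rel = pts - isocenter_mm.reshape(3, 1, 1, 1)
        along = np.tensordot(u, rel, axes=1)  # signed distance along beam from iso
        # depth measured from the grid entry plane on the source side
        depth = along - along.min()
        lat2 = ((rel - along[None] * u.reshape(3, 1, 1, 1)) ** 2).sum(axis=0)
        profile = (
            np.ones(shape)
            if beam.sigma_mm is None or not np.isfinite(beam.sigma_mm)
            else np.exp(-lat2 / (2.0 * beam.sigma_mm**2))
        )
        total += beam.weight * profile * np.exp(-beam.mu_per_mm * depth)

    iso_idx = tuple(np.clip(np.round(isocenter_mm / spacing).astype(int), 0, np.array(shape) - 1))
    norm = total[iso_idx]
    if norm <= 0:
        norm = total.max()
    dose = prescription * total / norm
    return DoseGrid(dose, tuple(spacing), prescription)
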