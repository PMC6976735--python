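"""Synthetic-CT assembly: median-HU missing-slice compensation.

When the MR volume does not cover the full CT extent, the generator cannot
predict the top/bottom slices. Those slices are filled with the corresponding
real-CT slices, after replacing each CT number with the median of the
predicted HU values observed (over the predicted region) at voxels sharing
that CT number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import BodyMask, ImageVolume

CT_BACKGROUND = -1000.0


@dataclass
class HULookup:
    """Integer rCT HU value -> median predicted sCT HU on the overlap region.

    Defined exactly on the HU values present in the overlap (``coverage``);
    queries in between covered values are resolved by linear interpolation,
    and beyond the covered range by constant extrapolation.
    """

    coverage: np.ndarray  # sorted integer HU values observed
    medians: np.ndarray  # median predicted HU per covered value

    def __post_init__(self):
        self.coverage = np.asarray(self.coverage, dtype=float)
        self.medians = np.asarray(self.medians, dtype=float)
        if self.coverage.size == 0:
            raise ValueError("empty lookup coverage")
        if not np.all(np.diff(self.coverage) > 0):
            raise ValueError("coverage values must be strictly increasing")

    def __call__(self, hu: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(hu, dtype=float), self.coverage, self.medians)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"hu": self.coverage, "median_hu": self.medians})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HULookup":
        return cls(df["hu"].to_numpy(), df["median_hu"].to_numpy())


def build_hu_lookup(
    rct_overlap: ImageVolume, sct_overlap: ImageVolume, mask: BodyMask
) -> HULookup:
    """Learn the rCT -> median(sCT) correspondence on the predicted overlap.

    rCT values are binned to integer HU before grouping.
    """
    rct_overlap.check_geometry(sct_overlap)
    rct_overlap.check_geometry(mask)
    m = mask.data
    if not m.any():
        raise ValueError("empty mask: no overlap voxels")
    r = np.rint(np.asarray(rct_overlap.data, dtype=float)[m]).astype(np.int64)
    s = np.asarray(sct_overlap.data, dtype=float)[m]
    order = np.argsort(r, kind="stable")
    r, s = r[order], s[order]
    values, starts = np.unique(r, return_index=True)
    bounds = np.append(starts, r.size)
    medians = np.array([np.median(s[a:b]) for a, b in zip(bounds[:-1], bounds[1:])])
    return HULookup(values, medians)


def compensate_missing_slices(
    sct_partial: ImageVolume,
    rct_full: ImageVolume,
    predicted_slice_range: tuple[int, int],
    lookup: HULookup,
) -> ImageVolume:
    """Fill non-predicted slices from the real CT with remapped CT numbers.

    ``predicted_slice_range`` is the half-open slice interval [a, b) that the
    generator actually produced; those slices are copied from ``sct_partial``,
    all others come from ``rct_full`` with each voxel passed through the
    lookup. Background voxels (-1000 HU) pass through unchanged.
    """
    sct_partial.check_geometry(rct_full)
    a, b = predicted_slice_range
    nz = rct_full.shape[0]
    if not (0 <= a < b <= nz):
        raise ValueError(f"empty or out-of-range predicted_slice_range {predicted_slice_range}")
    out = np.asarray(rct_full.data, dtype=float).copy()
    missing = np.ones(nz, dtype=bool)
    missing[a:b] = False
    if missing.any():
        mapped = lookup(out[missing])
        bg = np.isclose(out[missing], CT_BACKGROUND)
        mapped[bg] = CT_BACKGROUND
        out[missing] = mapped
    out[a:b] = np.asarray(sct_partial.data, dtype=float)[a:b]
    return rct_full.with_data(out)
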