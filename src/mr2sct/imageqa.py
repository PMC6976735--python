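"""Image-quality evaluation: region-wise MAE and binned HU-difference profiles.

Regions are defined on the real-CT values inside the body mask: the whole
body, soft tissue (-100 HU < rCT < 150 HU, strict on both ends) and bone
(rCT >= 250 HU).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import BodyMask, ImageVolume

SOFT_TISSUE_RANGE = (-100.0, 150.0)  # strict inequalities on both ends
BONE_THRESHOLD = 250.0
BIN_ANCHOR = -1000.0


@dataclass
class RegionMAEReport:
    """MAE (HU) and voxel count for the body, soft-tissue and bone regions.

    An empty region reports count 0 and MAE ``nan``.
    """

    mae_body: float
    mae_soft: float
    mae_bone: float
    n_body: int
    n_soft: int
    n_bone: int

    def to_dict(self) -> dict:
        return {
            "mae_body": self.mae_body,
            "mae_soft": self.mae_soft,
            "mae_bone": self.mae_bone,
            "n_body": self.n_body,
            "n_soft": self.n_soft,
            "n_bone": self.n_bone,
        }


def region_mae(sct: ImageVolume, rct: ImageVolume, mask: BodyMask) -> RegionMAEReport:
    """Mean absolute CT-number error over the body, soft-tissue and bone regions."""
    rct.check_geometry(sct)
    rct.check_geometry(mask)
    m = mask.data
    if not m.any():
        raise ValueError("empty body mask")
    r = np.asarray(rct.data, dtype=float)[m]
    s = np.asarray(sct.data, dtype=float)[m]
    err = np.abs(s - r)
    lo, hi = SOFT_TISSUE_RANGE
    soft = (r > lo) & (r < hi)
    bone = r >= BONE_THRESHOLD

    def _mae(sel):
        n = int(sel.sum())
        return (float(err[sel].mean()) if n else float("nan")), n

    mae_soft, n_soft = _mae(soft)
    mae_bone, n_bone = _mae(bone)
    return RegionMAEReport(
        mae_body=float(err.mean()),
        mae_soft=mae_soft,
        mae_bone=mae_bone,
        n_body=int(m.sum()),
        n_soft=n_soft,
        n_bone=n_bone,
    )


@dataclass
class BinnedDifferenceProfile:
    """Per-bin percentile statistics of the sCT - rCT difference.

    Voxels are grouped by their rCT value into contiguous bins of
    ``bin_width`` HU anchored at -1000. Signed-difference percentiles are the
    primary statistics; absolute-difference percentiles are also provided.
    Empty bins carry count 0 and ``nan`` statistics.
    """

    table: pd.DataFrame  # bin_lo, bin_hi, n, p25, median, p75, abs_p25, abs_median, abs_p75
    bin_width: float

    def __len__(self):
        return len(self.table)


def binned_difference(
    sct: ImageVolume, rct: ImageVolume, mask: BodyMask, bin_width: float = 20.0
) -> BinnedDifferenceProfile:
    """Median/25th/75th percentile of (sCT - rCT) per 20-HU bin of rCT."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    rct.check_geometry(sct)
    rct.check_geometry(mask)
    m = mask.data
    r = np.asarray(rct.data, dtype=float)[m]
    d = np.asarray(sct.data, dtype=float)[m] - r
    first = int(np.floor((r.min() - BIN_ANCHOR) / bin_width))
    last = int(np.floor((r.max() - BIN_ANCHOR) / bin_width))
    edges = BIN_ANCHOR + bin_width * np.arange(first, last + 2)
    idx = np.floor((r - BIN_ANCHOR) / bin_width).astype(int) - first
    rows = []
    for b in range(last - first + 1):
        sel = idx == b
        n = int(sel.sum())
        if n:
            q = np.percentile(d[sel], [25, 50, 75])
            aq = np.percentile(np.abs(d[sel]), [25, 50, 75])
        else:
            q = aq = (np.nan, np.nan, np.nan)
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "n": n,
                "p25": q[0],
                "median": q[1],
                "p75": q[2],
                "abs_p25": aq[0],
                "abs_median": aq[1],
                "abs_p75": aq[2],
            }
        )
    return BinnedDifferenceProfile(pd.DataFrame(rows), bin_width)
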