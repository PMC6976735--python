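"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately avoid the implementation's code paths: direct double loops
and dense sampling instead of im2col tricks, integral images or Siddon
traversal.
"""

import numpy as np

from mr2sct.dosimetry import hu_to_red


def gamma_bruteforce(ref, ev, spacing_mm, dose_percent, dta_mm, norm_dose,
                     upsample=3, search_factor=3.0):
    """Exhaustive-search gamma: for every reference point, scan every point of
    the bilinearly upsampled evaluated grid inside the search disc."""
    from scipy import ndimage

    ref = np.asarray(ref, float)
    ev = np.asarray(ev, float)
    u = upsample
    sy, sx = spacing_mm
    h, w = ref.shape
    hf, wf = (h - 1) * u + 1, (w - 1) * u + 1
    yy, xx = np.meshgrid(np.arange(hf) / u, np.arange(wf) / u, indexing="ij")
    evf = ndimage.map_coordinates(ev, [yy, xx], order=1, mode="nearest")
    fine_y = (np.arange(hf) / u) * sy
    fine_x = (np.arange(wf) / u) * sx
    dd = dose_percent / 100.0 * norm_dose
    radius = search_factor * dta_mm
    gamma = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            dy = fine_y - i * sy
            dx = fine_x - j * sx
            dist2 = dy[:, None] ** 2 + dx[None, :] ** 2
            sel = dist2 <= radius**2 + 1e-12
            g2 = ((evf - ref[i, j]) / dd) ** 2 + dist2 / dta_mm**2
            gamma[i, j] = np.sqrt(g2[sel].min())
    return gamma


def dvh_bruteforce(doses, prescription):
    """Sort-based DVH oracle with linear interpolation between order stats."""
    v = np.sort(np.asarray(doses, float))
    n = v.size

    def pct(q):  # ascending percentile, linear interpolation
        h = (n - 1) * q / 100.0
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    return {
        "D2%": pct(98.0),
        "D50%": pct(50.0),
        "D98%": pct(2.0),
        "V95%": 100.0 * np.mean(v >= 0.95 * prescription),
        "Dmax": v[-1],
        "Dmean": v.mean(),
    }


def epl_dense_oracle(ct, beam, t_entry, cal=None, n_samples=200_000):
    """Midpoint-rule line integral of RED along the ray with nearest-voxel
    lookup; independent of the exact boundary traversal."""
    sp = np.asarray(ct.spacing)
    iso = np.asarray(beam.isocenter_mm, float)
    u = beam.source_direction()
    dt = t_entry / n_samples
    t = (np.arange(n_samples) + 0.5) * dt
    pts = iso[None, :] + t[:, None] * u[None, :]
    idx = np.floor(pts / sp[None, :] + 0.5).astype(int)
    idx = np.clip(idx, 0, np.array(ct.shape) - 1)
    red = hu_to_red(ct.data[idx[:, 0], idx[:, 1], idx[:, 2]], cal)
    return float(red.sum() * dt)


def wilcoxon_enumeration(diffs):
    """Exact two-sided signed-rank p-value by enumerating all sign vectors."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    ws = []
    for bits in range(2**n):
        signs = [(bits >> k) & 1 for k in range(n)]
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_hi = np.mean(ws >= w_obs)
    p_lo = np.mean(ws <= w_obs)
    return min(1.0, 2.0 * min(p_hi, p_lo))
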