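"""Fiber-angle measurement, axial circular statistics and field comparison.

A measured (diffusion-tensor-like) fiber field is embedded in the local
axis system by Gram-Schmidt projection onto the wall-tangent plane,

    s_D = e_t,
    f_D = (f_m - (f_m.e_t) e_t)/|...|,
    n_D = e_t x f_D,

and its axial angle alpha in (-pi/2, pi/2] is measured against the
longitudinal axis.  Per bundle and per layer the dominant angle is the
modal histogram bin; dispersion uses the angle-doubling convention for
axial data.  Two unit fiber fields are compared point-wise with

    diff(x) = 1 - |f_A(x) . f_B(x)|,

zero for parallel and one for orthogonal fibers; the absolute value
accounts for the directional invariance of fibers (a config flag restores
the sign-sensitive literal formula).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class MeasureError(ValueError):
    pass


_EPS = 1e-12


def embed_measured(f_m, e_l, e_n, e_t):
    """Project a raw measured fiber field into the tangent plane of Q.

    Returns (f_D, n_D, s_D, mask) where mask flags degenerate nodes whose
    measured vector is (numerically) parallel to the transmural axis; those
    nodes are excluded from angle statistics.
    """
    f_m = np.atleast_2d(np.asarray(f_m, dtype=float))
    proj = f_m - np.einsum("ij,ij->i", f_m, e_t)[:, None] * e_t
    norm = np.linalg.norm(proj, axis=1)
    scale = np.maximum(np.linalg.norm(f_m, axis=1), 1.0)
    mask = norm < 1e-8 * scale
    f_D = proj / np.where(mask, 1.0, norm)[:, None]
    f_D[mask] = np.nan
    n_D = np.cross(e_t, f_D)
    s_D = e_t
    return f_D, n_D, s_D, mask


def fiber_angle(f_D, e_l, e_n):
    """Signed axial angle of an in-plane fiber w.r.t. the longitudinal axis.

    atan2 of the (e_n, e_l) components folded into (-pi/2, pi/2]; the
    unsigned arccos form cannot produce negative angles, so the signed
    two-argument form with axial folding is used.
    """
    x = np.einsum("ij,ij->i", np.atleast_2d(f_D), np.atleast_2d(e_l))
    y = np.einsum("ij,ij->i", np.atleast_2d(f_D), np.atleast_2d(e_n))
    a = np.arctan2(y, x)
    a = np.where(a > np.pi / 2, a - np.pi, a)
    a = np.where(a <= -np.pi / 2, a + np.pi, a)
    return a if a.size > 1 else float(a[0])


@dataclass
class AngleStats:
    """Statistics of one (bundle, layer) angle sample."""

    n: int
    dominant_deg: float | None
    mean_deg: float | None
    sd_deg: float
    resultant: float
    hist_counts: np.ndarray
    hist_centers_deg: np.ndarray
    flagged: bool = False


def dominant_angle(samples_rad, bin_width_deg: float = 10.0, n_min: int = 50):
    """Modal histogram bin center over (-90, 90] with axial wrap.

    Ties are broken toward the bin nearest 0 degrees, negative first.
    Returns (dominant_deg or None, counts, centers_deg); None when fewer
    than ``n_min`` samples.
    """
    a = np.degrees(np.asarray(samples_rad, dtype=float))
    a = a[np.isfinite(a)]
    # fold exactly -90 onto +90 (axial wrap of the half-open range)
    a = np.where(a <= -90.0, a + 180.0, a)
    nbins = int(round(180.0 / bin_width_deg))
    bw = 180.0 / nbins
    # bins centered at multiples of the bin width: center c covers
    # (c - bw/2, c + bw/2]; the +90 bin wraps axially onto (-90, -90 + bw/2]
    k = np.ceil(a / bw - 0.5).astype(int)
    half = nbins // 2
    k = np.where(k <= -half, k + nbins, k)  # axial wrap
    centers = bw * np.arange(-half + 1, half + 1)
    counts = np.bincount(k + half - 1, minlength=nbins)
    if a.size < n_min:
        return None, counts, centers
    best = counts.max()
    tied = np.nonzero(counts == best)[0]
    order = sorted(tied, key=lambda i: (abs(centers[i]), centers[i]))
    return float(centers[order[0]]), counts, centers


def axial_stats(samples_rad, eps_uniform: float = 0.05):
    """Axial mean, angular SD and resultant length by angle doubling.

    theta = 2 alpha; Rbar = |mean(exp(i theta))|; mean = arg/2 folded into
    (-pi/2, pi/2]; SD = sqrt(2 (1 - Rbar))/2 (halved back to the axial
    scale).  A near-uniform sample (Rbar < eps_uniform) has no meaningful
    mean direction and is flagged (mean None).
    """
    a = np.asarray(samples_rad, dtype=float)
    a = a[np.isfinite(a)]
    if a.size < 2:
        raise MeasureError("need at least 2 samples")
    th = 2.0 * a
    C, S = np.cos(th).mean(), np.sin(th).mean()
    rbar = float(np.hypot(C, S))
    sd = float(np.sqrt(2.0 * max(1.0 - rbar, 0.0)) / 2.0)
    if rbar < eps_uniform:
        return None, sd, rbar
    mean = 0.5 * np.arctan2(S, C)
    if mean > np.pi / 2:
        mean -= np.pi
    elif mean <= -np.pi / 2:
        mean += np.pi
    return float(mean), sd, rbar


def angle_statistics(
    angles_rad,
    labels,
    layers,
    mask=None,
    bin_width_deg: float = 10.0,
    n_min: int = 50,
):
    """Per-(bundle, layer) dominant angles and axial circular statistics.

    Returns dict {(label, layer): AngleStats}; groups below ``n_min`` valid
    samples are flagged and carry no dominant angle.
    """
    angles_rad = np.asarray(angles_rad)
    ok = np.isfinite(angles_rad)
    if mask is not None:
        ok &= ~np.asarray(mask)
    out = {}
    for lbl in np.unique(np.asarray(labels)):
        for lay in (0, 1):
            sel = ok & (labels == lbl) & (layers == lay)
            n = int(sel.sum())
            if n == 0:
                continue
            sample = angles_rad[sel]
            dom, counts, centers = dominant_angle(sample, bin_width_deg, n_min)
            if n >= 2:
                mean, sd, rbar = axial_stats(sample)
            else:
                mean, sd, rbar = None, 0.0, 1.0
            out[(int(lbl), int(lay))] = AngleStats(
                n=n,
                dominant_deg=dom,
                mean_deg=None if mean is None else float(np.degrees(mean)),
                sd_deg=float(np.degrees(sd)),
                resultant=rbar,
                hist_counts=counts,
                hist_centers_deg=centers,
                flagged=dom is None or mean is None,
            )
    return out


def measure_fiber_field(f_m, frames, labels, bin_width_deg=10.0, n_min=50):
    """Full measurement pipeline on a mesh: embed, angle, group statistics.

    Returns (angles_rad (N,), degenerate mask (N,), stats dict).
    """
    f_D, _, _, mask = embed_measured(f_m, frames.e_l, frames.e_n, frames.e_t)
    angles = fiber_angle(f_D, frames.e_l, frames.e_n)
    angles = np.atleast_1d(angles)
    stats = angle_statistics(
        angles, labels, frames.layer, mask=mask,
        bin_width_deg=bin_width_deg, n_min=n_min,
    )
    return angles, mask, stats


# ---------------------------------------------------------------------------
# field comparison
# ---------------------------------------------------------------------------


def fiber_diff(f_A, f_B, axial: bool = True):
    """Point-wise fiber orientation difference in [0, 1].

    ``axial=True`` (default) uses 1 - |f_A.f_B|; ``axial=False`` restores
    the sign-sensitive literal form 1 - f_A.f_B (range [0, 2]).
    """
    d = np.einsum("ij,ij->i", np.atleast_2d(f_A), np.atleast_2d(f_B))
    return 1.0 - np.abs(d) if axial else 1.0 - d


#: default "good agreement" threshold: within 30 degrees of the reference
DEFAULT_AGREEMENT_THRESHOLD = 1.0 - np.cos(np.radians(30.0))


def agreement_fraction(diff, mask=None, threshold: float = DEFAULT_AGREEMENT_THRESHOLD):
    """Percentage of nodes (within mask) whose diff is <= threshold."""
    diff = np.asarray(diff)
    if mask is None:
        mask = np.ones(diff.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MeasureError("empty mask")
    return 100.0 * float((diff[mask] <= threshold).sum()) / float(mask.sum())


def agreement_report(diff, labels, layers, threshold=DEFAULT_AGREEMENT_THRESHOLD):
    """Overall, per-layer and per-bundle agreement percentages."""
    labels = np.asarray(labels)
    layers = np.asarray(layers)
    out = {
        "overall": agreement_fraction(diff, threshold=threshold),
        "endo": agreement_fraction(diff, layers == 0, threshold),
        "epi": agreement_fraction(diff, layers == 1, threshold),
        "per_bundle": {},
    }
    for lbl in np.unique(labels):
        out["per_bundle"][int(lbl)] = agreement_fraction(
            diff, labels == lbl, threshold
        )
    return out
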