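"""Local orthonormal axis systems and the rotated fiber/sheet frames.

For each node the flat axis system Q = (e_l, e_n, e_t) is built from the
bundle's transmural source gamma and normal source k:

    e_t = gamma/|gamma|,
    e_n = (k - (k.e_t) e_t)/|...|,
    e_l = e_n x e_t,

and the final fiber/sheet-normal/sheet triad (f, n, s) is obtained by
rotating the longitudinal axis about e_t by the bundle's endo- or
epicardial angle:

    f =  cos(a) e_l + sin(a) e_n,
    n = -sin(a) e_l + cos(a) e_n,
    s =  e_t.

The wall is split into two volumetric layers by the chamber transmural
coordinate (endocardial side phi_chamber < tau_layer); fibers are axial
(f and -f equivalent) for all downstream consumers.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .bundles import BundleMap
from .mesh import LabeledTetMesh


class DegenerateAxisError(ValueError):
    """gamma vanishes or k is (numerically) parallel to gamma."""


_EPS_PAR = 1e-12


def local_axis(gamma, k):
    """Flat axis system from a transmural and a normal source vector.

    Accepts single 3-vectors or (N, 3) arrays; returns (e_l, e_n, e_t) of
    the same shape plus a degenerate mask for array input.  For single
    vectors a degenerate axis raises :class:`DegenerateAxisError`.
    """
    single = np.ndim(gamma) == 1
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    k = np.atleast_2d(np.asarray(k, dtype=float))

    gn = np.linalg.norm(gamma, axis=1)
    bad_g = gn < _EPS_PAR
    e_t = np.where(bad_g[:, None], np.nan, gamma / np.where(bad_g, 1.0, gn)[:, None])

    kproj = k - np.einsum("ij,ij->i", k, e_t)[:, None] * e_t
    kn = np.linalg.norm(kproj, axis=1)
    bad_k = kn < _EPS_PAR * np.maximum(np.linalg.norm(k, axis=1), 1.0)
    e_n = np.where(
        bad_k[:, None], np.nan, kproj / np.where(bad_k, 1.0, kn)[:, None]
    )
    e_l = np.cross(e_n, e_t)
    degenerate = bad_g | bad_k | ~np.isfinite(e_t).all(axis=1)

    if single:
        if degenerate[0]:
            raise DegenerateAxisError("gamma ~ 0 or k parallel to gamma")
        return e_l[0], e_n[0], e_t[0]
    return e_l, e_n, e_t, degenerate


def orient(e_l, e_n, e_t, alpha):
    """Rotate the longitudinal axis about e_t by alpha (radians).

    Returns (f, n, s); alpha may be scalar or per-row.
    """
    alpha = np.asarray(alpha, dtype=float)
    c = np.cos(alpha)
    s = np.sin(alpha)
    if np.ndim(e_l) == 1:
        f = c * e_l + s * e_n
        n = -s * e_l + c * e_n
        return f, n, e_t
    c = c[..., None]
    s = s[..., None]
    f = c * e_l + s * e_n
    n = -s * e_l + c * e_n
    return f, n, e_t


def assign_layer(phi_chamber, tau_layer: float = 0.5):
    """Volumetric bilayer split: 0 = endocardial (phi_chamber < tau_layer),
    1 = epicardial (boundary value goes to the epicardial layer)."""
    return (np.asarray(phi_chamber) >= tau_layer).astype(np.int8)


@dataclass
class FrameField:
    """Per-node flat axes, final triads and layer assignment.

    f and -f are equivalent (axial data); ``degenerate_fixed`` counts nodes
    whose axis system was inherited from the nearest well-defined neighbour.
    """

    e_l: np.ndarray
    e_n: np.ndarray
    e_t: np.ndarray
    f: np.ndarray
    n: np.ndarray
    s: np.ndarray
    layer: np.ndarray  # 0 endo, 1 epi
    alpha: np.ndarray  # applied rotation angle, radians
    degenerate_fixed: int = 0


def _inherit_from_neighbors(mesh: LabeledTetMesh, bad: np.ndarray):
    """For each flagged node, the nearest (BFS over mesh edges) good node."""
    src = np.arange(mesh.n_nodes)
    if not bad.any():
        return src
    adj = mesh.node_neighbors()
    dist = np.where(bad, -1, 0)
    queue = deque(np.nonzero(~bad)[0].tolist())
    while queue:
        i = queue.popleft()
        for j in adj[i]:
            if dist[j] < 0:
                dist[j] = dist[i] + 1
                src[j] = src[i]
                queue.append(j)
    if (dist < 0).any():  # pragma: no cover - fully degenerate component
        raise DegenerateAxisError("no non-degenerate neighbour reachable")
    return src


def generate_fibers(
    mesh: LabeledTetMesh,
    bundlemap: BundleMap,
    tau_layer: float = 0.5,
) -> FrameField:
    """Build the per-node frame field from a bundle map.

    Degenerate axes (harmonic-field extrema where a gradient vanishes, or k
    parallel to gamma) inherit the full assignment of their nearest
    non-degenerate neighbour by breadth-first search over mesh edges.  The
    flip rule of the inter-atrial branches negates e_l and e_t after the
    axis construction (preserving right-handedness).
    """
    e_l, e_n, e_t, bad = local_axis(bundlemap.gamma, bundlemap.k)

    src = _inherit_from_neighbors(mesh, bad)
    fixed = int(bad.sum())
    e_l, e_n, e_t = e_l[src], e_n[src], e_t[src]
    alpha_endo = bundlemap.alpha_endo[src]
    alpha_epi = bundlemap.alpha_epi[src]
    flip = bundlemap.flip[src]

    # flip rule: e_l -> -e_l, e_t -> -e_t (still right-handed)
    sgn = np.where(flip, -1.0, 1.0)[:, None]
    e_l = e_l * sgn
    e_t = e_t * sgn

    layer = assign_layer(bundlemap.phi_chamber, tau_layer)
    alpha = np.where(layer == 0, alpha_endo, alpha_epi)
    f, n, s = orient(e_l, e_n, e_t, alpha)
    return FrameField(
        e_l=e_l, e_n=e_n, e_t=e_t, f=f, n=n, s=s,
        layer=layer, alpha=alpha, degenerate_fixed=fixed,
    )
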