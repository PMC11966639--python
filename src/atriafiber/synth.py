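"""Synthetic labeled geometries and ground-truth fiber fields.

Every pipeline stage is testable without any external data: this module
procedurally builds labeled tetrahedral fixtures --

* ``make_slab``: a structured box whose faces carry a full left-atrial tag
  set (endocardium at z=0, epicardium at the top, ring tags on the sides),
  used for closed-form harmonic and conduction-velocity oracles;
* ``make_idealized_atrium``: a curved dome-shaped shell of finite thickness
  (a single-chart spherical cap, no mesher required) with vein orifices
  punched through the wall, valve-ring sectors along the rim, endo/epi bands
  and landmark nodes -- enough anatomy for every branch of the bundle rules;
* ``make_biatrial``: two dome chambers joined by a flat septal wall built
  from one structured chart, so the left/right harmonic separator and the
  inter-atrial connection windows are exercised on a conforming mesh;
* ``make_ground_truth_fibers``: a measured-fiber stand-in (synthetic, in
  place of diffusion-tensor imaging data) -- per-bundle/per-layer truth
  angles perturbed by axial von Mises noise with random sign flips.

All constructions are deterministic for a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .mesh import LabeledTetMesh
from .tags import BoundaryTag as T


class FixtureError(ValueError):
    """Raised for degenerate or inconsistent fixture specifications."""


# ---------------------------------------------------------------------------
# structured chart -> tetrahedra
# ---------------------------------------------------------------------------

# Freudenthal/Kuhn 6-tet split: one tet per axis permutation, walking from
# corner (0,0,0) to (1,1,1).  Identical in every cell, hence face-conforming
# across the whole structured grid.
_PERMS = list(itertools.permutations(range(3)))


def _build_chart(nu, nv, nw, hole_of_cell, mapping):
    """Mesh the parametric box [-1,1]^2 x [0,1] minus removed cell columns.

    Parameters
    ----------
    hole_of_cell : callable (uc, vc) -> int; -1 keeps the cell, >= 0 removes
        it and records which opening exposed the neighbouring wall faces.
    mapping : callable (u, v, w) arrays -> (x, y, z) arrays, the geometry.

    Returns
    -------
    nodes_xyz, node_uvw, tets, tris, tri_meta
        tri_meta is a structured dict of arrays: axis (0=u,1=v,2=w),
        side (0/1), uc/vc/wc face centers, hole id (-1 if outer boundary).
    """
    du, dv, dw = 2.0 / nu, 2.0 / nv, 1.0 / nw
    uc = -1.0 + du * (np.arange(nu) + 0.5)
    vc = -1.0 + dv * (np.arange(nv) + 0.5)

    hole = np.full((nu, nv), -1, dtype=np.int64)
    for i in range(nu):
        for j in range(nv):
            hole[i, j] = hole_of_cell(uc[i], vc[j])
    keep = hole < 0
    if not keep.any():
        raise FixtureError("all cells removed")

    def nid(i, j, k):
        return (i * (nv + 1) + j) * (nw + 1) + k

    tets = []
    tris = []
    meta_axis, meta_side, meta_u, meta_v, meta_w, meta_hole = [], [], [], [], [], []

    corner = np.empty((2, 2, 2), dtype=np.int64)
    for i in range(nu):
        for j in range(nv):
            if not keep[i, j]:
                continue
            for k in range(nw):
                for di in range(2):
                    for dj in range(2):
                        for dk in range(2):
                            corner[di, dj, dk] = nid(i + di, j + dj, k + dk)
                start = corner[0, 0, 0]
                end = corner[1, 1, 1]
                for p in _PERMS:
                    off = [0, 0, 0]
                    off[p[0]] = 1
                    a = corner[off[0], off[1], off[2]]
                    off[p[1]] = 1
                    b = corner[off[0], off[1], off[2]]
                    tets.append((start, a, b, end))

                # boundary faces of this cell
                for axis in range(3):
                    for side in range(2):
                        ni_, nj_, nk_ = i, j, k
                        if axis == 0:
                            ni_ += 1 if side else -1
                        elif axis == 1:
                            nj_ += 1 if side else -1
                        else:
                            nk_ += 1 if side else -1
                        h = -1
                        if axis < 2:
                            outside = not (0 <= ni_ < nu and 0 <= nj_ < nv)
                            if not outside and keep[ni_, nj_]:
                                continue
                            if not outside:
                                h = int(hole[ni_, nj_])
                        else:
                            if 0 <= nk_ < nw:
                                continue
                        # face corners in the two in-face axes (ascending)
                        oth = [a for a in range(3) if a != axis]
                        offs = {axis: side}
                        def fc(b_, c_):
                            o = dict(offs)
                            o[oth[0]] = b_
                            o[oth[1]] = c_
                            return corner[o[0], o[1], o[2]]
                        q00, q10, q01, q11 = fc(0, 0), fc(1, 0), fc(0, 1), fc(1, 1)
                        tris.append((q00, q10, q11))
                        tris.append((q00, q11, q01))
                        fu = uc[i] + (0.5 * du if axis == 0 else 0) * (2 * side - 1)
                        fv = vc[j] + (0.5 * dv if axis == 1 else 0) * (2 * side - 1)
                        fw = (k + 0.5) * dw + (0.5 * dw if axis == 2 else 0) * (2 * side - 1)
                        for _ in range(2):
                            meta_axis.append(axis)
                            meta_side.append(side)
                            meta_u.append(fu)
                            meta_v.append(fv)
                            meta_w.append(fw)
                            meta_hole.append(h)

    tets = np.array(tets, dtype=np.int64)
    tris = np.array(tris, dtype=np.int64)

    # compress node numbering to used nodes
    used = np.unique(np.concatenate([tets.ravel(), tris.ravel()]))
    newid = -np.ones((nu + 1) * (nv + 1) * (nw + 1), dtype=np.int64)
    newid[used] = np.arange(used.size)
    tets = newid[tets]
    tris = newid[tris]

    ii = used // ((nv + 1) * (nw + 1))
    jj = (used // (nw + 1)) % (nv + 1)
    kk = used % (nw + 1)
    node_uvw = np.column_stack([-1.0 + du * ii, -1.0 + dv * jj, dw * kk])

    x, y, z = mapping(node_uvw[:, 0], node_uvw[:, 1], node_uvw[:, 2])
    nodes = np.column_stack([x, y, z])

    tri_meta = {
        "axis": np.array(meta_axis),
        "side": np.array(meta_side),
        "u": np.array(meta_u),
        "v": np.array(meta_v),
        "w": np.array(meta_w),
        "hole": np.array(meta_hole),
    }
    return nodes, node_uvw, tets, tris, tri_meta


def _nearest_node(node_uvw, u, v, w):
    d = (node_uvw[:, 0] - u) ** 2 + (node_uvw[:, 1] - v) ** 2 + (node_uvw[:, 2] - w) ** 2
    return int(np.argmin(d))


def _finalize(nodes, tets, tris, tri_tags, landmarks, node_chamber=None):
    mesh = LabeledTetMesh(
        nodes=nodes,
        tets=tets,
        boundary_tris=tris,
        tri_tags=np.asarray(tri_tags, dtype=np.int64),
        landmarks=landmarks,
        node_chamber=node_chamber,
    )
    mesh.orient_tets()
    return mesh


# ---------------------------------------------------------------------------
# slab
# ---------------------------------------------------------------------------


@dataclass
class SlabSpec:
    """Structured slab: dimensions in meters, target edge length h."""

    lx: float = 20e-3
    ly: float = 5e-3
    lz: float = 2e-3
    h: float = 0.6e-3
    seed: int = 0


def slab_grid_counts(spec: SlabSpec):
    """Closed-form (nx, ny, nz) cell counts used by :func:`make_slab`."""
    return (
        max(1, round(spec.lx / spec.h)),
        max(1, round(spec.ly / spec.h)),
        max(1, round(spec.lz / spec.h)),
    )


def make_slab(spec: SlabSpec = SlabSpec()) -> LabeledTetMesh:
    """Structured tet slab carrying a complete left-atrial tag set.

    Faces: z=0 endocardium (with septal/lateral strips at the y extremes),
    z=lz epicardium (with two transverse top bands), x=0 the valve-ring
    sectors, x=lx the four vein-ring quarters.  Node/tet counts follow the
    closed-form structured-grid formulas (nx+1)(ny+1)(nz+1) and 6*nx*ny*nz.
    """
    if min(spec.lx, spec.ly, spec.lz) <= 0 or spec.h <= 0:
        raise FixtureError("slab dimensions and h must be positive")
    nx, ny, nz = slab_grid_counts(spec)

    def mapping(u, v, w):
        return (
            (u + 1) / 2 * spec.lx,
            (v + 1) / 2 * spec.ly,
            w * spec.lz,
        )

    nodes, uvw, tets, tris, meta = _build_chart(nx, ny, nz, lambda u, v: -1, mapping)

    tags = np.empty(tris.shape[0], dtype=np.int64)
    ax, sd, u, v = meta["axis"], meta["side"], meta["u"], meta["v"]
    for idx in range(tags.size):
        if ax[idx] == 2 and sd[idx] == 0:  # endocardium
            if v[idx] < -0.6:
                tags[idx] = T.LA_ENDO_SEPT
            elif v[idx] > 0.6:
                tags[idx] = T.LA_ENDO_LAT
            else:
                tags[idx] = T.LA_ENDO
        elif ax[idx] == 2:  # epicardium
            if -0.55 <= u[idx] < -0.15:
                tags[idx] = T.EPI_TOP_LA
            elif 0.15 <= u[idx] < 0.55:
                tags[idx] = T.EPI_TOP_LP
            else:
                tags[idx] = T.EPI
        elif ax[idx] == 0 and sd[idx] == 0:  # valve ring
            tags[idx] = T.MV_ANT if v[idx] >= 0 else T.MV_POST
        elif ax[idx] == 0:  # vein rings
            if v[idx] < -0.5:
                tags[idx] = T.RIPV
            elif v[idx] < 0:
                tags[idx] = T.RSPV
            elif v[idx] < 0.5:
                tags[idx] = T.LIPV
            else:
                tags[idx] = T.LSPV
        elif sd[idx] == 0:  # y=0 wall
            tags[idx] = T.LA_ENDO_SEPT
        else:  # y=ly wall
            tags[idx] = T.LA_ENDO_LAT

    landmarks = {
        "LAA_apex": _nearest_node(uvw, -0.4, 0.0, 1.0),
        "FO_center": _nearest_node(uvw, 0.4, 0.0, 0.0),
    }
    return _finalize(nodes, tets, tris, tags, landmarks)


# ---------------------------------------------------------------------------
# idealized atria (dome shells)
# ---------------------------------------------------------------------------


@dataclass
class AtriumSpec:
    """Dome-shell fixture: a spherical-cap wall of finite thickness.

    The chart square [-1,1]^2 maps to a cap of radius ``radius`` (meters)
    via the direction field n(u,v) = (u t, v t, 1)/|.| with t = ``spread``;
    ``openings`` are through-wall circular holes in chart coordinates
    (name -> (uc, vc, rho)); ``None`` selects the side defaults and an empty
    dict builds an unperforated shell (used by the harmonic oracles).
    Defaults give a chamber of realistic atrial size (2 cm radius,
    2.5 mm wall).
    """

    nu: int = 40
    nv: int = 40
    nw: int = 2
    radius: float = 0.02
    thickness: float = 2.5e-3
    spread: float = 1.6
    center: tuple = (0.0, 0.0, 0.0)
    openings: dict | None = None
    seed: int = 0


LA_OPENINGS = {
    "rspv": (-0.5, 0.45, 0.16),
    "ripv": (-0.5, -0.45, 0.16),
    "lspv": (0.5, 0.45, 0.16),
    "lipv": (0.5, -0.45, 0.16),
}
RA_OPENINGS = {
    "scv": (0.0, 0.5, 0.18),
    "icv": (0.0, -0.5, 0.18),
}

_OPENING_TAG = {
    "rspv": T.RSPV,
    "ripv": T.RIPV,
    "lspv": T.LSPV,
    "lipv": T.LIPV,
    "scv": T.SCV,
    "icv": T.ICV,
}


def _check_openings(openings):
    names = list(openings)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ua, va, ra = openings[names[a]]
            ub, vb, rb = openings[names[b]]
            if np.hypot(ua - ub, va - vb) <= ra + rb:
                raise FixtureError(f"openings {names[a]} and {names[b]} overlap")


def _hole_fn(openings):
    items = list(openings.values())

    def hole_of_cell(u, v):
        for h, (uc, vc, rho) in enumerate(items):
            if np.hypot(u - uc, v - vc) < rho:
                return h
        return -1

    return hole_of_cell


def _dome_mapping(spec: AtriumSpec):
    t = spec.spread
    cx, cy, cz = spec.center

    def mapping(u, v, w):
        nx, ny, nz = u * t, v * t, np.ones_like(u)
        norm = np.sqrt(nx**2 + ny**2 + nz**2)
        r = spec.radius + w * spec.thickness
        return cx + r * nx / norm, cy + r * ny / norm, cz + r * nz / norm

    return mapping


def _tag_la_chart(meta, tags, mask, u_of=None):
    """Tag LA-side faces; `u_of` rescales the chart u to local chamber u."""
    ax, sd = meta["axis"], meta["side"]
    u = meta["u"] if u_of is None else u_of(meta["u"])
    v, hole = meta["v"], meta["hole"]
    for idx in np.nonzero(mask)[0]:
        if hole[idx] >= 0:
            continue  # set by the opening pass
        if ax[idx] == 2 and sd[idx] == 0:
            if u[idx] < -0.62:
                tags[idx] = T.LA_ENDO_LAT
            elif u[idx] > 0.62:
                tags[idx] = T.LA_ENDO_SEPT
            else:
                tags[idx] = T.LA_ENDO
        elif ax[idx] == 2:
            if 0.3 <= v[idx] <= 0.6 and abs(u[idx]) <= 0.66:
                tags[idx] = T.EPI_TOP_LA
            elif -0.6 <= v[idx] <= -0.3 and abs(u[idx]) <= 0.66:
                tags[idx] = T.EPI_TOP_LP
            else:
                tags[idx] = T.EPI
        elif ax[idx] == 1:
            tags[idx] = T.MV_ANT if sd[idx] == 1 else T.MV_POST
        else:
            tags[idx] = T.MV_ANT if v[idx] >= 0 else T.MV_POST


def _tag_ra_chart(meta, tags, mask, u_of=None, septal_edge=True):
    ax, sd = meta["axis"], meta["side"]
    u = meta["u"] if u_of is None else u_of(meta["u"])
    v, hole = meta["v"], meta["hole"]
    for idx in np.nonzero(mask)[0]:
        if hole[idx] >= 0:
            continue
        if ax[idx] == 2 and sd[idx] == 0:
            if v[idx] > 0.62:
                tags[idx] = T.RA_ENDO_ANT
            elif v[idx] < -0.62:
                tags[idx] = T.RA_ENDO_POST
            else:
                tags[idx] = T.RA_ENDO
        elif ax[idx] == 2:
            if abs(u[idx]) <= 0.16 and abs(v[idx]) <= 0.68:
                tags[idx] = T.EPI_TOP_RA
            else:
                tags[idx] = T.EPI
        elif ax[idx] == 1:
            tags[idx] = T.TV_ANT if sd[idx] == 1 else T.TV_POST
        else:
            if sd[idx] == 1:
                tags[idx] = T.TV_LAT
            else:
                tags[idx] = T.TV_SEPT if septal_edge else T.TV_LAT


def make_idealized_atrium(spec: AtriumSpec | None = None, side: str = "la") -> LabeledTetMesh:
    """Dome-shell single atrium with all side-appropriate tags and landmarks."""
    if spec is None:
        spec = AtriumSpec()
    if spec.openings is None:
        openings = dict(LA_OPENINGS if side == "la" else RA_OPENINGS)
    else:
        openings = dict(spec.openings)
    _check_openings(openings)

    nodes, uvw, tets, tris, meta = _build_chart(
        spec.nu, spec.nv, spec.nw, _hole_fn(openings), _dome_mapping(spec)
    )

    tags = np.empty(tris.shape[0], dtype=np.int64)
    names = list(openings)
    hole_faces = meta["hole"] >= 0
    tags[hole_faces] = [
        int(_OPENING_TAG[names[h]]) for h in meta["hole"][hole_faces]
    ]
    allmask = np.ones(tags.size, dtype=bool)
    if side == "la":
        _tag_la_chart(meta, tags, allmask)
        landmarks = {
            "LAA_apex": _nearest_node(uvw, -0.35, 0.05, 0.0),
            "FO_center": _nearest_node(uvw, 0.8, -0.1, 0.0),
        }
    elif side == "ra":
        _tag_ra_chart(meta, tags, allmask)
        landmarks = {
            "RAA_apex": _nearest_node(uvw, 0.5, 0.3, 0.0),
            "CSM_apex": _nearest_node(uvw, -0.55, -0.7, 0.0),
        }
    else:
        raise ValueError(f"side must be la or ra, got {side!r}")
    return _finalize(nodes, tets, tris, tags, landmarks)


# ---------------------------------------------------------------------------
# bi-atrial fixture
# ---------------------------------------------------------------------------


@dataclass
class BiatrialSpec:
    """Two dome chambers joined by a flat septal wall (one structured chart).

    The chart u-interval [-1,-b] maps onto the left chamber, [b,1] onto the
    right, |u|<b onto a ruled septal wall between the facing rims; b is
    ``bridge_halfwidth``.  Chamber separation is chosen so the septum is
    about 0.4 chamber radii wide.
    """

    nu: int = 72
    nv: int = 36
    nw: int = 2
    radius: float = 0.02
    thickness: float = 2.5e-3
    spread: float = 1.6
    bridge_halfwidth: float = 0.12
    septal_bridge: bool = True
    seed: int = 0


def make_biatrial(spec: BiatrialSpec | None = None) -> LabeledTetMesh:
    """Connected bi-atrial fixture with all 26 taxonomy tags and 4 landmarks."""
    if spec is None:
        spec = BiatrialSpec()
    b = spec.bridge_halfwidth
    t = spec.spread
    R, thk = spec.radius, spec.thickness
    D = 1.05 * R  # chamber center offset along x

    la_spec = AtriumSpec(radius=R, thickness=thk, spread=t, center=(-D, 0, 0))
    ra_spec = AtriumSpec(radius=R, thickness=thk, spread=t, center=(+D, 0, 0))
    map_la, map_ra = _dome_mapping(la_spec), _dome_mapping(ra_spec)

    def ul_of(u):
        return 2.0 * (u + 1.0) / (1.0 - b) - 1.0

    def ur_of(u):
        return 2.0 * (u - b) / (1.0 - b) - 1.0

    def mapping(u, v, w):
        u = np.asarray(u, dtype=float)
        x = np.empty_like(u)
        y = np.empty_like(u)
        z = np.empty_like(u)
        la = u <= -b
        ra = u >= b
        br = ~la & ~ra
        x[la], y[la], z[la] = map_la(ul_of(u[la]), v[la], w[la])
        x[ra], y[ra], z[ra] = map_ra(ur_of(u[ra]), v[ra], w[ra])
        if br.any():
            s = (u[br] + b) / (2 * b)
            xa, ya, za = map_la(np.ones_like(s), v[br], w[br])
            xb, yb, zb = map_ra(-np.ones_like(s), v[br], w[br])
            x[br] = (1 - s) * xa + s * xb
            y[br] = (1 - s) * ya + s * yb
            z[br] = (1 - s) * za + s * zb
        return x, y, z

    # openings in local chamber coordinates -> chart coordinates
    def to_chart_la(ul):
        return (ul + 1.0) * (1.0 - b) / 2.0 - 1.0

    def to_chart_ra(ur):
        return (ur + 1.0) * (1.0 - b) / 2.0 + b

    scale_u = (1.0 - b) / 2.0  # chart-u per local-u
    openings = {}
    for name, (uc, vc, rho) in LA_OPENINGS.items():
        openings[name] = (to_chart_la(uc), vc, rho * scale_u * 1.3)
    for name, (uc, vc, rho) in RA_OPENINGS.items():
        openings[name] = (to_chart_ra(uc), vc, rho * scale_u * 1.3)
    _check_openings(openings)

    hole_names = list(openings)

    def hole_fn(u, v):
        if not spec.septal_bridge and abs(u) < b:
            return 10_000  # removed cell, not an opening
        for h, (uc, vc, rho) in enumerate(openings.values()):
            # holes are round in local chamber coordinates
            if np.hypot((u - uc) / scale_u, v - vc) < rho / scale_u:
                return h
        return -1

    nodes, uvw, tets, tris, meta = _build_chart(spec.nu, spec.nv, spec.nw, hole_fn, mapping)

    # connectivity check (the septal bridge is the only LA-RA connection)
    e = np.sort(tets[:, [0, 1, 0, 2, 0, 3, 1, 2, 1, 3, 2, 3]].reshape(-1, 2), axis=1)
    g = coo_matrix(
        (np.ones(e.shape[0]), (e[:, 0], e[:, 1])), shape=(nodes.shape[0],) * 2
    )
    ncomp, _ = connected_components(g, directed=False)
    if ncomp != 1:
        raise FixtureError(f"bi-atrial mesh is disconnected ({ncomp} components)")

    u_face = meta["u"]
    tags = np.empty(tris.shape[0], dtype=np.int64)
    hole = meta["hole"]
    real_hole = (hole >= 0) & (hole < 10_000)
    tags[real_hole] = [int(_OPENING_TAG[hole_names[h]]) for h in hole[real_hole]]
    meta = dict(meta)
    meta["hole"] = np.where(real_hole, hole, -1)

    la_mask = (u_face < -b) & ~real_hole
    ra_mask = (u_face > b) & ~real_hole
    br_mask = ~la_mask & ~ra_mask & ~real_hole
    _tag_la_chart(meta, tags, la_mask, u_of=ul_of)
    _tag_ra_chart(meta, tags, ra_mask, u_of=ur_of, septal_edge=False)

    # septal wall: both wall surfaces are epicardial for the harmonic fields
    # (left/right separator interpolates freely across the septum); the rim
    # edges provide the anterior/posterior MV junction and the septal TV sector
    ax, sd = meta["axis"], meta["side"]
    for idx in np.nonzero(br_mask)[0]:
        if ax[idx] == 2:
            tags[idx] = T.EPI
        elif ax[idx] == 1 or ax[idx] == 0:
            if u_face[idx] < 0:
                tags[idx] = T.MV_ANT if (ax[idx] == 1 and sd[idx] == 1) else T.MV_POST
            else:
                tags[idx] = T.TV_SEPT

    landmarks = {
        "LAA_apex": _nearest_node(uvw, to_chart_la(-0.35), 0.05, 0.0),
        "FO_center": _nearest_node(uvw, 0.0, -0.15, 0.0),
        "RAA_apex": _nearest_node(uvw, to_chart_ra(0.5), 0.3, 0.0),
        # coronary-sinus musculature: posterior LA/RA junction, on the septum
        "CSM_apex": _nearest_node(uvw, 0.05, -0.55, 0.0),
    }

    chamber = np.where(
        uvw[:, 0] < -b + 1e-12, 1, np.where(uvw[:, 0] > b - 1e-12, -1, 0)
    ).astype(np.int64)
    return _finalize(nodes, tets, tris, tags, landmarks, node_chamber=chamber)


# ---------------------------------------------------------------------------
# synthetic measured-fiber fields
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthFiberSpec:
    """Truth table of per-bundle (endo, epi) angles in degrees, axial von
    Mises noise concentration ``kappa`` (np.inf = noiseless), and a seed.
    ``truth`` maps bundle label -> (alpha_endo_deg, alpha_epi_deg); bundles
    absent from the map fall back to the frame's own rotation angle."""

    truth: dict = field(default_factory=dict)
    kappa: float = np.inf
    sign_flips: bool = True
    seed: int = 0


def make_ground_truth_fibers(frames, bundlemap, spec: GroundTruthFiberSpec):
    """Noisy axial measured-fiber stand-in aligned with known truth angles.

    ``frames`` is the :class:`~atriafiber.fibers.FrameField` of the mesh
    (provides the flat axes and the endo/epi layer); the returned array is a
    per-node raw direction field f_m with random sign flips, suitable for the
    measurement pipeline.  Noise: the axial angle is perturbed by delta with
    2*delta ~ von Mises(0, kappa) in the tangent (e_l, e_n) plane.
    """
    rng = np.random.default_rng(spec.seed)
    n = frames.e_l.shape[0]
    is_endo = frames.layer == 0
    # default truth = the rotation angles the bundle map itself prescribes
    alpha = np.where(is_endo, bundlemap.alpha_endo, bundlemap.alpha_epi)
    for lbl, (a_endo, a_epi) in spec.truth.items():
        m = bundlemap.label == int(lbl)
        alpha = np.where(m & is_endo, np.radians(a_endo), alpha)
        alpha = np.where(m & ~is_endo, np.radians(a_epi), alpha)

    if np.isfinite(spec.kappa):
        # axial noise: 2*delta ~ von Mises(0, kappa), drawn on the doubled
        # scale and halved back
        delta = 0.5 * rng.vonmises(0.0, spec.kappa, size=n)
        alpha = alpha + delta
    f = (
        np.cos(alpha)[:, None] * frames.e_l
        + np.sin(alpha)[:, None] * frames.e_n
    )
    if spec.sign_flips:
        sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
        f = f * sign[:, None]
    return f
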