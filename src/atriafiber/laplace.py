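"""P1 finite-element Laplace-Dirichlet solves and harmonic distance fields.

Each inter- or intra-atrial "distance" is the solution of

    -div(grad chi) = 0   in the atrial wall,
    chi = chi_a on Gamma_a,  chi = chi_b on Gamma_b,  d(chi)/dn = 0 elsewhere,

for prescribed boundary values on tagged boundary partitions.  The full set
of fields (the left/right separator xi, the transmural phi with its chamber
variants phi_la = 1 - phi and phi_ra = 1 + phi, and the intra-atrial psi_i)
is produced by :func:`solve_distance_set` from the boundary-data table below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import LabeledTetMesh
from .tags import (
    GAMMA_EPI,
    GAMMA_LA,
    GAMMA_LPV,
    GAMMA_MV,
    GAMMA_RA,
    GAMMA_RPV,
    GAMMA_TV,
    BoundaryTag as T,
    tag_priority,
)


class LaplaceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Dirichlet specification
# ---------------------------------------------------------------------------


@dataclass
class DirichletSpec:
    """Ordered list of (node-set source, value) assignments.

    Each assignment is ``(tags_or_nodes, value)`` where the first element is
    a set of boundary tags, a landmark name (resolved to its k-ring patch),
    or an explicit node-index array.  Conflicting values at patch-junction
    nodes are resolved by tag priority (landmark patches > rings > bands >
    endo/epi), then by assignment order; conflicts are recorded.
    """

    assignments: list
    patch_k: int = 1

    def resolve(self, mesh: LabeledTetMesh):
        """Return (dirichlet node indices, values) plus a conflict report."""
        value = {}
        prio = {}
        conflicts = []
        for entry, val in self.assignments:
            if isinstance(entry, str):  # landmark name
                nodes = mesh.landmark_patch(entry, k=self.patch_k)
                p = 3
            elif isinstance(entry, (set, frozenset)) or (
                isinstance(entry, (list, tuple)) and entry and isinstance(entry[0], T)
            ):
                tags = set(entry)
                nodes = mesh.tag_nodes(tags)
                p = max(tag_priority(t) for t in tags)
            else:
                nodes = np.asarray(entry, dtype=np.int64)
                p = 3
            for n in nodes.tolist():
                if n in value:
                    if value[n] != val and p > prio[n]:
                        conflicts.append((n, value[n], val))
                        value[n] = val
                        prio[n] = p
                    elif value[n] != val:
                        conflicts.append((n, value[n], val))
                else:
                    value[n] = val
                    prio[n] = p
        if not value:
            raise LaplaceError("empty Dirichlet set")
        idx = np.array(sorted(value), dtype=np.int64)
        vals = np.array([value[i] for i in idx])
        return idx, vals, conflicts


# ---------------------------------------------------------------------------
# assembly and solve
# ---------------------------------------------------------------------------


def _shape_gradients(mesh: LabeledTetMesh):
    """Per-tet P1 shape-function gradients (T, 4, 3) and volumes (T,)."""
    p = mesh.nodes[mesh.tets]
    v0, v1, v2, v3 = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
    # rows of the Jacobian inverse give grad of barycentric coords 1..3
    J = np.stack([v1 - v0, v2 - v0, v3 - v0], axis=2)  # (T, 3, 3) columns
    detJ = np.linalg.det(J)
    vol = detJ / 6.0
    Jinv = np.linalg.inv(J)
    g123 = Jinv  # (T, 3, 3): row i is grad of barycentric coord i+1
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)  # (T, 4, 3)
    return grads, vol


def stiffness_matrix(mesh: LabeledTetMesh) -> sp.csr_matrix:
    """Assembled P1 stiffness matrix (symmetric positive semidefinite)."""
    grads, vol = _shape_gradients(mesh)
    if np.any(vol <= 0):
        raise LaplaceError("mesh contains non-positive tets; call orient_tets()")
    ke = np.einsum("tid,tjd,t->tij", grads, grads, vol)  # (T, 4, 4)
    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    K = sp.coo_matrix(
        (ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()
    return K


@dataclass
class ScalarField:
    name: str
    values: np.ndarray


@dataclass
class VectorField:
    name: str
    vectors: np.ndarray  # (N, 3) nodal
    degenerate: np.ndarray  # (N,) bool


def solve_laplace(
    mesh: LabeledTetMesh,
    spec: DirichletSpec,
    name: str = "chi",
    rtol: float = 1e-8,
    K: sp.csr_matrix | None = None,
) -> ScalarField:
    """Solve the Laplace-Dirichlet problem; homogeneous Neumann elsewhere.

    Dirichlet conditions are imposed by symmetric row/column elimination and
    the reduced SPD system is solved with diagonally preconditioned CG
    (relative residual <= ``rtol``), with a direct sparse fallback.
    """
    idx, vals, _ = spec.resolve(mesh)
    if K is None:
        K = stiffness_matrix(mesh)
    n = mesh.n_nodes
    free = np.setdiff1d(np.arange(n), idx, assume_unique=False)

    u = np.zeros(n)
    u[idx] = vals
    if free.size:
        Kff = K[free][:, free].tocsr()
        rhs = -K[free][:, idx] @ vals
        d = Kff.diagonal()
        d[d == 0] = 1.0
        M = sp.diags(1.0 / d)
        x, info = spla.cg(Kff, rhs, rtol=rtol, atol=0.0, M=M, maxiter=20000)
        if info != 0:  # pragma: no cover - robustness fallback
            x = spla.spsolve(Kff.tocsc(), rhs)
        u[free] = x
    return ScalarField(name=name, values=u)


def gradient(
    mesh: LabeledTetMesh,
    f,
    eps_scale: float = 1e-10,
    grads_vol=None,
) -> VectorField:
    """Nodal gradient of a P1 field: per-tet constant gradients averaged to
    nodes with tet-volume weights; near-zero gradients are flagged degenerate
    (threshold eps_scale * field range / bbox diagonal)."""
    values = f.values if isinstance(f, ScalarField) else np.asarray(f)
    name = f.name if isinstance(f, ScalarField) else "field"
    grads, vol = grads_vol if grads_vol is not None else _shape_gradients(mesh)
    gt = np.einsum("tid,ti->td", grads, values[mesh.tets])  # (T, 3)

    gn = np.zeros((mesh.n_nodes, 3))
    wn = np.zeros(mesh.n_nodes)
    for c in range(4):
        np.add.at(gn, mesh.tets[:, c], gt * vol[:, None])
        np.add.at(wn, mesh.tets[:, c], vol)
    gn /= wn[:, None]

    frange = float(values.max() - values.min())
    eps = eps_scale * (frange if frange > 0 else 1.0) / mesh.bbox_diagonal()
    degenerate = np.linalg.norm(gn, axis=1) < eps
    return VectorField(name=f"grad_{name}", vectors=gn, degenerate=degenerate)


# ---------------------------------------------------------------------------
# the boundary-data table
# ---------------------------------------------------------------------------

# Each row: field name -> ordered (boundary set, value) assignments.
# Landmark patches are referenced by landmark name.  LA and RA intra-atrial
# rows are kept separate; on a bi-atrial mesh both sets are solved on the
# full domain (the Dirichlet data only touches the respective side).

XI_ROW = [(GAMMA_LA, 1.0), (GAMMA_RA, -1.0)]
PHI_ROW = [(GAMMA_LA, 1.0), (GAMMA_RA, -1.0), (GAMMA_EPI, 0.0)]

LA_ROWS = {
    "psi_ab": [
        (GAMMA_RPV, 2.0),
        (GAMMA_LPV, 0.0),
        (GAMMA_MV, 1.0),
        ("LAA_apex", -1.0),
    ],
    "psi_v": [(GAMMA_RPV, 1.0), (GAMMA_LPV, 0.0)],
    "psi_r": [
        (GAMMA_MV, 1.0),
        (GAMMA_LPV | GAMMA_RPV | {T.EPI_TOP_LA, T.EPI_TOP_LP}, 0.0),
    ],
    "psi_w": [
        ({T.RSPV, T.LSPV, T.MV_ANT}, 1.0),
        ({T.RIPV, T.LIPV, T.MV_POST}, -1.0),
    ],
    "psi_t": [(GAMMA_MV, 1.0), ({T.EPI_TOP_LA, T.EPI_TOP_LP}, 0.0)],
    "psi_a": [({T.LA_ENDO_SEPT}, 1.0), ({T.LA_ENDO_LAT}, 0.0)],
    "psi_aa": [("FO_center", 1.0), ("LAA_apex", -2.0)],
    # stacked-row pairing in printed order: anterior ring 1, top-anterior band
    # with the endocardial side bands 0, top-posterior band -0.5, posterior
    # ring -1
    "psi_s": [
        ({T.MV_ANT}, 1.0),
        ({T.EPI_TOP_LA, T.LA_ENDO_SEPT, T.LA_ENDO_LAT}, 0.0),
        ({T.EPI_TOP_LP}, -0.5),
        ({T.MV_POST}, -1.0),
    ],
}

RA_ROWS = {
    "psi_ab": [
        ({T.ICV}, 2.0),
        ({T.SCV}, 0.0),
        (GAMMA_TV, 1.0),
        ("RAA_apex", -2.0),
        ("CSM_apex", -2.0),
    ],
    "psi_v": [({T.ICV}, 1.0), ({T.SCV}, 0.0)],
    "psi_r": [(GAMMA_TV, 1.0), ({T.ICV, T.SCV, T.EPI_TOP_RA}, 0.0)],
    "psi_w": [({T.TV_SEPT}, 1.0), ({T.TV_LAT}, -1.0), ({T.EPI_TOP_RA}, 0.0)],
    "psi_t": [(GAMMA_TV, 1.0), ({T.EPI_TOP_RA}, 0.0)],
    "psi_a": [
        ({T.RA_ENDO_ANT, T.SCV}, 1.0),
        ({T.RA_ENDO_POST, T.ICV}, -1.0),
        ("RAA_apex", 2.0),
    ],
    "psi_aa": [
        ({T.ICV, T.RA_ENDO_POST}, 1.0),
        ("RAA_apex", -2.0),
        ({T.SCV}, 0.0),
    ],
    "psi_ct": [
        ({T.TV_SEPT, T.TV_ANT, T.TV_POST}, 1.0),
        ({T.TV_LAT}, -1.0),
    ],
}


@dataclass
class DistanceFields:
    """All harmonic distances and nodal gradients for one side or bi-atrial.

    LA and RA intra-atrial distances carry ``_la`` / ``_ra`` suffixes; use
    :meth:`f` and :meth:`g` for access by short name and side.
    """

    side: str
    fields: dict = field(default_factory=dict)  # name -> (N,) values
    gradients: dict = field(default_factory=dict)  # name -> VectorField

    def f(self, name: str, side: str | None = None) -> np.ndarray:
        return self.fields[self._key(name, side)]

    def g(self, name: str, side: str | None = None) -> np.ndarray:
        return self.gradients[self._key(name, side)].vectors

    def _key(self, name, side):
        if name in self.fields:
            return name
        key = f"{name}_{side}" if side else name
        if key not in self.fields:
            raise KeyError(f"field {name!r} (side={side}) not available")
        return key


def _required_tags_present(mesh, row, row_name):
    for entry, _ in row:
        if isinstance(entry, str):
            if entry not in mesh.landmarks:
                raise LaplaceError(
                    f"boundary-data row {row_name!r} needs landmark {entry}"
                )
        else:
            if mesh.tag_nodes(entry).size == 0:
                names = sorted(t.name.lower() for t in entry)
                raise LaplaceError(
                    f"boundary-data row {row_name!r} needs tags {names}"
                )


def solve_distance_set(
    mesh: LabeledTetMesh,
    side: str = "biatrial",
    rtol: float = 1e-10,
    patch_k: int = 1,
) -> DistanceFields:
    """Solve every boundary-data row required for ``side``.

    For ``side="biatrial"`` the separator xi, the transmural phi and both the
    LA and RA intra-atrial sets are solved on the whole domain.  For a single
    atrium phi uses only that chamber's endocardium (so phi_la / phi_ra still
    span [0, 1] across the wall).
    """
    K = stiffness_matrix(mesh)
    grads_vol = _shape_gradients(mesh)
    out = DistanceFields(side=side)

    def solve_row(name, row):
        _required_tags_present(mesh, row, name)
        f = solve_laplace(
            mesh, DirichletSpec(list(row), patch_k=patch_k), name=name, rtol=rtol, K=K
        )
        out.fields[name] = f.values
        out.gradients[name] = gradient(mesh, f, grads_vol=grads_vol)

    if side == "biatrial":
        solve_row("xi", XI_ROW)
        solve_row("phi", PHI_ROW)
    elif side == "la":
        solve_row("phi", [(GAMMA_LA, 1.0), (GAMMA_EPI, 0.0)])
    elif side == "ra":
        solve_row("phi", [(GAMMA_RA, -1.0), (GAMMA_EPI, 0.0)])
    else:
        raise ValueError(f"unknown side {side!r}")

    phi = out.fields["phi"]
    out.fields["phi_la"] = 1.0 - phi
    out.fields["phi_ra"] = 1.0 + phi
    gphi = out.gradients["phi"]
    out.gradients["phi_la"] = VectorField("grad_phi_la", -gphi.vectors, gphi.degenerate)
    out.gradients["phi_ra"] = VectorField("grad_phi_ra", gphi.vectors.copy(), gphi.degenerate)

    if side in ("la", "biatrial"):
        for name, row in LA_ROWS.items():
            solve_row(f"{name}_la", row)
    if side in ("ra", "biatrial"):
        for name, row in RA_ROWS.items():
            solve_row(f"{name}_ra", row)
    return out
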