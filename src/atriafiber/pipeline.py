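"""End-to-end workflows: fiber generation, measurement, activation runs.

Thin orchestration over the library modules; each step returns plain data
plus a JSON-serializable run report.  The command line wraps these.
"""

from __future__ import annotations

import time

import numpy as np

from .bundles import (
    AngleTable,
    BundleParams,
    LABEL_LEGEND,
    select_biatrial,
    select_la,
    select_ra,
)
from .eikonal import (
    EPParams,
    compare_at,
    element_tensors,
    solve_activation,
    spherical_stimulus,
)
from .fibers import generate_fibers
from .laplace import solve_distance_set
from .measure import agreement_report, fiber_diff, measure_fiber_field
from .mesh import LabeledTetMesh, validate_labels


class PipelineError(RuntimeError):
    pass


def run_fibers(
    mesh: LabeledTetMesh,
    side: str = "biatrial",
    params: BundleParams | None = None,
    angles: AngleTable | None = None,
    patch_k: int = 1,
):
    """Full fiber-generation pipeline (harmonic solves -> bundles -> frames).

    Returns (fields, bundlemap, frames, report).
    """
    params = params or BundleParams()
    angles = angles or AngleTable()
    rep = validate_labels(mesh, side)
    if not rep.passed:
        raise PipelineError(f"label validation failed:\n{rep}")

    t0 = time.perf_counter()
    fields = solve_distance_set(mesh, side, patch_k=patch_k)
    t1 = time.perf_counter()
    select = {"la": select_la, "ra": select_ra, "biatrial": select_biatrial}[side]
    bundlemap = select(fields, params, angles)
    t2 = time.perf_counter()
    frames = generate_fibers(mesh, bundlemap, tau_layer=params.tau_layer)
    t3 = time.perf_counter()

    report = {
        "side": side,
        "n_nodes": mesh.n_nodes,
        "n_tets": mesh.n_tets,
        "timings_s": {
            "laplace": t1 - t0,
            "bundles": t2 - t1,
            "frames": t3 - t2,
        },
        "degenerate_nodes_fixed": frames.degenerate_fixed,
        "bundle_counts": bundlemap.counts(),
        "legend": LABEL_LEGEND,
    }
    return fields, bundlemap, frames, report


def run_measure(
    frames,
    bundlemap,
    f_measured: np.ndarray,
    f_reference: np.ndarray | None = None,
    bin_width_deg: float = 10.0,
    n_min: int = 50,
    agreement_threshold: float | None = None,
):
    """Measurement pipeline on a measured fiber field (+ optional diff).

    Returns (angles, mask, stats, comparison) where comparison is None
    without a reference field.
    """
    angles, mask, stats = measure_fiber_field(
        f_measured, frames, bundlemap.label, bin_width_deg=bin_width_deg, n_min=n_min
    )
    comparison = None
    if f_reference is not None:
        fm = np.asarray(f_measured, dtype=float)
        fm = fm / np.linalg.norm(fm, axis=1, keepdims=True)
        kwargs = {}
        if agreement_threshold is not None:
            kwargs["threshold"] = agreement_threshold
        diff = fiber_diff(fm, f_reference)
        comparison = {
            "diff": diff,
            "report": agreement_report(
                diff, bundlemap.label, frames.layer, **kwargs
            ),
        }
    return angles, mask, stats, comparison


def run_simulate(
    mesh: LabeledTetMesh,
    frames,
    ep: EPParams | None = None,
    stimulus_center=None,
    stimulus_nodes=None,
    reference_frames=None,
    labels=None,
):
    """Eikonal activation with fiber tensors; optional reference comparison.

    The stimulus is a sphere at ``stimulus_center`` (default: the mesh node
    closest to the domain centroid of the superior caval region is NOT
    guessed -- callers must supply a center or explicit nodes).
    """
    ep = ep or EPParams()
    if stimulus_nodes is None:
        if stimulus_center is None:
            raise PipelineError("need stimulus_center or stimulus_nodes")
        stimulus_nodes = spherical_stimulus(mesh, stimulus_center, ep.stimulus_radius)
    amap = solve_activation(mesh, element_tensors(mesh, frames, ep), ep, stimulus_nodes)
    comparison = None
    if reference_frames is not None:
        ref = solve_activation(
            mesh, element_tensors(mesh, reference_frames, ep), ep, stimulus_nodes
        )
        comparison = compare_at(amap, ref, labels=labels, legend=LABEL_LEGEND)
    return amap, comparison


def stats_to_rows(stats):
    """Flatten a measurement stats dict to CSV-ready rows."""
    rows = [
        (
            "bundle",
            "layer",
            "n",
            "dominant_deg",
            "mean_deg",
            "sd_deg",
            "resultant",
        )
    ]
    for (lbl, lay), st in sorted(stats.items()):
        rows.append(
            (
                LABEL_LEGEND.get(lbl, str(lbl)),
                "endo" if lay == 0 else "epi",
                st.n,
                "" if st.dominant_deg is None else f"{st.dominant_deg:.1f}",
                "" if st.mean_deg is None else f"{st.mean_deg:.2f}",
                f"{st.sd_deg:.2f}",
                f"{st.resultant:.4f}",
            )
        )
    return rows
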