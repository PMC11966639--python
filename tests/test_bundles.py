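"""Bundle-selection cascades: literal branches, coverage, order sensitivity."""

import hashlib

import numpy as np
import pytest

import atriafiber as af
from atriafiber.bundles import (
    AngleTable,
    BundleLabel as L,
    BundleParams,
    IC_LABELS,
    LA_LABELS,
    RA_LABELS,
    pm_intervals,
    pm_membership,
    select_biatrial,
    select_la,
    select_ra,
)
from atriafiber.laplace import DistanceFields, VectorField


# ---------------------------------------------------------------------------
# hand-built field sets to force single branches
# ---------------------------------------------------------------------------


def _fieldset(side, n=4, **values):
    """Constant DistanceFields with per-name constant gradients.

    values: name -> (value, gradient 3-vector); names without side suffix.
    """
    df = DistanceFields(side=side)
    for name, (val, grad) in values.items():
        df.fields[name] = np.full(n, float(val))
        g = np.tile(np.asarray(grad, dtype=float), (n, 1))
        df.gradients[name] = VectorField(f"grad_{name}", g, np.zeros(n, dtype=bool))
    return df


def _la_base(n=4, **over):
    vals = dict(
        phi=(0.5, (0, 0, 1)), phi_la=(0.5, (0, 0, -1)), phi_ra=(1.5, (0, 0, 1)),
        psi_r_la=(0.5, (1, 0, 0)), psi_v_la=(0.5, (0, 1, 0)),
        psi_w_la=(0.0, (1, 1, 0)), psi_aa_la=(0.0, (0, 1, 1)),
        psi_s_la=(0.5, (1, 0, 0)), psi_a_la=(0.5, (0, 1, 0)),
        psi_t_la=(0.5, (1, 0, 0)), psi_ab_la=(0.5, (0, 1, 0)),
    )
    vals.update(over)
    return _fieldset("la", n, **vals)


def test_mitral_branch_takes_psi_r_normal():
    df = _la_base(psi_r_la=(0.95, (1, 0, 0)))
    bm = select_la(df, BundleParams(tau_mv=0.9))
    assert (bm.label == L.MV).all()
    assert np.allclose(bm.k, [1, 0, 0])
    assert np.allclose(bm.gamma, [0, 0, 1])  # grad phi


def test_right_inferior_vein_branch():
    p = BundleParams(tau_rpv=0.7, tau_rpv_up=0.2, tau_ripv=-0.2)
    df = _la_base(psi_v_la=(0.8, (0, 1, 0)), psi_r_la=(0.1, (1, 0, 0)),
                  psi_w_la=(-0.5, (1, 1, 0)))
    bm = select_la(df, p)
    assert (bm.label == L.RIPV).all()
    assert np.allclose(bm.k, [0, 1, 0])  # k = grad psi_v


def test_carina_takes_psi_w_normal():
    p = BundleParams(tau_rpv=0.7, tau_rpv_up=0.2, tau_ripv=-0.35, tau_rspv=0.35)
    df = _la_base(psi_v_la=(0.8, (0, 1, 0)), psi_r_la=(0.1, (1, 0, 0)),
                  psi_w_la=(0.0, (1, 1, 0)))
    bm = select_la(df, p)
    assert (bm.label == L.RC).all()
    assert np.allclose(bm.k, np.array([1, 1, 0]))


def test_posterior_wall_layer_dependent_normal():
    # reaches LAW_TOP: psi_s below tau_las, none of the earlier sub-branches
    p = BundleParams(tau_las=-0.05, tau_plw_la=0.25, tau_psw_la=0.75,
                     tau_lar=0.15, tau_law=0.45)
    common = dict(
        psi_s_la=(-0.5, (1, 0, 0)), psi_a_la=(0.5, (0, 1, 0)),
        psi_w_la=(-0.5, (1, 1, 0)), psi_t_la=(0.5, (1, 0, 0)),
        psi_r_la=(0.3, (1, 0, 0)), psi_v_la=(0.5, (0, 1, 0)),
        psi_ab_la=(0.5, (0, 0, 1)),
    )
    endo = _la_base(phi_la=(0.2, (0, 0, -1)), **common)
    epi = _la_base(phi_la=(0.8, (0, 0, -1)), **common)
    bm_endo = select_la(endo, p)
    bm_epi = select_la(epi, p)
    assert (bm_endo.label == L.LAW_TOP).all() and (bm_epi.label == L.LAW_TOP).all()
    assert np.allclose(bm_endo.k, [0, 1, 0])  # endocardial side: grad psi_v
    assert np.allclose(bm_epi.k, [0, 0, 1])  # epicardial side: grad psi_ab


def _ra_base(n=4, **over):
    vals = dict(
        phi=(-0.5, (0, 0, 1)), phi_la=(1.5, (0, 0, -1)), phi_ra=(0.5, (0, 0, 1)),
        psi_r_ra=(0.5, (1, 0, 0)), psi_v_ra=(0.5, (0, 1, 0)),
        psi_w_ra=(0.0, (1, 1, 0)), psi_aa_ra=(0.5, (0, 1, 1)),
        psi_a_ra=(0.0, (0, 1, 0)), psi_t_ra=(0.5, (1, 0, 0)),
        psi_ab_ra=(0.5, (0, 1, 0)), psi_ct_ra=(0.5, (1, 0, 1)),
    )
    vals.update(over)
    return _fieldset("ra", n, **vals)


def test_crista_terminalis_branch():
    p = BundleParams(tau_ct_minus=-0.15, tau_ct_plus=0.2, tau_ct_phi=0.3,
                     tau_alw_ra=0.5, tau_ib_l=0.1)
    df = _ra_base(psi_ct_ra=(0.1, (1, 0, 1)), phi_ra=(0.2, (0, 0, 1)),
                  psi_t_ra=(0.5, (1, 0, 0)), psi_a_ra=(0.0, (0, 1, 0)))
    bm = select_ra(df, p)
    assert (bm.label == L.CT).all()
    assert np.allclose(bm.k, [1, 0, 1])


def test_pectinate_loop_and_switch():
    p = BundleParams(tau_raa=0.10, pm_tk=0.05, pm_rg=0.03, n_pm=2, pm_end=0.5,
                     tau_ct_minus=-0.15, tau_ct_plus=0.0, tau_ct_phi=0.6,
                     tau_raa_w=-2.0)  # keep the RAA branch off
    inside = _ra_base(psi_ct_ra=(-0.5, (1, 0, 1)), psi_aa_ra=(0.12, (0, 1, 1)),
                      phi_ra=(0.2, (0, 0, 1)))
    gap = _ra_base(psi_ct_ra=(-0.5, (1, 0, 1)), psi_aa_ra=(0.16, (0, 1, 1)),
                   phi_ra=(0.2, (0, 0, 1)))
    assert (select_ra(inside, p).label == L.PM).all()
    assert (select_ra(gap, p).label == L.RLW).all()
    p_off = BundleParams(**{**p.__dict__, "pm": False})
    assert (select_ra(inside, p_off).label == L.RLW).all()


def test_pm_intervals_closed_form():
    p = BundleParams(tau_raa=0.10, pm_tk=0.05, pm_rg=0.03, n_pm=2)
    assert pm_intervals(p) == [
        pytest.approx((0.10, 0.15, 0.18)),
        pytest.approx((0.18, 0.23, 0.26)),
    ]
    p1 = BundleParams(tau_raa=0.10, pm_tk=0.05, pm_rg=0.03, n_pm=1)
    assert pm_intervals(p1) == [pytest.approx((0.10, 0.15, 0.18))]


def test_pm_membership_matches_exhaustive_scan(rng):
    p = BundleParams(tau_raa=-0.8, pm_tk=0.1, pm_rg=0.07, n_pm=6, pm_end=0.55)
    psi = rng.uniform(-1.5, 1.5, size=1000)
    fast = pm_membership(psi, p)
    ivs = pm_intervals(p)
    slow = np.array([
        any(lo <= x <= hi for lo, hi, _ in ivs) and x <= p.pm_end for x in psi
    ])
    assert np.array_equal(fast, slow)


# ---------------------------------------------------------------------------
# inter-atrial connections
# ---------------------------------------------------------------------------


def _bia_base(n=4, xi=0.05, **over):
    vals = dict(
        xi=(xi, (1, 0, 0)),
        phi=(0.5, (0, 0, 1)), phi_la=(0.5, (0, 0, -1)), phi_ra=(1.5, (0, 0, 1)),
    )
    df = _fieldset("biatrial", n, **vals)
    for src in (_la_base(n), _ra_base(n)):
        for name in src.fields:
            if name not in df.fields:
                df.fields[name] = src.fields[name]
                df.gradients[name] = src.gradients[name]
    for name, (val, grad) in over.items():
        df.fields[name] = np.full(n, float(val))
        df.gradients[name] = VectorField(
            f"grad_{name}", np.tile(np.asarray(grad, float), (n, 1)),
            np.zeros(n, dtype=bool),
        )
    return df


def test_bachmann_connection_first_branch_with_flip():
    p = BundleParams(tau_bbic_r=-0.1, tau_bbic_l=0.1, tau_bbic=0.2)
    df = _bia_base(xi=0.05, psi_v_ra=(0.1, (0, 1, 0)))
    bm = select_biatrial(df, p)
    assert (bm.label == L.BB_IC).all()
    assert bm.flip.all()
    assert np.allclose(bm.gamma, [1, 0, 0])  # grad xi, not grad phi


def test_outside_ic_windows_dispatches_by_separator_sign():
    p = BundleParams(tau_bbic_r=-0.1, tau_bbic_l=0.1)
    df = _bia_base(xi=0.5, psi_r_la=(0.95, (1, 0, 0)))
    bm = select_biatrial(df, p)
    assert (bm.label == L.MV).all()
    df_ra = _bia_base(xi=-0.5, psi_r_ra=(0.95, (1, 0, 0)), psi_ab_ra=(0.9, (0, 1, 0)))
    bm2 = select_biatrial(df_ra, p)
    assert (bm2.label == L.TV).all()


def test_coronary_sinus_connection_zero_angles_and_flip():
    p = BundleParams(tau_csic_r=-0.1, tau_csic_l=0.1, tau_csic=-0.5,
                     tau_bbic=0.2, fo_ic=False)
    df = _bia_base(xi=0.0, psi_v_ra=(0.5, (0, 1, 0)), psi_ab_ra=(-0.8, (0, 1, 0)))
    bm = select_biatrial(df, p)
    assert (bm.label == L.CS_IC).all()
    assert bm.flip.all()
    assert np.allclose(bm.alpha_endo, 0.0) and np.allclose(bm.alpha_epi, 0.0)


# ---------------------------------------------------------------------------
# fixture-level coverage, switches, monotonicity, order pinning
# ---------------------------------------------------------------------------


def test_la_cascade_identifies_fifteen_bundles(la_fields):
    bm = select_la(la_fields)
    assert set(bm.labels_present()) == LA_LABELS
    assert len(bm.labels_present()) == 15


def test_ra_cascade_identifies_twelve_bundles(ra_fields):
    bm = select_ra(ra_fields)
    assert set(bm.labels_present()) == RA_LABELS
    assert len(bm.labels_present()) == 12


def test_biatrial_cascade_covers_all_bundles(bia_fields):
    bm = select_biatrial(bia_fields)
    present = set(bm.labels_present())
    assert IC_LABELS < present
    assert present == IC_LABELS | LA_LABELS | RA_LABELS
    # partition: every node assigned exactly one label
    assert sum(bm.counts().values()) == bm.label.size


def test_ic_switches_remove_exactly_their_labels(bia_fields):
    base = select_biatrial(bia_fields)
    for switch, lbl in (("bb_ic", L.BB_IC), ("fo_ic", L.FO_IC), ("cs_ic", L.CS_IC)):
        p = BundleParams(**{switch: False})
        bm = select_biatrial(bia_fields, p)
        assert lbl in base.labels_present()
        assert lbl not in bm.labels_present()
        others = {l for l in IC_LABELS if l != lbl}
        assert others <= set(bm.labels_present())


def test_csm_switch_on_ra_fixture(ra_fields):
    bm = select_ra(ra_fields, BundleParams(csm=False))
    assert L.CSM not in bm.labels_present()


def test_pm_switch_reassigns_to_lateral_wall(ra_fields):
    with_pm = select_ra(ra_fields)
    without = select_ra(ra_fields, BundleParams(pm=False))
    pm_nodes = with_pm.label == L.PM
    assert pm_nodes.any()
    assert (without.label[pm_nodes] == L.RLW).all()


def test_raising_single_threshold_shrinks_its_bundle(la_fields, ra_fields):
    mv_lo = (select_la(la_fields, BundleParams(tau_mv=0.80)).label == L.MV)
    mv_hi = (select_la(la_fields, BundleParams(tau_mv=0.90)).label == L.MV)
    assert mv_hi.sum() < mv_lo.sum()
    assert not (mv_hi & ~mv_lo).any()  # strictly nested
    tv_lo = (select_ra(ra_fields, BundleParams(tau_tv=0.80)).label == L.TV)
    tv_hi = (select_ra(ra_fields, BundleParams(tau_tv=0.90)).label == L.TV)
    assert not (tv_hi & ~tv_lo).any()


def test_cascade_order_regression_hash(la_fields):
    """The branch order is part of the method: pin the LA label array."""
    bm = select_la(la_fields)
    digest = hashlib.sha256(bm.label.astype(np.int64).tobytes()).hexdigest()
    assert digest == "74b3664bbb6b828c5f83e87b01f6bef8f87e34b11121046e09caa5f7bdb91262"


def test_labels_respect_separator_sign(bia_fields):
    bm = select_biatrial(bia_fields)
    xi = bia_fields.f("xi")
    la_nodes = np.isin(bm.label, [int(l) for l in LA_LABELS])
    ra_nodes = np.isin(bm.label, [int(l) for l in RA_LABELS])
    assert (xi[la_nodes] > 0).all()
    assert (xi[ra_nodes] <= 0).all()


def test_angle_table_rejects_out_of_range():
    with pytest.raises(ValueError):
        AngleTable(angles={L.MV: (120.0, 0.0)})


def test_params_yaml_round_trip():
    p = BundleParams(tau_mv=0.77, n_pm=3, pm=False)
    q = BundleParams.from_yaml(p.to_yaml())
    assert q == p
    at = AngleTable()
    at2 = AngleTable.from_yaml(at.to_yaml())
    assert at2.angles == at.angles


def test_invalid_pectinate_parameters_rejected():
    with pytest.raises(ValueError):
        BundleParams(pm_tk=0.0)
    with pytest.raises(ValueError):
        BundleParams(n_pm=-1)
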