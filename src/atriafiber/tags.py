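"""Boundary-tag taxonomy for labeled bi-atrial meshes.

The atrial boundary is partitioned into endocardial bands, epicardial
surfaces (with "top" bands joining the vein orifices), vein/valve rings and
four landmark patches (appendage apices, fossa ovalis center, coronary-sinus
apex).  Composite sets such as the full mitral ring or the union of the left
pulmonary-vein rings are always *derived* from the atomic tags and never
stored separately.
"""

from __future__ import annotations

from enum import IntEnum


class BoundaryTag(IntEnum):
    """Atomic boundary-triangle tags.

    Integer values are the on-disk cell-data codes used by the VTU dialect.
    """

    # LA endocardium and its bands
    LA_ENDO = 1
    LA_ENDO_SEPT = 2
    LA_ENDO_LAT = 3
    # RA endocardium and its bands
    RA_ENDO = 4
    RA_ENDO_ANT = 5
    RA_ENDO_POST = 6
    # epicardium and top bands
    EPI = 7
    EPI_TOP_LA = 8
    EPI_TOP_LP = 9
    EPI_TOP_RA = 10
    # pulmonary-vein rings
    LSPV = 11
    LIPV = 12
    RSPV = 13
    RIPV = 14
    # caval-vein rings
    SCV = 15
    ICV = 16
    # mitral-valve ring sectors
    MV_ANT = 17
    MV_POST = 18
    # tricuspid-valve ring sectors
    TV_ANT = 19
    TV_POST = 20
    TV_SEPT = 21
    TV_LAT = 22
    # landmark patches (apex node + k-ring)
    LAA_APEX = 23
    RAA_APEX = 24
    FO_CENTER = 25
    CSM_APEX = 26


#: lower-case names as used in configs / reports
TAG_NAMES = {t: t.name.lower() for t in BoundaryTag}
NAME_TO_TAG = {v: k for k, v in TAG_NAMES.items()}

# ---------------------------------------------------------------------------
# composite boundary sets (Gamma_* in the harmonic-distance boundary table)
# ---------------------------------------------------------------------------
T = BoundaryTag

GAMMA_LA = frozenset({T.LA_ENDO, T.LA_ENDO_SEPT, T.LA_ENDO_LAT})
GAMMA_RA = frozenset({T.RA_ENDO, T.RA_ENDO_ANT, T.RA_ENDO_POST})
GAMMA_EPI = frozenset({T.EPI, T.EPI_TOP_LA, T.EPI_TOP_LP, T.EPI_TOP_RA})
GAMMA_MV = frozenset({T.MV_ANT, T.MV_POST})
GAMMA_TV = frozenset({T.TV_ANT, T.TV_POST, T.TV_SEPT, T.TV_LAT})
GAMMA_LPV = frozenset({T.LSPV, T.LIPV})
GAMMA_RPV = frozenset({T.RSPV, T.RIPV})

#: tags required for each validation side
LA_TAGS = frozenset(
    {
        T.LA_ENDO,
        T.LA_ENDO_SEPT,
        T.LA_ENDO_LAT,
        T.EPI,
        T.EPI_TOP_LA,
        T.EPI_TOP_LP,
        T.LSPV,
        T.LIPV,
        T.RSPV,
        T.RIPV,
        T.MV_ANT,
        T.MV_POST,
        T.LAA_APEX,
        T.FO_CENTER,
    }
)
RA_TAGS = frozenset(
    {
        T.RA_ENDO,
        T.RA_ENDO_ANT,
        T.RA_ENDO_POST,
        T.EPI,
        T.EPI_TOP_RA,
        T.SCV,
        T.ICV,
        T.TV_ANT,
        T.TV_POST,
        T.TV_SEPT,
        T.TV_LAT,
        T.RAA_APEX,
        T.CSM_APEX,
    }
)
BIATRIAL_TAGS = frozenset(BoundaryTag)

#: landmark names -> the boundary tag realizing the patch
LANDMARK_TAGS = {
    "LAA_apex": T.LAA_APEX,
    "RAA_apex": T.RAA_APEX,
    "FO_center": T.FO_CENTER,
    "CSM_apex": T.CSM_APEX,
}

LANDMARKS_BY_SIDE = {
    "la": ("LAA_apex", "FO_center"),
    "ra": ("RAA_apex", "CSM_apex"),
    "biatrial": ("LAA_apex", "RAA_apex", "FO_center", "CSM_apex"),
}

# Dirichlet conflict resolution: higher class wins; within a class the
# first-listed assignment wins.  Landmark patches > rings > bands > endo/epi.
_PRIORITY = {}
for t in (T.LAA_APEX, T.RAA_APEX, T.FO_CENTER, T.CSM_APEX):
    _PRIORITY[t] = 3
for t in GAMMA_MV | GAMMA_TV | GAMMA_LPV | GAMMA_RPV | {T.SCV, T.ICV}:
    _PRIORITY[t] = 2
for t in (
    T.LA_ENDO_SEPT,
    T.LA_ENDO_LAT,
    T.RA_ENDO_ANT,
    T.RA_ENDO_POST,
    T.EPI_TOP_LA,
    T.EPI_TOP_LP,
    T.EPI_TOP_RA,
):
    _PRIORITY[t] = 1
for t in (T.LA_ENDO, T.RA_ENDO, T.EPI):
    _PRIORITY[t] = 0


def tag_priority(tag: BoundaryTag) -> int:
    """Priority class of a tag for Dirichlet-conflict resolution."""
    return _PRIORITY[tag]


def required_tags(side: str) -> frozenset:
    """Tag set a mesh must carry to run the given side's pipeline."""
    try:
        return {"la": LA_TAGS, "ra": RA_TAGS, "biatrial": BIATRIAL_TAGS}[side]
    except KeyError:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown side {side!r}; expected la, ra or biatrial")
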