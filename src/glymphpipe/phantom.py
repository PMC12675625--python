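"""Ground-truth digital phantoms for the microstructure / glymphatic pipeline.

The phantom is a deliberately simple geometric convention, not an anatomy: two
tube-shaped white-matter tracts crossing at 90°, a gray-matter ribbon
enclosing the interior, a central CSF block standing in for the lateral
ventricle, and two periventricular slabs ("projection" and "association"
fibers) flanking it, where perivascular flow along the left–right (x) axis is
encoded as a multiplicative gain on x-axis diffusivity.  Regions are defined
in fractional coordinates so the same layout scales to any grid that is large
enough to keep every region non-empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = ["Label", "ConditionParams", "PhantomTruth", "make_phantom"]

MIN_GRID = (20, 24, 20)


class Label(IntEnum):
    """Fixed tissue-label enumeration used by every phantom."""

    BACKGROUND = 0
    CSF = 1
    GM = 2
    WM_TRACT_1 = 3       # tube along x
    WM_TRACT_2 = 4       # tube along y
    WM_CROSSING = 5      # both orientations
    PV_PROJECTION = 6    # periventricular, fibers along z
    PV_ASSOCIATION = 7   # periventricular, fibers along y


# tissue parameter table: (icvf, odi, iso)
_TISSUE_NODDI = {
    Label.CSF: (0.0, 1.0, 1.0),
    Label.GM: (0.40, 0.60, 0.10),
    Label.WM_TRACT_1: (0.70, 0.20, 0.05),
    Label.WM_TRACT_2: (0.70, 0.20, 0.05),
    Label.WM_CROSSING: (0.70, 0.25, 0.05),
    Label.PV_PROJECTION: (0.60, 0.15, 0.10),
    Label.PV_ASSOCIATION: (0.60, 0.15, 0.10),
}


@dataclass(frozen=True)
class ConditionParams:
    """Condition knobs separating "control" from "patient" phantoms.

    ``odi_delta`` is subtracted from ODI inside the configured deficit
    regions (patients show *lower* dispersion there); ``perivascular_gain``
    multiplies x-axis diffusivity in the periventricular slabs and is lower
    in patients (worse glymphatic flow).  With tortuosity
    d_perp = d_par·(1−icvf), the noiseless planted ALPS index equals the
    gain exactly, so the defaults put controls near 1.6 and patients near
    1.2 — the ordering the glymphatic literature reports.
    """

    odi_delta: float = 0.0
    perivascular_gain: float = 1.6
    deficit_labels: tuple = (Label.WM_TRACT_1,)
    #: fractional x-range of the deficit region within deficit-labelled voxels
    deficit_x_range: tuple = (0.15, 0.45)

    def __post_init__(self):
        if not (0.0 <= self.odi_delta <= 1.0):
            raise ValueError("odi_delta must lie in [0, 1]")
        if self.perivascular_gain < 0:
            raise ValueError("perivascular_gain must be >= 0")

    @classmethod
    def control(cls) -> "ConditionParams":
        return cls()

    @classmethod
    def patient(cls, odi_delta: float = 0.10,
                perivascular_gain: float = 1.2) -> "ConditionParams":
        return cls(odi_delta=odi_delta, perivascular_gain=perivascular_gain)


@dataclass
class PhantomTruth:
    """Voxelwise ground truth for one synthetic subject/condition."""

    label_map: np.ndarray            # int8, Label values
    orientation_field: np.ndarray    # (X, Y, Z, 2, 3); zero rows where absent
    icvf_map: np.ndarray
    odi_map: np.ndarray
    iso_map: np.ndarray
    perivascular_gain: float
    voxel_size_mm: float
    deficit_mask: np.ndarray
    condition: ConditionParams
    seed: int

    @property
    def grid_shape(self):
        return self.label_map.shape

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.label_map != Label.BACKGROUND

    @property
    def wm_mask(self) -> np.ndarray:
        return np.isin(self.label_map, [Label.WM_TRACT_1, Label.WM_TRACT_2,
                                        Label.WM_CROSSING,
                                        Label.PV_PROJECTION,
                                        Label.PV_ASSOCIATION])

    def gm_probability(self) -> np.ndarray:
        """Idealized GM tissue-probability map (0.9 on the ribbon)."""
        p = np.zeros(self.grid_shape)
        p[self.label_map == Label.GM] = 0.9
        p[np.isin(self.label_map, [Label.WM_TRACT_1, Label.WM_TRACT_2,
                                   Label.WM_CROSSING])] = 0.1
        p[self.label_map == Label.CSF] = 0.02
        return p


def _box(shape, fx, fy, fz):
    """Boolean box from fractional (lo, hi) ranges per axis."""
    nx, ny, nz = shape
    m = np.zeros(shape, dtype=bool)
    sl = tuple(slice(int(round(lo * n)), max(int(round(lo * n)) + 1,
                                             int(round(hi * n))))
               for (lo, hi), n in zip((fx, fy, fz), shape))
    m[sl] = True
    return m


def make_phantom(grid_shape=(40, 48, 40), voxel_size_mm: float = 2.0,
                 condition: ConditionParams | None = None,
                 seed: int = 0) -> PhantomTruth:
    """Build the ground-truth phantom for one condition.

    Deterministic given ``seed`` (recorded for provenance; tissue parameters
    are piecewise constant by design, so the layout itself is seed-free).
    Raises if the grid cannot hold the documented layout.
    """
    condition = ConditionParams.control() if condition is None else condition
    grid_shape = tuple(int(n) for n in grid_shape)
    if len(grid_shape) != 3 or any(n < m for n, m in zip(grid_shape, MIN_GRID)):
        raise ValueError(
            f"grid {grid_shape} too small for the tract layout "
            f"(minimum {MIN_GRID})")

    labels = np.zeros(grid_shape, dtype=np.int8)

    # GM ribbon: shell of the brain box
    brain = _box(grid_shape, (0.06, 0.94), (0.06, 0.94), (0.06, 0.94))
    interior = _box(grid_shape, (0.12, 0.88), (0.12, 0.88), (0.12, 0.88))
    labels[brain & ~interior] = Label.GM

    # crossing tube tracts
    t1 = _box(grid_shape, (0.10, 0.90), (0.16, 0.28), (0.16, 0.28))
    t2 = _box(grid_shape, (0.60, 0.72), (0.10, 0.90), (0.16, 0.28))
    labels[t1] = Label.WM_TRACT_1
    labels[t2] = Label.WM_TRACT_2
    labels[t1 & t2] = Label.WM_CROSSING

    # ventricle and periventricular slabs (left hemisphere = lower x)
    vent = _box(grid_shape, (0.42, 0.58), (0.40, 0.62), (0.40, 0.60))
    proj = _box(grid_shape, (0.30, 0.42), (0.40, 0.62), (0.40, 0.60))
    assoc = _box(grid_shape, (0.18, 0.30), (0.40, 0.62), (0.40, 0.60))
    labels[vent] = Label.CSF
    labels[proj] = Label.PV_PROJECTION
    labels[assoc] = Label.PV_ASSOCIATION

    for lab in Label:
        if lab != Label.BACKGROUND and not np.any(labels == lab):
            raise ValueError(f"grid {grid_shape} leaves region {lab.name} empty")

    # orientations: up to two unit vectors per voxel
    orient = np.zeros(grid_shape + (2, 3))
    ex, ey, ez = np.eye(3)
    orient[labels == Label.WM_TRACT_1, 0] = ex
    orient[labels == Label.WM_TRACT_2, 0] = ey
    orient[labels == Label.WM_CROSSING, 0] = ex
    orient[labels == Label.WM_CROSSING, 1] = ey
    orient[labels == Label.PV_PROJECTION, 0] = ez
    orient[labels == Label.PV_ASSOCIATION, 0] = ey
    orient[labels == Label.GM, 0] = ez          # nominal axis, heavily dispersed
    orient[labels == Label.CSF, 0] = ez

    icvf = np.zeros(grid_shape)
    odi = np.zeros(grid_shape)
    iso = np.zeros(grid_shape)
    for lab, (v_icvf, v_odi, v_iso) in _TISSUE_NODDI.items():
        m = labels == lab
        icvf[m], odi[m], iso[m] = v_icvf, v_odi, v_iso

    # patient ODI deficit confined to a fractional-x window of the
    # configured labels
    nx = grid_shape[0]
    xs = np.arange(nx)
    lo, hi = condition.deficit_x_range
    in_x = (xs >= round(lo * nx)) & (xs < round(hi * nx))
    deficit = np.isin(labels, [int(l) for l in condition.deficit_labels])
    deficit &= in_x[:, None, None]
    odi[deficit] = np.clip(odi[deficit] - condition.odi_delta, 0.0, 1.0)

    return PhantomTruth(
        label_map=labels, orientation_field=orient, icvf_map=icvf,
        odi_map=odi, iso_map=iso,
        perivascular_gain=condition.perivascular_gain,
        voxel_size_mm=float(voxel_size_mm), deficit_mask=deficit,
        condition=condition, seed=int(seed),
    )
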