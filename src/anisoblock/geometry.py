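"""Tissue geometries: two orthogonal-fiber regions meeting at a straight border.

The canonical domain is split by a vertical border at ``border_x``.  In the
left ("transverse") region the fibers run parallel to the border, so
propagation in +x crosses the fibers and uses the low conductivity; in the
right ("longitudinal") region fibers are orthogonal to the border and +x
propagation is fast.  An optional isotropic strip (or a
patch limited in y) straddling the border uses a single conductivity in
both directions.

Coordinates are 0-based node indices with physical x = index * h; the border
lies on a half-node plane between two columns.  Conductivities live on the
half-integer links between nodes; a link takes the region of its midpoint,
and a midpoint exactly on the border belongs to the left region.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "TissueGeometry",
    "ConductivityMap",
    "build_conductivity",
    "two_region_cable",
    "two_region_sheet",
    "SIGMA_PAR_DEFAULT",
]

SIGMA_PAR_DEFAULT = 0.154  # mm^2/ms, along-fiber coupling coefficient

REGION_TRANSVERSE = 0
REGION_LONGITUDINAL = 1
REGION_ISOTROPIC = 2


@dataclasses.dataclass(frozen=True)
class TissueGeometry:
    """Rectangular domain with a straight fiber-orientation border.

    Lengths are stored in mm (grid spacing ``h_um`` in micrometres).
    ``height_mm`` equal to ``h`` gives a 1D cable.
    """

    width_mm: float
    height_mm: float
    h_um: float
    border_x_mm: float
    strip_halfwidth_mm: float = 0.0
    # isotropic region limited to a band in y (None: full height)
    strip_y_center_mm: float = None
    strip_halfheight_mm: float = None

    def __post_init__(self) -> None:
        if not (0.0 < self.border_x_mm < self.width_mm):
            raise ValueError("border_x must lie strictly inside the domain")
        if self.strip_halfwidth_mm < 0:
            raise ValueError("strip halfwidth must be >= 0")

    @property
    def h_mm(self) -> float:
        return self.h_um / 1000.0

    @property
    def nx(self) -> int:
        return int(round(self.width_mm / self.h_mm))

    @property
    def ny(self) -> int:
        return max(1, int(round(self.height_mm / self.h_mm)))

    @property
    def shape(self) -> tuple:
        return (self.ny, self.nx)

    def x_of(self, ix: int) -> float:
        return ix * self.h_mm

    def node_at_x(self, x_mm: float) -> int:
        ix = int(round(x_mm / self.h_mm))
        return min(max(ix, 0), self.nx - 1)

    def node_at_y(self, y_mm: float) -> int:
        iy = int(round(y_mm / self.h_mm))
        return min(max(iy, 0), self.ny - 1)

    def region_of(self, x_mm: float, y_mm: float = 0.0) -> int:
        if self.strip_halfwidth_mm > 0 and abs(x_mm - self.border_x_mm) <= self.strip_halfwidth_mm:
            if (self.strip_halfheight_mm is None
                    or abs(y_mm - (self.strip_y_center_mm or 0.0))
                    <= self.strip_halfheight_mm):
                return REGION_ISOTROPIC
        return REGION_TRANSVERSE if x_mm <= self.border_x_mm else REGION_LONGITUDINAL

    def region_map(self) -> np.ndarray:
        """Per-node region labels (ny, nx) for inspection/export."""
        xs = np.arange(self.nx) * self.h_mm
        ys = np.arange(self.ny) * self.h_mm
        grid = np.where(xs <= self.border_x_mm, REGION_TRANSVERSE,
                        REGION_LONGITUDINAL)[None, :].repeat(self.ny, axis=0)
        if self.strip_halfwidth_mm > 0:
            in_x = np.abs(xs - self.border_x_mm) <= self.strip_halfwidth_mm
            if self.strip_halfheight_mm is None:
                in_y = np.ones(self.ny, dtype=bool)
            else:
                in_y = np.abs(ys - (self.strip_y_center_mm or 0.0)) <= self.strip_halfheight_mm
            grid[np.ix_(in_y, in_x)] = REGION_ISOTROPIC
        return grid.astype(np.int8)

    def export_region_csv(self, path) -> None:
        np.savetxt(path, self.region_map(), fmt="%d", delimiter=",")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TissueGeometry":
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class ConductivityMap:
    """Half-node link conductivities (mm^2/ms).

    ``sigx`` has shape (ny, nx-1): link k couples columns k and k+1.
    ``sigy`` has shape (ny-1, nx).
    """

    sigx: np.ndarray
    sigy: np.ndarray
    sigma_par: float
    sigma_perp: float
    ar: float

    def __post_init__(self) -> None:
        if np.any(self.sigx <= 0) or np.any(self.sigy <= 0):
            raise ValueError("conductivities must be positive")

    @property
    def sigma_max(self) -> float:
        mx = float(self.sigx.max()) if self.sigx.size else 0.0
        my = float(self.sigy.max()) if self.sigy.size else 0.0
        return max(mx, my, 1e-30)


def build_conductivity(
    geom: TissueGeometry, ar: float, sigma_par: float = SIGMA_PAR_DEFAULT,
    strip_sigma: str = "par",
) -> ConductivityMap:
    """Assemble link conductivities for the two-region (plus strip) domain.

    The cross-fiber coefficient is sigma_par / AR^2, so plane-wave speeds
    obey v_par / v_perp = AR.  AR < 1 is rejected: fiber orientation is
    encoded by the region map, not by the ratio.

    ``strip_sigma`` sets the coupling inside the optional isotropic strip:
    "par" (default) uses the fast along-fiber coefficient in both
    directions; "perp" the slow one; "geometric" their geometric mean
    sigma_par/AR (the speed of disordered fibers).
    """
    if ar < 1.0:
        raise ValueError(f"AR must be >= 1 (orientation is set by the region map), got {ar}")
    if sigma_par <= 0:
        raise ValueError("sigma_par must be positive")
    sigma_perp = sigma_par / (ar * ar)
    try:
        sigma_iso = {"par": sigma_par, "perp": sigma_perp,
                     "geometric": sigma_par / ar}[strip_sigma]
    except KeyError:
        raise ValueError(f"unknown strip_sigma {strip_sigma!r}") from None
    ny, nx, h = geom.ny, geom.nx, geom.h_mm

    def link_sigma(x_mid: float, y_mid: float, along_x: bool) -> float:
        region = geom.region_of(x_mid, y_mid)
        if region == REGION_ISOTROPIC:
            return sigma_iso
        if region == REGION_TRANSVERSE:
            # fibers parallel to the border (along y)
            return sigma_perp if along_x else sigma_par
        return sigma_par if along_x else sigma_perp

    x_mid_links = (np.arange(nx - 1) + 0.5) * h
    x_nodes = np.arange(nx) * h
    y_nodes = np.arange(ny) * h
    y_mid_links = (np.arange(max(ny - 1, 0)) + 0.5) * h
    sigx = np.array([[link_sigma(x, y, True) for x in x_mid_links]
                     for y in y_nodes]).reshape(ny, nx - 1)
    sigy = np.array([[link_sigma(x, y, False) for x in x_nodes]
                     for y in y_mid_links]).reshape(max(ny - 1, 0), nx)

    return ConductivityMap(
        sigx=np.ascontiguousarray(sigx),
        sigy=np.ascontiguousarray(sigy),
        sigma_par=sigma_par,
        sigma_perp=sigma_perp,
        ar=ar,
    )


def two_region_cable(length_mm: float = 64.0, h_um: float = 125.0) -> TissueGeometry:
    """Production 1D cable: 64 mm (512 nodes at 125 um), border at midpoint.

    Long enough that the sealed ends do not influence the border during the
    decision window.
    """
    return TissueGeometry(
        width_mm=length_mm,
        height_mm=h_um / 1000.0,
        h_um=h_um,
        border_x_mm=length_mm / 2.0,
    )


def two_region_sheet(
    width_cm: float = 6.4,
    height_cm: float = 3.2,
    h_um: float = 250.0,
    strip_halfwidth_mm: float = 0.0,
    strip_y_center_mm: float = None,
    strip_halfheight_mm: float = None,
) -> TissueGeometry:
    """2D sheet with the border at mid-width, optional isotropic strip.

    ``strip_halfheight_mm`` limits the isotropic region to a patch centred
    on ``strip_y_center_mm``; None keeps it the full height.
    """
    return TissueGeometry(
        width_mm=width_cm * 10.0,
        height_mm=height_cm * 10.0,
        h_um=h_um,
        border_x_mm=width_cm * 10.0 / 2.0,
        strip_halfwidth_mm=strip_halfwidth_mm,
        strip_y_center_mm=strip_y_center_mm,
        strip_halfheight_mm=strip_halfheight_mm,
    )
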