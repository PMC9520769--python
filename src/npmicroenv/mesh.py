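"""Finite-volume meshes for culture geometries.

Three symmetries cover the scenario families:

* ``planar1D`` -- a vertical media column for monolayer vessels (lateral
  uniformity assumed); the adherent cells live on the base as a flux
  boundary.
* ``axisymmetric2D`` -- an r-z grid for a single construct (bead,
  cylindrical hydrogel, or pellet) resting centred on the base of a
  flat-bottomed well or a truncated-cone tube.
* ``spherical1D`` -- radial shells, used for the reduced-order multi-bead
  model and for analytic-oracle verification.

Meshes are conservative: cell volumes are computed from exact slice
volumes of the vessel solid, so the meshed volume equals the media plus
construct volume independent of resolution.  Spherical constructs that do
not conform to the grid are represented by per-cell construct volume
fractions (normalised so the total encapsulated volume -- and hence the
total cell number -- is exact); diffusivities of interface cells are
fraction-blended.

All lengths are stored in metres; the free surface of the media is the
top of the domain and carries the dissolved-oxygen Dirichlet condition,
every other exterior boundary (plastic, symmetry axis) is no-flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .exceptions import GeometryError
from .scenarios import SOLUTES, CultureScenario

MM = 1e-3  # mm -> m
UL = 1e-9  # ul -> m^3
ML = 1e-6  # ml -> m^3


@dataclass
class Mesh:
    """A conservative finite-volume mesh.

    Faces are stored as index pairs with the geometric data needed for a
    two-sided transmissibility, ``T = area / (d_i/D_i + d_j/D_j)``.
    ``top_*`` arrays describe the free-surface faces where the
    dissolved-oxygen Dirichlet value applies.
    """

    symmetry: str
    vol: np.ndarray  # cell volumes, m^3
    frac: np.ndarray  # construct volume fraction per cell
    region: np.ndarray  # 0 = media, 1 = construct
    diff: Mapping[str, np.ndarray]  # cell diffusivities per solute, m^2/s
    face_i: np.ndarray
    face_j: np.ndarray
    face_area: np.ndarray  # m^2
    face_di: np.ndarray  # centre-to-face distance on side i, m
    face_dj: np.ndarray
    top_cells: np.ndarray
    top_area: np.ndarray
    top_d: np.ndarray
    centers_r_mm: np.ndarray
    centers_z_mm: np.ndarray
    axis_cells: np.ndarray  # cells along the symmetry axis / column, ordered
    base_cell: Optional[int] = None  # planar1D: cell carrying the monolayer flux
    base_area_m2: float = 0.0
    expected_volume_m3: float = 0.0

    @property
    def n_cells(self) -> int:
        return self.vol.size

    @property
    def total_volume_m3(self) -> float:
        return float(self.vol.sum())

    @property
    def construct_volume_m3(self) -> float:
        return float((self.vol * self.frac).sum())

    def transmissibility(self, solute: str) -> np.ndarray:
        """Per-face transmissibility for ``solute``, m^3/h."""
        d = self.diff[solute]
        t = self.face_area / (
            self.face_di / d[self.face_i] + self.face_dj / d[self.face_j]
        )
        return t * 3600.0

    def top_transmissibility(self, solute: str) -> np.ndarray:
        d = self.diff[solute]
        return self.top_area / (self.top_d / d[self.top_cells]) * 3600.0


def _axis_faces(
    fine_end: float,
    total_end: float,
    dx: float,
    growth: float = 1.3,
    dx_max: float = math.inf,
) -> np.ndarray:
    """Face coordinates: uniform spacing ``dx`` to ``fine_end``, then a
    geometrically graded tail rescaled to land exactly on ``total_end``."""
    fine_end = min(fine_end, total_end)
    n_fine = max(int(round(fine_end / dx)), 1)
    faces = list(np.linspace(0.0, fine_end, n_fine + 1))
    if total_end > fine_end * (1 + 1e-12):
        step = dx
        tail = [fine_end]
        while tail[-1] < total_end:
            step = min(step * growth, dx_max)
            tail.append(tail[-1] + step)
        tail = np.array(tail)
        tail = fine_end + (tail - fine_end) * (total_end - fine_end) / (
            tail[-1] - fine_end
        )
        faces.extend(tail[1:])
    return np.asarray(faces)


def _blend_diffusivities(scenario: CultureScenario, frac: np.ndarray) -> dict:
    out = {}
    for s in SOLUTES:
        dm = scenario.media_diffusivities[s]
        dc = scenario.construct.diffusivities[s] if scenario.construct else dm
        out[s] = dm * (1.0 - frac) + dc * frac
    return out


def _sphere_fraction(
    rf: np.ndarray, zf: np.ndarray, zc: float, a: float, nsub: int = 4
) -> np.ndarray:
    """Construct volume fraction of each (r, z) cell for a sphere of radius
    ``a`` centred on the axis at height ``zc`` (midpoint subsampling with
    annular volume weights)."""
    nr, nz = rf.size - 1, zf.size - 1
    frac = np.zeros((nz, nr))
    u = (np.arange(nsub) + 0.5) / nsub
    for iz in range(nz):
        z0, z1 = zf[iz], zf[iz + 1]
        if z1 < zc - a or z0 > zc + a:
            continue
        zs = z0 + u * (z1 - z0)
        for ir in range(nr):
            r0, r1 = rf[ir], rf[ir + 1]
            if r0 > a:
                continue
            rs = r0 + u * (r1 - r0)
            R, Z = np.meshgrid(rs, zs)
            inside = R**2 + (Z - zc) ** 2 <= a**2
            w = R  # annular volume weight
            frac[iz, ir] = float((w * inside).sum() / w.sum())
    return frac


def _normalise_fraction(frac: np.ndarray, vol: np.ndarray, target: float) -> np.ndarray:
    """Scale fractions so the encapsulated volume matches ``target`` exactly
    while keeping every fraction within [0, 1]."""
    frac = frac.copy()
    for _ in range(8):
        captured = float((frac * vol).sum())
        if captured <= 0:
            break
        free = frac < 1.0
        fixed = float((vol * frac)[~free].sum())
        denom = float((frac * vol)[free].sum())
        if denom <= 0:
            break
        scale = (target - fixed) / denom
        frac[free] = np.minimum(frac[free] * scale, 1.0)
        if abs((frac * vol).sum() - target) <= 1e-12 * target:
            break
    return frac


def build_mesh(scenario: CultureScenario, resolution: int = 40) -> Mesh:
    """Discretise a scenario.

    ``resolution`` is the number of cells across the smallest construct
    dimension (the default 40 is the package's convergence-verified
    standard); monolayer columns use ``3 * resolution`` cells.
    """
    scenario.validate()
    if scenario.mode == "monolayer":
        return _build_planar(scenario, resolution)
    if scenario.mode == "multibead":
        return build_compartment_mesh(scenario, resolution)
    return _build_axisymmetric(scenario, resolution)


def _build_planar(scenario: CultureScenario, resolution: int) -> Mesh:
    area = scenario.vessel.base_area_cm2 * 1e-4
    height = scenario.vessel.media_volume_ml * ML / area
    nz = max(3 * resolution, 30)
    zf = np.linspace(0.0, height, nz + 1)
    dz = np.diff(zf)
    vol = area * dz
    centers = 0.5 * (zf[:-1] + zf[1:])
    idx = np.arange(nz)
    frac = np.zeros(nz)
    return Mesh(
        symmetry="planar1D",
        vol=vol,
        frac=frac,
        region=np.zeros(nz, dtype=np.int8),
        diff=_blend_diffusivities(scenario, frac),
        face_i=idx[:-1],
        face_j=idx[1:],
        face_area=np.full(nz - 1, area),
        face_di=dz[:-1] / 2,
        face_dj=dz[1:] / 2,
        top_cells=np.array([nz - 1]),
        top_area=np.array([area]),
        top_d=np.array([dz[-1] / 2]),
        centers_r_mm=np.zeros(nz),
        centers_z_mm=centers / MM,
        axis_cells=idx,
        base_cell=0,
        base_area_m2=area,
        expected_volume_m3=scenario.vessel.media_volume_ml * ML,
    )


def _row_wall_radii(scenario: CultureScenario, zf: np.ndarray) -> np.ndarray:
    """Effective wall radius per z-row, from the exact vessel slice volume
    (so summed cell volumes reproduce the vessel solid exactly)."""
    vessel = scenario.vessel
    if vessel.shape == "cylinder":
        return np.full(zf.size - 1, vessel.radius_mm * MM)
    r0 = vessel.cone_tip_radius_mm * MM
    s = vessel.cone_wall_slope
    r_at = r0 + s * zf
    # slice volume pi/(3s) (r(z1)^3 - r(z0)^3) => r_eff = sqrt(V / (pi dz))
    vslice = math.pi / (3.0 * s) * (r_at[1:] ** 3 - r_at[:-1] ** 3)
    return np.sqrt(vslice / (math.pi * np.diff(zf)))


def _build_axisymmetric(scenario: CultureScenario, resolution: int) -> Mesh:
    c = scenario.construct
    vessel = scenario.vessel
    total_ul = scenario.construct_count * c.construct_volume_ul
    fill = vessel.fill_height_mm(total_ul) * MM
    dx = c.smallest_dimension_mm * MM / resolution

    if c.kind == "cylinder":
        a, h = c.radius_mm * MM, c.height_mm * MM
        r_extent = vessel.radius_mm * MM
        if a >= r_extent or h >= fill:
            raise GeometryError("construct does not fit inside the vessel")
        rf = _axis_faces(a, r_extent, dx, dx_max=r_extent / 4)
        zf = _axis_faces(h, fill, dx, dx_max=fill / 8)
        zc = None
    else:
        a = c.sphere_radius_mm * MM
        r_extent = (
            vessel.radius_mm * MM
            if vessel.shape == "cylinder"
            else float(vessel.radius_at_mm(fill / MM)) * MM
        )
        fine_r = min(1.15 * a, r_extent)
        fine_z = min(2.16 * a, fill)
        rf = _axis_faces(fine_r, r_extent, dx, dx_max=max(r_extent / 4, 2 * dx))
        zf = _axis_faces(fine_z, fill, dx, dx_max=max(fill / 12, 2 * dx))
        zc = a  # sphere resting on the base (point contact)

    nr, nz = rf.size - 1, zf.size - 1
    dz = np.diff(zf)
    wall = _row_wall_radii(scenario, zf)

    # active cells and volumes (outer cell of each row truncated at the wall)
    index = -np.ones((nz, nr), dtype=int)
    vols, rc_list, zc_list = [], [], []
    outer_r = np.zeros((nz, nr))  # effective outer radius per active cell
    k = 0
    for iz in range(nz):
        zmid = 0.5 * (zf[iz] + zf[iz + 1])
        for ir in range(nr):
            r0 = rf[ir]
            if r0 >= wall[iz] - 1e-15:
                break
            r1 = min(rf[ir + 1], wall[iz])
            index[iz, ir] = k
            outer_r[iz, ir] = r1
            vols.append(math.pi * (r1**2 - r0**2) * dz[iz])
            rc_list.append(0.5 * (r0 + r1))
            zc_list.append(zmid)
            k += 1
    n = k
    vol = np.array(vols)
    centers_r = np.array(rc_list)
    centers_z = np.array(zc_list)

    # construct volume fraction
    if c.kind == "cylinder":
        frac2d = np.zeros((nz, nr))
        for iz in range(nz):
            zov = max(0.0, min(zf[iz + 1], c.height_mm * MM) - zf[iz])
            if zov <= 0:
                continue
            for ir in range(nr):
                if index[iz, ir] < 0:
                    continue
                r0, r1 = rf[ir], outer_r[iz, ir]
                rov = max(0.0, min(r1, a) ** 2 - r0**2)
                frac2d[iz, ir] = (rov / (r1**2 - r0**2)) * (zov / dz[iz])
        frac = frac2d[index >= 0]
    else:
        frac2d = _sphere_fraction(rf, zf, zc, a)
        frac = frac2d[index >= 0]
        frac = _normalise_fraction(frac, vol, c.construct_volume_ul * UL)

    # faces
    fi, fj, farea, fdi, fdj = [], [], [], [], []
    for iz in range(nz):
        for ir in range(nr - 1):
            ki, kj = index[iz, ir], index[iz, ir + 1]
            if ki < 0 or kj < 0:
                continue
            rface = rf[ir + 1]
            fi.append(ki)
            fj.append(kj)
            farea.append(2.0 * math.pi * rface * dz[iz])
            fdi.append(rface - centers_r[ki])
            fdj.append(centers_r[kj] - rface)
    for iz in range(nz - 1):
        for ir in range(nr):
            ki, kj = index[iz, ir], index[iz + 1, ir]
            if ki < 0 or kj < 0:
                continue
            r0 = rf[ir]
            r1 = min(outer_r[iz, ir], outer_r[iz + 1, ir])
            if r1 <= r0:
                continue
            fi.append(ki)
            fj.append(kj)
            farea.append(math.pi * (r1**2 - r0**2))
            fdi.append(dz[iz] / 2)
            fdj.append(dz[iz + 1] / 2)

    top_cells, top_area, top_d = [], [], []
    for ir in range(nr):
        ki = index[nz - 1, ir]
        if ki < 0:
            continue
        r0 = rf[ir]
        r1 = outer_r[nz - 1, ir]
        top_cells.append(ki)
        top_area.append(math.pi * (r1**2 - r0**2))
        top_d.append(dz[-1] / 2)

    axis_cells = np.array([index[iz, 0] for iz in range(nz) if index[iz, 0] >= 0])

    return Mesh(
        symmetry="axisymmetric2D",
        vol=vol,
        frac=frac,
        region=(frac >= 0.5).astype(np.int8),
        diff=_blend_diffusivities(scenario, frac),
        face_i=np.array(fi),
        face_j=np.array(fj),
        face_area=np.array(farea),
        face_di=np.array(fdi),
        face_dj=np.array(fdj),
        top_cells=np.array(top_cells),
        top_area=np.array(top_area),
        top_d=np.array(top_d),
        centers_r_mm=centers_r / MM,
        centers_z_mm=centers_z / MM,
        axis_cells=axis_cells,
        expected_volume_m3=scenario.vessel.media_volume_ml * ML + total_ul * UL,
    )


def build_spherical_mesh(
    radius_mm: float,
    diffusivities: Mapping[str, float],
    n: int = 40,
    outer_dirichlet: bool = True,
) -> Mesh:
    """An isolated sphere of radial shells (construct region throughout).

    With ``outer_dirichlet`` the surface concentration is held at the
    boundary value -- the configuration of the classical zero-order
    consumption closed form ``Delta C = q R^2 / (6 D)``.
    """
    a = radius_mm * MM
    rfaces = np.linspace(0.0, a, n + 1)
    vol = 4.0 / 3.0 * math.pi * (rfaces[1:] ** 3 - rfaces[:-1] ** 3)
    centers = 0.5 * (rfaces[:-1] + rfaces[1:])
    idx = np.arange(n)
    frac = np.ones(n)
    diff = {s: np.full(n, diffusivities[s]) for s in SOLUTES}
    rmid = rfaces[1:-1]
    mesh = Mesh(
        symmetry="spherical1D",
        vol=vol,
        frac=frac,
        region=np.ones(n, dtype=np.int8),
        diff=diff,
        face_i=idx[:-1],
        face_j=idx[1:],
        face_area=4.0 * math.pi * rmid**2,
        face_di=rmid - centers[:-1],
        face_dj=centers[1:] - rmid,
        top_cells=np.array([n - 1] if outer_dirichlet else [], dtype=int),
        top_area=np.array([4.0 * math.pi * a**2] if outer_dirichlet else []),
        top_d=np.array([a - centers[-1]] if outer_dirichlet else []),
        centers_r_mm=centers / MM,
        centers_z_mm=np.zeros(n),
        axis_cells=idx,
        expected_volume_m3=4.0 / 3.0 * math.pi * a**3,
    )
    return mesh


def build_slab_mesh(
    height_mm: float,
    area_cm2: float,
    diffusivities: Mapping[str, float],
    construct_height_mm: float = 0.0,
    n: int = 80,
) -> Mesh:
    """A 1D vertical slab with an optional construct layer at its base.

    Used for closed-form verification: a uniform zero-order sink of
    strength ``q`` in the bottom layer of thickness ``h`` under a media
    column of height ``L - h`` gives a base-to-surface deficit
    ``q h^2 / (2 D_c) + q h (L - h) / D_m``; a pure boundary flux ``j``
    gives the classical surface deficit ``j L / D``.
    """
    area = area_cm2 * 1e-4
    height = height_mm * MM
    zf = np.linspace(0.0, height, n + 1)
    dz = np.diff(zf)
    centers = 0.5 * (zf[:-1] + zf[1:])
    frac = (centers < construct_height_mm * MM).astype(float)
    idx = np.arange(n)
    return Mesh(
        symmetry="planar1D",
        vol=area * dz,
        frac=frac,
        region=frac.astype(np.int8),
        diff={s: np.full(n, diffusivities[s]) for s in SOLUTES},
        face_i=idx[:-1],
        face_j=idx[1:],
        face_area=np.full(n - 1, area),
        face_di=dz[:-1] / 2,
        face_dj=dz[1:] / 2,
        top_cells=np.array([n - 1]),
        top_area=np.array([area]),
        top_d=np.array([dz[-1] / 2]),
        centers_r_mm=np.zeros(n),
        centers_z_mm=centers / MM,
        axis_cells=idx,
        base_cell=0,
        base_area_m2=area,
        expected_volume_m3=area * height,
    )


def build_compartment_mesh(scenario: CultureScenario, resolution: int = 40) -> Mesh:
    """Reduced-order multi-bead mesh: one representative bead of radial
    shells coupled to a well-mixed media compartment through a stagnant
    boundary-layer film (Sherwood number 2, i.e. film coefficient D/R),
    with the media compartment exchanging oxygen with the incubator
    through half the media column.

    All beads being identical, the media volume and free-surface area are
    divided by the bead count so the mesh describes one bead's share.
    """
    c = scenario.construct
    if c is None or c.kind not in ("bead", "pellet"):
        raise GeometryError("compartment meshes require a spherical construct")
    count = scenario.construct_count
    a = c.sphere_radius_mm * MM
    n = max(resolution, 8)
    base = build_spherical_mesh(
        c.sphere_radius_mm, c.diffusivities, n=n, outer_dirichlet=False
    )
    v_media = scenario.vessel.media_volume_ml * ML / count
    fill = scenario.vessel.fill_height_mm(count * c.construct_volume_ul) * MM
    a_surface = scenario.vessel.base_area_cm2 * 1e-4 / count

    vol = np.append(base.vol, v_media)
    frac = np.append(base.frac, 0.0)
    diff = {
        s: np.append(base.diff[s], scenario.media_diffusivities[s]) for s in SOLUTES
    }
    centers_shell = base.centers_r_mm
    dr_half = a - centers_shell[-1] * MM
    # bead surface <-> media film: half-shell resistance in series with D/R film
    face_i = np.append(base.face_i, n - 1)
    face_j = np.append(base.face_j, n)
    face_area = np.append(base.face_area, 4.0 * math.pi * a**2)
    face_di = np.append(base.face_di, dr_half)
    face_dj = np.append(base.face_dj, a)
    return Mesh(
        symmetry="spherical1D",
        vol=vol,
        frac=frac,
        region=np.append(np.ones(n, dtype=np.int8), 0),
        diff=diff,
        face_i=face_i,
        face_j=face_j,
        face_area=face_area,
        face_di=face_di,
        face_dj=face_dj,
        top_cells=np.array([n]),
        top_area=np.array([a_surface]),
        top_d=np.array([fill / 2]),
        centers_r_mm=np.append(centers_shell, c.sphere_radius_mm * 1.5),
        centers_z_mm=np.zeros(n + 1),
        axis_cells=np.arange(n),
        expected_volume_m3=float(base.vol.sum()) + v_media,
    )
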