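"""Scoring geometries: water spheres, the 14-um cell, 19-cell clusters, multi-cluster.

All geometries live in Cartesian um coordinates with the origin at the model
centre. Cells are concentric spheres: a 10-um nucleus, cytoplasm, and a 10-nm
membrane shell closed on its outer radius (a point exactly at r = 7 um is
membrane; a point on the nucleus boundary is nucleus). Medium is water at
1 g/cm^3 everywhere, including between cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import WATER_DENSITY_KG_M3

__all__ = [
    "SphereModel",
    "CellModel",
    "ClusterModel",
    "MultiClusterModel",
    "Compartment",
    "COMPARTMENTS",
    "classify",
    "sample_source",
    "compartment_mass",
    "build_cluster",
    "build_multicluster",
    "DEFAULT_UNLABELED_CELLS",
]

COMPARTMENTS = ("nucleus", "cytoplasm", "membrane")

CELL_RADIUS_UM = 7.0
MEMBRANE_THICKNESS_UM = 0.010
NUCLEUS_RADIUS_UM = 5.0

# default heterogeneity mask: 4 of 19 cells unlabeled
# (one first-ring cell and three spread-out second-ring cells - an assumption,
#  the published cluster figure does not identify them)
DEFAULT_UNLABELED_CELLS = (1, 8, 12, 16)


def _sphere_volume_um3(r: float) -> float:
    return 4.0 / 3.0 * np.pi * r**3


@dataclass(frozen=True)
class SphereModel:
    """Uniform water sphere, diameter in um."""

    diameter: float

    def __post_init__(self):
        if not 1.0 <= self.diameter <= 1000.0:
            raise ValueError("sphere diameter must be within 1-1000 um")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def volume_um3(self) -> float:
        return np.pi * self.diameter**3 / 6.0

    @property
    def mass_kg(self) -> float:
        return self.volume_um3 * 1e-18 * WATER_DENSITY_KG_M3


@dataclass(frozen=True)
class CellModel:
    """One 14-um cell: 10-um centred nucleus and a 10-nm membrane shell."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cell_radius: float = CELL_RADIUS_UM
    membrane_thickness: float = MEMBRANE_THICKNESS_UM
    nucleus_radius: float = NUCLEUS_RADIUS_UM

    @property
    def inner_membrane_radius(self) -> float:
        return self.cell_radius - self.membrane_thickness

    @property
    def volume_um3(self) -> float:
        return _sphere_volume_um3(self.cell_radius)

    def compartment_volume_um3(self, compartment: str) -> float:
        if compartment == "nucleus":
            return _sphere_volume_um3(self.nucleus_radius)
        if compartment == "membrane":
            return _sphere_volume_um3(self.cell_radius) - _sphere_volume_um3(self.inner_membrane_radius)
        if compartment == "cytoplasm":
            return _sphere_volume_um3(self.inner_membrane_radius) - _sphere_volume_um3(self.nucleus_radius)
        if compartment == "cell":
            return self.volume_um3
        raise ValueError(f"unknown compartment {compartment!r}")


@dataclass
class ClusterModel:
    """19 touching cells: 1 central, 6 first neighbours, 12 second neighbours."""

    cells: list[CellModel]
    rings: np.ndarray          # 0 central, 1 first ring, 2 second ring
    labeling_mask: np.ndarray  # bool per cell

    def __post_init__(self):
        counts = np.bincount(self.rings, minlength=3)
        if list(counts[:3]) != [1, 6, 12]:
            raise ValueError(f"ring sizes must be 1/6/12, got {list(counts)}")
        _check_no_overlap(self.centers())

    def centers(self) -> np.ndarray:
        return np.array([c.center for c in self.cells])


@dataclass
class MultiClusterModel:
    """Seven 19-cell clusters in a planar flower; one cluster unlabeled."""

    clusters: list[ClusterModel]
    labeled_clusters: np.ndarray  # bool per cluster

    def all_cells(self) -> list[CellModel]:
        return [c for cl in self.clusters for c in cl.cells]

    def centers(self) -> np.ndarray:
        return np.concatenate([cl.centers() for cl in self.clusters])

    def central_cell_centers(self) -> np.ndarray:
        return np.array([cl.cells[0].center for cl in self.clusters])


@dataclass(frozen=True)
class Compartment:
    kind: str  # nucleus / cytoplasm / membrane / outside
    cell_index: int | None = None


def _check_no_overlap(centers: np.ndarray, min_spacing: float = 2 * CELL_RADIUS_UM) -> None:
    n = len(centers)
    if n < 2:
        return
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    d[np.diag_indices(n)] = np.inf
    if d.min() < min_spacing - 1e-9:
        raise ValueError(f"cells overlap: min centre distance {d.min():.3f} < {min_spacing} um")


def _cells_of(model) -> list[CellModel]:
    if isinstance(model, CellModel):
        return [model]
    if isinstance(model, ClusterModel):
        return model.cells
    if isinstance(model, MultiClusterModel):
        return model.all_cells()
    raise TypeError(f"no cells in {type(model).__name__}")


def classify(point, model) -> Compartment:
    """Deterministic compartment lookup; the partition covers all of space."""
    p = np.asarray(point, dtype=float)
    if isinstance(model, SphereModel):
        if np.dot(p, p) <= model.radius**2:
            return Compartment("inside", 0)
        return Compartment("outside", None)
    for i, cell in enumerate(_cells_of(model)):
        d2 = float(np.sum((p - np.asarray(cell.center)) ** 2))
        if d2 > cell.cell_radius**2:
            continue
        if d2 <= cell.nucleus_radius**2:
            return Compartment("nucleus", i)
        if d2 < cell.inner_membrane_radius**2:
            return Compartment("cytoplasm", i)
        return Compartment("membrane", i)
    return Compartment("outside", None)


def _uniform_in_shell(rng, n, r_in, r_out):
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = (r_in**3 + rng.random(n) * (r_out**3 - r_in**3)) ** (1.0 / 3.0)
    return u * r[:, None]


def sample_source(model, distribution: str, rng: np.random.Generator,
                  n: int = 1, labeling_mask=None, cell_index: int | None = None):
    """Sample source positions for a radionuclide distribution.

    distribution: "cell_surface" (uniform on the outer membrane sphere,
    r = 7 um exactly), "cytoplasm" (uniform in the cytoplasmic shell),
    "nucleus" (uniform in the nuclear volume), or "uniform_sphere"
    (SphereModel only). Returns ``(positions (n,3), cell_indices (n,))``.
    Labeled cells are chosen with equal weight unless ``cell_index`` pins one.
    """
    if isinstance(model, SphereModel):
        if distribution != "uniform_sphere":
            raise ValueError("spheres only support the uniform_sphere distribution")
        pos = _uniform_in_shell(rng, n, 0.0, model.radius)
        return pos, np.zeros(n, dtype=int)
    if distribution == "uniform_sphere":
        raise ValueError("uniform_sphere applies to SphereModel only")
    cells = _cells_of(model)
    if cell_index is not None:
        idx = np.full(n, cell_index, dtype=int)
    else:
        if labeling_mask is None:
            labeling_mask = getattr(model, "labeling_mask", np.ones(len(cells), bool))
        labeled = np.flatnonzero(np.asarray(labeling_mask, bool))
        if len(labeled) == 0:
            raise ValueError("labeling mask selects no cells")
        idx = labeled[rng.integers(0, len(labeled), n)]
    centers = np.array([cells[i].center for i in idx])
    c0 = cells[0]
    if distribution == "cell_surface":
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        local = u * c0.cell_radius
    elif distribution == "cytoplasm":
        local = _uniform_in_shell(rng, n, c0.nucleus_radius, c0.inner_membrane_radius)
    elif distribution == "nucleus":
        local = _uniform_in_shell(rng, n, 0.0, c0.nucleus_radius)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return centers + local, idx


def compartment_mass(model, compartment: str) -> float:
    """Mass in kg of one compartment (water, 1 g/cm^3)."""
    if isinstance(model, SphereModel):
        if compartment not in ("inside", "sphere"):
            raise ValueError("sphere has a single compartment")
        return model.mass_kg
    cell = _cells_of(model)[0]
    return cell.compartment_volume_um3(compartment) * 1e-18 * WATER_DENSITY_KG_M3


def build_cluster(spacing: float = 14.0, labeling_mask=None) -> ClusterModel:
    """Planar hexagonal 19-cell cluster.

    First ring: 6 cells at centre distance ``spacing``; second ring: the 12
    cells at distances spacing*sqrt(3) and 2*spacing of the hexagonal lattice.
    """
    if spacing < 2 * CELL_RADIUS_UM:
        raise ValueError("spacing below 14 um would overlap cells")
    centers = [(0.0, 0.0, 0.0)]
    rings = [0]
    for k in range(6):
        a = np.pi / 3 * k
        centers.append((spacing * np.cos(a), spacing * np.sin(a), 0.0))
        rings.append(1)
    for k in range(6):
        a = np.pi / 3 * k
        centers.append((2 * spacing * np.cos(a), 2 * spacing * np.sin(a), 0.0))
        rings.append(2)
    for k in range(6):
        a = np.pi / 3 * k + np.pi / 6
        d = spacing * np.sqrt(3.0)
        centers.append((d * np.cos(a), d * np.sin(a), 0.0))
        rings.append(2)
    if labeling_mask is None:
        labeling_mask = np.ones(19, bool)
    labeling_mask = np.asarray(labeling_mask, bool)
    if labeling_mask.shape != (19,):
        raise ValueError("labeling mask must have 19 entries")
    cells = [CellModel(center=c) for c in centers]
    return ClusterModel(cells=cells, rings=np.array(rings), labeling_mask=labeling_mask)


def heterogeneous_mask(unlabeled=DEFAULT_UNLABELED_CELLS) -> np.ndarray:
    mask = np.ones(19, bool)
    mask[list(unlabeled)] = False
    return mask


def build_multicluster(spacing: float = 14.0, cluster_spacing: float = 70.0,
                       unlabeled_cluster: int = 1) -> MultiClusterModel:
    """Seven-cluster flower: central cluster plus six at ``cluster_spacing``.

    The default spacing makes the 35-um bounding spheres of adjacent clusters
    touch, so the nearest labeled cell surface lies 35 um from the unlabeled
    cluster's central-cell nucleus - beyond the >= 28 um separation the model
    requires.
    """
    clusters = []
    offsets = [(0.0, 0.0)] + [
        (cluster_spacing * np.cos(-np.pi / 2 + np.pi / 3 * k),
         cluster_spacing * np.sin(-np.pi / 2 + np.pi / 3 * k))
        for k in range(6)
    ]
    for ox, oy in offsets:
        base = build_cluster(spacing=spacing)
        cells = [CellModel(center=(c.center[0] + ox, c.center[1] + oy, c.center[2]))
                 for c in base.cells]
        clusters.append(ClusterModel(cells=cells, rings=base.rings,
                                     labeling_mask=np.ones(19, bool)))
    labeled = np.ones(7, bool)
    labeled[unlabeled_cluster] = False
    for i, cl in enumerate(clusters):
        cl.labeling_mask = np.full(19, labeled[i])
    model = MultiClusterModel(clusters=clusters, labeled_clusters=labeled)
    _check_no_overlap(model.centers())
    # separation constraint: unlabeled central-cell nucleus vs nearest labeled cell
    target = np.asarray(clusters[unlabeled_cluster].cells[0].center)
    labeled_centers = np.concatenate([cl.centers() for i, cl in enumerate(clusters) if labeled[i]])
    gap = np.linalg.norm(labeled_centers - target, axis=1).min() - CELL_RADIUS_UM
    if gap < 28.0 - 1e-9:
        raise ValueError(f"multi-cluster layout violates the 28 um separation (got {gap:.1f})")
    return model


def geometry_dump(model) -> dict:
    """JSON-serialisable description (cell centres, radii, rings) for plots/checks."""
    if isinstance(model, SphereModel):
        return dict(kind="sphere", diameter_um=model.diameter)
    if isinstance(model, CellModel):
        return dict(kind="cell", center=list(model.center), cell_radius=model.cell_radius,
                    nucleus_radius=model.nucleus_radius,
                    membrane_thickness=model.membrane_thickness)
    if isinstance(model, ClusterModel):
        return dict(kind="cluster", centers=model.centers().tolist(),
                    rings=model.rings.tolist(), labeled=model.labeling_mask.tolist())
    if isinstance(model, MultiClusterModel):
        return dict(kind="multicluster",
                    clusters=[geometry_dump(c) for c in model.clusters],
                    labeled_clusters=model.labeled_clusters.tolist())
    raise TypeError(type(model).__name__)
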