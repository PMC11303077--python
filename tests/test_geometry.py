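import numpy as np
import pytest
from hypothesis import assume, given, strategies as st

import augerdose as ad
from augerdose.geometry import (
    COMPARTMENTS,
    CellModel,
    SphereModel,
    build_cluster,
    build_multicluster,
    classify,
    compartment_mass,
    heterogeneous_mask,
    sample_source,
)


def test_sphere_mass_oracle():
    s = SphereModel(10.0)
    assert s.mass_kg == pytest.approx(4 / 3 * np.pi * 125e-18 * 1000.0, rel=1e-12)
    with pytest.raises(ValueError, match="diameter"):
        SphereModel(0.5)


def test_compartment_masses_exact():
    cell = CellModel()
    m_cell = 4 / 3 * np.pi * 7.0**3 * 1e-15
    m_nuc = 4 / 3 * np.pi * 5.0**3 * 1e-15
    m_mem = 4 / 3 * np.pi * (7.0**3 - 6.99**3) * 1e-15
    assert compartment_mass(cell, "cell") == pytest.approx(m_cell, rel=1e-12)
    assert compartment_mass(cell, "nucleus") == pytest.approx(m_nuc, rel=1e-12)
    assert compartment_mass(cell, "membrane") == pytest.approx(m_mem, rel=1e-12)
    assert compartment_mass(cell, "nucleus") == pytest.approx(5.236e-13, rel=1e-3)
    assert compartment_mass(cell, "membrane") == pytest.approx(6.148e-15, rel=1e-3)
    # compartments partition the cell volume
    total = sum(cell.compartment_volume_um3(c) for c in COMPARTMENTS)
    assert total == pytest.approx(cell.volume_um3, rel=1e-12)


@given(st.floats(0, 8), st.floats(0, 2 * np.pi), st.floats(-1, 1))
def test_classify_partitions_space(r, phi, mu):
    cell = CellModel()
    s = np.sqrt(1 - mu * mu)
    p = r * np.array([s * np.cos(phi), s * np.sin(phi), mu])
    comp = classify(p, cell)
    d = np.linalg.norm(p)
    # exact boundaries are rounding-sensitive (covered by test_boundary_conventions)
    assume(min(abs(d - 5.0), abs(d - 6.99), abs(d - 7.0)) > 1e-9)
    if d > 7.0:
        assert comp.kind == "outside"
    elif d <= 5.0:
        assert comp.kind == "nucleus"
    elif d < 6.99:
        assert comp.kind == "cytoplasm"
    else:
        assert comp.kind == "membrane"


def test_boundary_conventions():
    cell = CellModel()
    assert classify((5.0, 0, 0), cell).kind == "nucleus"
    assert classify((7.0, 0, 0), cell).kind == "membrane"
    assert classify((6.99, 0, 0), cell).kind == "membrane"
    assert classify((7.0 + 1e-9, 0, 0), cell).kind == "outside"


def test_cluster_layout():
    cl = build_cluster()
    c = cl.centers()
    d0 = np.linalg.norm(c[1:], axis=1)
    assert np.allclose(np.sort(d0), [14] * 6 + [14 * np.sqrt(3)] * 6 + [28] * 6)
    assert list(np.bincount(cl.rings)) == [1, 6, 12]
    # touching but never overlapping
    dm = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
    dm[np.diag_indices(19)] = np.inf
    assert dm.min() == pytest.approx(14.0)
    with pytest.raises(ValueError, match="overlap"):
        build_cluster(spacing=13.0)
    with pytest.raises(ValueError, match="19"):
        build_cluster(labeling_mask=[True] * 5)


def test_multicluster_separation():
    m = build_multicluster()
    assert len(m.clusters) == 7
    assert m.labeled_clusters.sum() == 6
    target = np.asarray(m.clusters[1].cells[0].center)
    labeled = np.concatenate([cl.centers() for i, cl in enumerate(m.clusters)
                              if m.labeled_clusters[i]])
    gap = np.linalg.norm(labeled - target, axis=1).min() - 7.0
    assert gap >= 28.0


def test_surface_source_exact_radius():
    cell = CellModel()
    pos, idx = sample_source(cell, "cell_surface", np.random.default_rng(0), 500)
    assert np.allclose(np.linalg.norm(pos, axis=1), 7.0, atol=1e-12)


def test_nucleus_source_radial_moment():
    # uniform ball: E[r^3] = R^3/2
    cell = CellModel()
    pos, _ = sample_source(cell, "nucleus", np.random.default_rng(1), 40000)
    r3 = (np.linalg.norm(pos, axis=1) ** 3).mean()
    assert r3 == pytest.approx(5.0**3 / 2, rel=0.02)


def test_cytoplasm_source_inside_shell():
    cell = CellModel()
    pos, _ = sample_source(cell, "cytoplasm", np.random.default_rng(2), 2000)
    r = np.linalg.norm(pos, axis=1)
    assert r.min() >= 5.0 and r.max() <= 6.99


def test_source_respects_labeling_mask():
    cl = build_cluster(labeling_mask=heterogeneous_mask())
    pos, idx = sample_source(cl, "cell_surface", np.random.default_rng(3), 3000)
    assert set(np.unique(idx)).isdisjoint({1, 8, 12, 16})
    with pytest.raises(ValueError, match="no cells"):
        sample_source(cl, "cell_surface", np.random.default_rng(4), 5,
                      labeling_mask=np.zeros(19, bool))


def test_uniform_sphere_only_on_spheres():
    with pytest.raises(ValueError, match="uniform_sphere"):
        sample_source(CellModel(), "uniform_sphere", np.random.default_rng(5), 1)
    with pytest.raises(ValueError, match="uniform_sphere"):
        sample_source(SphereModel(10.0), "nucleus", np.random.default_rng(6), 1)


def test_source_isotropy_chi2():
    # octant counts of surface-sampled points are uniform (chi-square, alpha=0.01)
    pos, _ = sample_source(CellModel(), "cell_surface", np.random.default_rng(7), 8000)
    octant = (pos[:, 0] > 0) * 4 + (pos[:, 1] > 0) * 2 + (pos[:, 2] > 0)
    counts = np.bincount(octant, minlength=8)
    chi2 = ((counts - 1000.0) ** 2 / 1000.0).sum()
    assert chi2 < 18.48  # chi2(7 dof, 0.99)
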