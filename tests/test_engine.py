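import numpy as np
import pytest

import augerdose as ad
from augerdose.constants import KEV_TO_J
from augerdose.engine import (
    FULL_ABSORPTION_GY,
    NormalizationRule,
    ScenarioConfig,
    category_contribution,
    rh_standalone_rescale,
    run_scenario,
    s_value,
    self_cross_split,
)
from augerdose.geometry import build_cluster, compartment_mass, CellModel


def test_normalization_decay_density(series_scheme):
    rule = NormalizationRule()
    assert rule.decays_per_um3(series_scheme) == pytest.approx(1000 / 43.51, rel=1e-6)
    with pytest.raises(ValueError, match="mode"):
        NormalizationRule(mode="per_bq")


def test_full_absorption_constant():
    assert FULL_ABSORPTION_GY == pytest.approx(160.2, rel=1e-3)


def test_config_validation_errors():
    with pytest.raises(ValueError, match="diameter"):
        ScenarioConfig("Pd103", "sphere", "uniform_sphere", 10).validate()
    with pytest.raises(ValueError, match="uniform_sphere"):
        ScenarioConfig("Pd103", "sphere", "nucleus", 10, diameter=10.0).validate()
    with pytest.raises(ValueError, match="cellular"):
        ScenarioConfig("Pd103", "cell", "uniform_sphere", 10).validate()
    with pytest.raises(ValueError, match="geometry"):
        ScenarioConfig("Pd103", "slab", "nucleus", 10).validate()
    with pytest.raises(ValueError, match="nuclide"):
        ScenarioConfig("Xx999", "cell", "nucleus", 10).validate()
    with pytest.raises(ValueError, match="mask"):
        ScenarioConfig("Pd103", "cluster", "nucleus", 10, labeling_mask=[True]).validate()


def test_energy_conservation_and_determinism(cluster_tally):
    assert cluster_tally.deposited_ev == pytest.approx(cluster_tally.released_ev, rel=1e-12)
    again = run_scenario(cluster_tally.meta["config"])
    assert np.array_equal(cluster_tally.energy_ev, again.energy_ev)


def test_parts_and_categories_sum_exactly(cluster_tally):
    whole = cluster_tally.dose(0, "nucleus")
    parts = (cluster_tally.dose(0, "nucleus", part="Pd103")
             + cluster_tally.dose(0, "nucleus", part="Rh103m"))
    cats = sum(cluster_tally.dose(0, "nucleus", category=c) for c in ("AE", "CE", "beta"))
    assert parts == pytest.approx(whole, rel=1e-12)
    assert cats == pytest.approx(whole, rel=1e-12)


def test_additivity_over_source_cells():
    base = dict(nuclide="Pd103_series", geometry="cluster", distribution="nucleus",
                histories=30, seed=17)
    full = run_scenario(ScenarioConfig(**base))
    acc = np.zeros_like(full.energy_ev)
    for c in range(19):
        single = run_scenario(ScenarioConfig(**base, labeling_mask=[i == c for i in range(19)]))
        acc += single.energy_ev
    assert np.array_equal(full.energy_ev, acc)


def test_ring_symmetry(cluster_tally):
    # cells are equivalent only within a symmetry class: same ring AND same
    # distance from the centre (the outer ring mixes 14*sqrt(3) and 28 um cells)
    rings = cluster_tally.meta["rings"]
    dist = np.round(np.linalg.norm(build_cluster().centers(), axis=1), 3)
    for ring in (1, 2):
        for d in np.unique(dist[rings == ring]):
            cells = np.flatnonzero((rings == ring) & (dist == d))
            doses = np.array([cluster_tally.dose(c, "nucleus") for c in cells])
            errs = np.array([cluster_tally.stderr(c, "nucleus") for c in cells])
            mean = doses.mean()
            assert np.all(np.abs(doses - mean) <= 4.0 * np.maximum(errs, 1e-12))


def test_sphere_dose_monotone_with_size():
    doses = []
    for d in (10.0, 50.0, 500.0):
        t = run_scenario(ScenarioConfig("Pd103_series", "sphere", "uniform_sphere",
                                        2000, seed=18, diameter=d))
        dose = t.dose(0, "inside")
        doses.append(dose)
        assert dose <= FULL_ABSORPTION_GY * (1 + 3 * t.stderr(0, "inside") / dose)
    assert doses[0] < doses[1] < doses[2]


def test_degenerate_s_value_oracle(tmp_path):
    """Fully absorbed single-line scheme: per-decay cell dose equals E/m exactly."""
    path = tmp_path / "mono.tsv"
    path.write_text(
        "energy_keV\tyield_per_decay\tcategory\tnuclide_part\tendpoint_keV\n"
        "0.119\t1\tAE\tPd103\t\n"
    )
    cfg = ScenarioConfig("Pd103", "cell", "nucleus", 400, seed=19,
                         normalization=NormalizationRule("per_decay"),
                         sampling="expected", spectrum_file=str(path))
    t = run_scenario(cfg)
    assert float(t.unscored_ev.sum()) == 0.0  # nothing leaves the cell
    cell = CellModel()
    total = sum(s_value(t, 0, c) * compartment_mass(cell, c)
                for c in ("nucleus", "cytoplasm", "membrane"))
    assert total == pytest.approx(0.119 * KEV_TO_J, rel=1e-12)


def test_s_value_requires_per_decay(sphere_tally_10):
    with pytest.raises(ValueError, match="per_decay"):
        s_value(sphere_tally_10, 0, "inside")


def test_self_cross_split(cluster_tally):
    self_f, cross_f = self_cross_split(cluster_tally, 0)
    assert self_f + cross_f == pytest.approx(1.0)
    assert 0 < self_f < 1
    single = run_scenario(ScenarioConfig("Pd103_series", "cell", "cell_surface", 50, seed=20))
    assert self_cross_split(single, 0) == (1.0, 0.0)


def test_category_contributions(cluster_tally):
    total = sum(category_contribution(cluster_tally, 0, c) for c in ("AE", "CE", "beta"))
    assert total == pytest.approx(1.0, rel=1e-12)
    with pytest.raises(ValueError, match="category"):
        category_contribution(cluster_tally, 0, "gamma")


def test_rh_rescale(cluster_tally):
    factor = 43.51 / 37.69
    rescaled = rh_standalone_rescale(cluster_tally, 0, "nucleus")
    assert rescaled == pytest.approx(
        cluster_tally.dose(0, "nucleus", part="Rh103m") * factor, rel=0.01
    )
    lu = run_scenario(ScenarioConfig("Lu177", "cell", "nucleus", 20, seed=21))
    with pytest.raises(ValueError, match="Pd103_series"):
        rh_standalone_rescale(lu)


def test_retention_bounded(sphere_tally_10):
    assert 0 < sphere_tally_10.retention_fraction() < 1


def test_to_frame_schema(cluster_tally):
    df = cluster_tally.to_frame()
    assert len(df) == 19 * 3
    for col in ("geometry", "nuclide", "compartment", "dose_Gy", "stderr_Gy",
                "AE_fraction", "CE_fraction", "beta_fraction"):
        assert col in df.columns
    total = df[df.compartment == "nucleus"].dose_Gy
    assert (total > 0).all()


def test_yaml_round_trip(tmp_path):
    cfg = ScenarioConfig("Tb161", "cluster", "cytoplasm", 123, seed=9,
                         labeling_mask=[bool(i % 2) for i in range(19)],
                         normalization=NormalizationRule("per_decay"),
                         transport=ad.TransportSettings(step_fraction=0.03))
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    assert ScenarioConfig.from_yaml(path) == cfg
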