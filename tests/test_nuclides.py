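import numpy as np
import pytest
from hypothesis import given, strategies as st

import augerdose as ad
from augerdose.nuclides import (
    BetaContinuum,
    EmissionLine,
    load_spectrum_tsv,
    sample_decays,
    save_spectrum_tsv,
    validate_scheme,
    weighted_average_energy,
)


@pytest.mark.parametrize("name", ad.SUPPORTED_NUCLIDES)
def test_all_builtin_schemes_validate(name):
    report = validate_scheme(ad.build_scheme(name))
    assert report["passed"], report


def test_unknown_nuclide_lists_supported():
    with pytest.raises(ValueError, match="Pd103_series"):
        ad.build_scheme("Tc99m")


def test_series_composition(series_scheme):
    pd = ad.build_scheme("Pd103")
    rh = ad.build_scheme("Rh103m")
    assert series_scheme.computed_energy_per_decay() == pytest.approx(
        pd.computed_energy_per_decay() + rh.computed_energy_per_decay()
    )
    # per-decay aggregates of the combined scheme
    assert series_scheme.computed_energy_per_decay() == pytest.approx(43.51, rel=0.01)
    assert series_scheme.line_energy_per_decay("AE") == pytest.approx(8.54, rel=0.01)
    assert series_scheme.line_energy_per_decay("CE") == pytest.approx(34.97, rel=0.01)
    assert series_scheme.line_count("AE") == pytest.approx(13.3, rel=0.02)


def test_ce_weighted_mean(series_scheme):
    ce = [ln for ln in series_scheme.lines if ln.category == "CE"]
    assert weighted_average_energy(ce) == pytest.approx(35.0, rel=0.01)


def test_weighted_average_empty_raises():
    with pytest.raises(ValueError, match="empty"):
        weighted_average_energy([])


@given(e=st.floats(-10, 0))
def test_line_rejects_nonpositive_energy(e):
    with pytest.raises(ValueError):
        EmissionLine(e, 0.5, "AE")


def test_line_rejects_bad_category():
    with pytest.raises(ValueError, match="AE or CE"):
        EmissionLine(1.0, 1.0, "beta")


def test_beta_requires_mean_below_endpoint():
    with pytest.raises(ValueError):
        BetaContinuum(mean_energy=200.0, endpoint_energy=100.0, yield_=1.0)


@pytest.mark.parametrize("name,mean", [("Lu177", 133.3), ("Tb161", 154.3)])
def test_beta_continuum_mean(name, mean):
    scheme = ad.build_scheme(name)
    (b,) = scheme.betas
    e, pdf = b.shape(8000)
    assert np.trapezoid(pdf * e, e) / np.trapezoid(pdf, e) == pytest.approx(mean, rel=0.005)


def test_beta_sampling_mean_matches(series_scheme):
    scheme = ad.build_scheme("Lu177")
    rng = np.random.default_rng(1)
    e, cat, part, decay, wt = sample_decays(scheme, 20000, rng)
    beta = e[cat == 2]
    assert beta.mean() == pytest.approx(133.3, rel=0.02)
    assert beta.max() <= scheme.betas[0].endpoint_energy


def test_expected_sampling_is_variance_free(series_scheme):
    rng = np.random.default_rng(2)
    e, cat, part, decay, wt = sample_decays(series_scheme, 7, rng, mode="expected")
    # every line appears exactly once per decay, weighted by its yield
    per_decay = (e * wt)[decay == 3].sum()
    assert per_decay == pytest.approx(series_scheme.computed_energy_per_decay(), rel=1e-12)


def test_poisson_sampling_energy_unbiased(series_scheme):
    rng = np.random.default_rng(3)
    n = 20000
    e, cat, part, decay, wt = sample_decays(series_scheme, n, rng)
    assert (e * wt).sum() / n == pytest.approx(series_scheme.computed_energy_per_decay(), rel=0.02)
    assert np.all(np.diff(decay) >= 0)  # grouped by decay


def test_sample_decays_bad_mode(series_scheme):
    with pytest.raises(ValueError, match="mode"):
        sample_decays(series_scheme, 1, np.random.default_rng(0), mode="exact")


def test_parts_tagged(series_scheme):
    rng = np.random.default_rng(4)
    e, cat, part, decay, wt = sample_decays(series_scheme, 2000, rng)
    for p, ref in ((0, 5.82), (1, 37.69)):
        assert (e[part == p] * wt[part == p]).sum() / 2000 == pytest.approx(ref, rel=0.05)


def test_tsv_round_trip(tmp_path, series_scheme):
    scheme = ad.build_scheme("Tb161")
    path = tmp_path / "tb.tsv"
    save_spectrum_tsv(scheme, path)
    lines, betas = load_spectrum_tsv(path)
    assert len(lines) == len(scheme.lines)
    assert len(betas) == len(scheme.betas)
    reloaded = ad.build_scheme("Tb161", spectrum_file=path)
    assert reloaded.computed_energy_per_decay() == pytest.approx(
        scheme.computed_energy_per_decay(), rel=1e-6
    )


def test_sample_decay_objects(series_scheme):
    emissions = ad.sample_decay(series_scheme, np.random.default_rng(5), mode="expected")
    assert {em.category for em in emissions} <= {"AE", "CE", "beta"}
    assert {em.nuclide_part for em in emissions} == {"Pd103", "Rh103m"}
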