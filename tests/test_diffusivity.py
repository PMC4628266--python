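import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from parenchyma3d.diffusivity import (
    GasConstants,
    cellular_diffusivity,
    combined_model,
    estimate_w,
    maxwell_eucken_serial,
    parallel_model,
)

# porosity, void shape factor (tortuosity proxy), measured D (m2/s), Table-1 style
GENOTYPES = {
    "Braeburn": (0.184, 2.032, 1.73e-9),
    "Kanzi": (0.121, 2.12, 2.73e-9),
    "Jonagold": (0.254, 2.29, 10.1e-9),
    "Conference": (0.057, 1.94, 0.28e-9),
}


def test_cellular_diffusivity_default_constants():
    assert cellular_diffusivity() == pytest.approx(9.3e-11, rel=0.01)


def test_cellular_diffusivity_linear_in_temperature():
    c2 = GasConstants(T=2 * 298.15)
    assert cellular_diffusivity(c2) == pytest.approx(2 * cellular_diffusivity())


def test_cellular_diffusivity_zero_water_limit():
    assert cellular_diffusivity(GasConstants(D_water=0.0)) == 0.0


@pytest.mark.parametrize(
    "eps,expected",
    [(0.057, 1.1e-10), (0.121, 1.3e-10), (0.184, 1.6e-10), (0.254, 1.9e-10)],
)
def test_maxwell_eucken_printed_values(eps, expected):
    assert maxwell_eucken_serial(eps) == pytest.approx(expected, rel=0.05)


def test_maxwell_eucken_zero_porosity_is_cellular():
    assert maxwell_eucken_serial(0.0) == pytest.approx(cellular_diffusivity())


def test_maxwell_eucken_full_porosity_invalid():
    with pytest.raises(ValueError):
        maxwell_eucken_serial(1.0)


def test_parallel_model_limits():
    assert parallel_model(0.0, 2.0) == 0.0
    assert parallel_model(0.3, 1.0) == pytest.approx(0.3 * 2.15e-5)
    with pytest.warns(UserWarning):
        parallel_model(0.3, 0.5)


def test_parallel_model_genotype_values():
    assert parallel_model(0.254, 2.29) == pytest.approx(1.0e-6, rel=0.05)
    assert parallel_model(0.121, 2.12) == pytest.approx(5.9e-7, rel=0.02)


def test_combined_model_limits_and_bounds():
    eps, tau = 0.121, 2.12
    res1 = combined_model(eps, tau, 1.0)
    res0 = combined_model(eps, tau, 0.0)
    assert res1.D_eff == parallel_model(eps, tau)
    assert res0.D_eff == maxwell_eucken_serial(eps)
    for w in np.linspace(0, 1, 21):
        d = combined_model(eps, tau, w).D_eff
        assert res0.D_eff <= d <= res1.D_eff


def test_combined_model_monotone_in_w():
    ds = [combined_model(0.121, 2.12, w).D_eff for w in np.linspace(0, 1, 50)]
    assert np.all(np.diff(ds) > 0)


def test_inversion_round_trip():
    eps, tau = 0.254, 2.29
    for w in (0.1, 0.5, 0.93):
        d = combined_model(eps, tau, w).D_eff
        assert estimate_w(d, eps, tau) == pytest.approx(w, rel=1e-12)


def test_w_boundary_values():
    eps, tau = 0.184, 2.032
    d_ser = maxwell_eucken_serial(eps)
    assert estimate_w(d_ser, eps, tau) == pytest.approx(0.0, abs=1e-12)
    with pytest.warns(UserWarning):
        assert estimate_w(d_ser / 2, eps, tau) == 0.0


def test_apple_genotypes_w_above_090():
    for name in ("Braeburn", "Kanzi", "Jonagold"):
        eps, tau, d = GENOTYPES[name]
        assert estimate_w(d, eps, tau) > 0.90, name


def test_small_serial_fraction_collapses_diffusivity():
    """A 5 % serial pathway cuts the effective diffusivity by > 20x for
    the high-porosity genotype parameters."""
    eps, tau, _ = GENOTYPES["Jonagold"]
    ratio = combined_model(eps, tau, 0.95).D_eff / combined_model(eps, tau, 1.0).D_eff
    assert ratio < 0.05


@settings(max_examples=100, derandomize=True)
@given(
    eps=st.floats(0.01, 0.5),
    tau=st.floats(1.0, 5.0),
    w=st.floats(0.0, 1.0),
)
def test_harmonic_bounds_and_inversion_hold_everywhere(eps, tau, w):
    """For any porosity, tortuosity and weighing factor the combined
    diffusivity lies between the serial and parallel limits, and
    inverting it recovers the weighing factor."""
    res = combined_model(eps, tau, w)
    assert res.D_ser <= res.D_eff <= res.D_par
    if 0.0 < w < 1.0:
        assert estimate_w(res.D_eff, eps, tau) == pytest.approx(w, abs=1e-9)


def test_constants_validation():
    with pytest.raises(ValueError):
        GasConstants(D_air=1e-9, D_water=2e-9)
    with pytest.raises(ValueError):
        GasConstants(T=-1.0)
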