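import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minwaves import models
from minwaves.models import (
    ConfigurationError,
    Geometry,
    ModelParameters,
    cm_theory,
    dimensionalize,
    membrane_reaction_rates,
    nondimensionalize,
    stationary_state,
)


class TestModelParameters:
    def test_bulk_field_count(self):
        assert ModelParameters(model_variant="I").n_bulk == 2
        assert ModelParameters(model_variant="II").n_bulk == 3

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelParameters(model_variant="III")

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelParameters(omega_D=-0.1)

    def test_eigen_roundtrip(self, canonical, rng):
        fields = rng.uniform(size=(3, 5))
        back = canonical.bulk_from_eigen(canonical.bulk_to_eigen(fields))
        np.testing.assert_allclose(back, fields, rtol=0, atol=1e-15)

    def test_canonical_values(self, canonical):
        assert canonical.omega_D == 0.1
        assert canonical.omega_dD == 5.0
        assert canonical.omega_E == 0.1
        assert canonical.omega_ed == 100.0
        assert canonical.D_bulk == 100.0
        assert canonical.omega_e == 1.0


class TestGeometry:
    def test_alpha(self):
        assert Geometry("sphere", 5.0).alpha == pytest.approx(3.0 / 5.0)
        assert Geometry("slab", 256.0).alpha == pytest.approx(1.0 / 256.0)

    def test_invalid(self):
        with pytest.raises(ConfigurationError):
            Geometry("cube", 1.0)
        with pytest.raises(ConfigurationError):
            Geometry("sphere", -1.0)


class TestReactionRates:
    def test_empty_system_is_fixed_point(self, canonical):
        p = canonical.replace(ce0=0.0)
        rates, fluxes = membrane_reaction_rates(
            (0.0, 0.0, 0.0), (0.0, 0.0, 0.0), p)
        np.testing.assert_allclose(rates, 0.0)
        np.testing.assert_allclose(fluxes, 0.0)

    @given(st.integers(min_value=0, max_value=2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_flux_matching(self, seed):
        """What leaves the bulk enters the membrane exactly, for both models
        and random nonnegative states."""
        r = np.random.default_rng(seed)
        for variant in ("I", "II"):
            p = ModelParameters(model_variant=variant,
                                ce0=float(r.uniform(0, 0.1)),
                                saturation=bool(r.integers(2)))
            mem = r.uniform(0, 0.5, size=3)
            bulk = r.uniform(0, 1.0, size=p.n_bulk)
            rates, fluxes = membrane_reaction_rates(mem, bulk, p)
            # total MinD on membrane: c_d + c_de; bulk MinD: all but last field
            d_mem_gain = rates[0] + rates[1]
            d_bulk_gain = fluxes[:-1].sum()
            assert d_mem_gain + d_bulk_gain == pytest.approx(0.0, abs=1e-12)
            e_mem_gain = rates[1] + rates[2]
            assert e_mem_gain + fluxes[-1] == pytest.approx(0.0, abs=1e-12)

    def test_negative_input_rejected(self, canonical):
        with pytest.raises(ValueError):
            membrane_reaction_rates((-0.5, 0.0, 0.0), (0.1, 0.1, 0.1),
                                    canonical, check=True)

    def test_wrong_bulk_count(self, canonical):
        with pytest.raises(ConfigurationError):
            membrane_reaction_rates((0.1, 0.1, 0.1), (0.1, 0.1), canonical)


class TestStationaryState:
    def test_printed_planar_fixed_point(self, canonical, slab256):
        """Model II, H=256, D0=0.5, eps0=0.8, ce0=0.07: the published
        stationary values to three significant figures."""
        ss = stationary_state(canonical.replace(ce0=0.07), slab256)
        assert ss.cd == pytest.approx(0.0105, abs=5e-5)
        assert ss.cde == pytest.approx(0.0750, abs=5e-5)
        assert ss.ce == pytest.approx(0.0708, abs=5e-5)

    def test_residual_is_tiny(self, canonical, sphere5):
        ss = stationary_state(canonical.replace(ce0=0.02), sphere5)
        assert ss.residual < 1e-10

    def test_root_property(self, canonical, sphere5):
        """Re-substituting the fixed point gives zero rates."""
        p = canonical.replace(ce0=0.02)
        ss = stationary_state(p, sphere5)
        rates, _ = membrane_reaction_rates(ss.membrane, ss.bulk_surface, p)
        np.testing.assert_allclose(rates, 0.0, atol=1e-10)

    def test_no_mine_saturated_membrane(self, sphere5):
        """eps0=0, ce0=0 with the saturation term: the membrane fills with
        MinD, c_d* = 1."""
        p = models.canonical_parameters(eps0=0.0, ce0=0.0, D0=1.0,
                                        saturation=True)
        ss = stationary_state(p, sphere5)
        assert ss.cd == pytest.approx(1.0, abs=1e-10)
        assert ss.cde == pytest.approx(0.0, abs=1e-12)
        assert ss.ce == pytest.approx(0.0, abs=1e-12)

    def test_no_mind_gives_ce0(self, sphere5):
        """Without MinD the membrane MinE level is exactly ce0."""
        p = models.canonical_parameters(D0=0.0, ce0=0.05)
        ss = stationary_state(p, sphere5)
        assert ss.ce == pytest.approx(0.05, abs=1e-12)
        assert ss.cd == pytest.approx(0.0, abs=1e-12)

    def test_size_dependence_through_alpha(self, canonical):
        """The homogeneous stationary state depends on the system size."""
        p = canonical.replace(ce0=0.05)
        small = stationary_state(p, Geometry("sphere", 5.0))
        large = stationary_state(p, Geometry("sphere", 50.0))
        assert small.cd != pytest.approx(large.cd, rel=1e-3)

    def test_mass_constraints_satisfied(self, canonical, sphere5):
        p = canonical.replace(ce0=0.03)
        ss = stationary_state(p, sphere5)
        alpha = sphere5.alpha
        d_total = sum(ss.bulk_mean[:-1]) + alpha * (ss.cd + ss.cde)
        e_total = ss.bulk_mean[-1] + alpha * (ss.cde + ss.ce)
        assert d_total == pytest.approx(p.D0, abs=1e-12)
        assert e_total == pytest.approx(p.eps0, abs=1e-12)

    def test_model_I_fixed_point_exists(self, sphere5):
        p = models.canonical_parameters(model_variant="I", ce0=0.02)
        ss = stationary_state(p, sphere5)
        assert ss.residual < 1e-10
        assert ss.cd > 0


class TestDimensionalize:
    UNITS = dict(omega_e_dim=0.2, Dd_dim=0.2, conc_bulk_unit=1e3,
                 conc_mem_unit=1e3)

    def test_printed_conversions(self, canonical):
        dim = dimensionalize(canonical, **self.UNITS)
        assert dim["omega_D"] == pytest.approx(0.02)        # um/s
        assert dim["omega_dD"] == pytest.approx(1e-3)       # um^3/s
        assert dim["omega_E"] == pytest.approx(2e-5)        # um^3/s
        assert dim["D_bulk"] == pytest.approx(20.0)         # um^2/s
        assert dim["omega_ed"] == pytest.approx(2e-2)       # um^2/s

    def test_identity_units(self, canonical):
        dim = dimensionalize(canonical, 1.0, 1.0, 1.0, 1.0)
        assert dim["omega_D"] == canonical.omega_D
        assert dim["D_bulk"] == canonical.D_bulk

    def test_roundtrip(self, canonical):
        dim = dimensionalize(canonical, **self.UNITS)
        back = nondimensionalize(dim, **self.UNITS)
        for name in ("omega_D", "omega_dD", "omega_E", "omega_ed", "omega_e",
                     "D_bulk", "D_mem", "ce0", "lam", "D0", "eps0"):
            assert getattr(back, name) == pytest.approx(
                getattr(canonical, name), rel=1e-12)

    def test_bad_unit_rejected(self, canonical):
        with pytest.raises(ValueError):
            dimensionalize(canonical, 0.0, 1.0, 1.0, 1.0)


class TestCmTheory:
    def test_fully_localized(self):
        assert cm_theory(0.5, 1.0, 0.5) == pytest.approx(0.0)

    def test_infinite_for_zero_ce0(self):
        assert cm_theory(0.5, 1.0, 0.0) == math.inf

    def test_monotone_decreasing_in_ce0(self):
        vals = [cm_theory(0.8, 0.6, c) for c in np.linspace(0.01, 0.1, 20)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_agrees_with_stationary_partition_without_mind(self, sphere5):
        """In the no-MinD limit the measured bulk/membrane MinE ratio equals
        the closed-form (eps0 - alpha ce0)/ce0."""
        p = models.canonical_parameters(D0=0.0, ce0=0.04)
        ss = stationary_state(p, sphere5)
        expect = cm_theory(p.eps0, sphere5.alpha, p.ce0)
        assert ss.cm_measured("E") == pytest.approx(expect, rel=1e-10)


class TestParameterIO:
    def test_yaml_roundtrip(self, canonical, tmp_path):
        path = tmp_path / "params.yaml"
        models.save_parameters(canonical.replace(ce0=0.123), path)
        back = models.load_parameters(path)
        assert back.ce0 == 0.123
        assert back == canonical.replace(ce0=0.123)

    def test_csv_export(self, canonical, sphere5, tmp_path):
        import pandas as pd

        p = canonical.replace(ce0=0.02)
        ss = stationary_state(p, sphere5)
        path = tmp_path / "states.csv"
        models.stationary_states_to_csv([(p, ss)], path)
        df = pd.read_csv(path)
        assert df.loc[0, "cd"] == pytest.approx(ss.cd)
        assert df.loc[0, "geometry"] == "sphere"


class TestRootDiagnostics:
    def test_multiple_roots_flagged(self, sphere5):
        """With saturation and no MinE both the saturated-membrane and the
        empty-bulk branches can coexist; multiplicity is reported."""
        p = models.ModelParameters(eps0=0.0, ce0=0.0, D0=1.0, saturation=True)
        states = models.find_stationary_states(p, sphere5)
        assert len(states) >= 1
        if len(states) > 1:
            assert all(s.multiple for s in states)

    def test_returns_all_nonnegative(self, canonical, sphere5):
        for s in models.find_stationary_states(canonical.replace(ce0=0.02),
                                               sphere5):
            assert (s.membrane >= 0).all()
            assert all(v >= -1e-12 for v in s.bulk_surface)
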