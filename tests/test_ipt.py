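"""Isotope-pairing equations: partitioning, inversion, rIPT, integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from benthicnloss.errors import (
    DegenerateRatioError,
    DivisionDomainError,
    InfeasibleInversionError,
    InputError,
    UndefinedFractionError,
)
from benthicnloss.ipt import (
    LabelingFraction,
    PairingObservation,
    anammox_ex1,
    anammox_ex2,
    anammox_fraction,
    denit_ex2,
    depth_integrate,
    excess_nitrate,
    infer_fstar,
    ript_nloss,
)


def forward_pairing(d, a, f):
    """Binomial pairing forward model: true rates -> (p29, p30)."""
    return 2 * f * (1 - f) * d + a * f, d * f * f


class TestPartitioningEquations:
    @pytest.mark.parametrize("p29,f,expected", [
        (5.0, 0.5, 10.0),   # A=10 at F=0.5 produces p29 = A*F = 5
        (3.0, 1.0, 3.0),    # fully labeled ammonium
        (0.0, 0.4, 0.0),
    ])
    def test_anammox_ex1(self, p29, f, expected):
        assert anammox_ex1(p29, LabelingFraction(f, "NH4")) == pytest.approx(expected)

    @pytest.mark.parametrize("p30,f,expected", [
        (25.0, 0.5, 100.0),  # D=100 at F=0.5 gives p30 = D*F^2 = 25
        (7.0, 1.0, 7.0),
        (0.0, 0.3, 0.0),
    ])
    def test_denit_ex2(self, p30, f, expected):
        assert denit_ex2(p30, f) == pytest.approx(expected)

    @pytest.mark.parametrize("p29,p30,f,expected", [
        (55.0, 25.0, 0.5, 10.0),  # D=100, A=10: p29 = 50 + 5
        (50.0, 25.0, 0.5, 0.0),   # pure denitrification
        (3.0, 10.0, 1.0, 3.0),    # no denitrifier 29N2 at F=1
    ])
    def test_anammox_ex2(self, p29, p30, f, expected):
        assert anammox_ex2(p29, p30, f) == pytest.approx(expected)

    def test_anammox_ex2_negative_floored(self, caplog):
        with caplog.at_level("WARNING"):
            assert anammox_ex2(1.0, 25.0, 0.5) == 0.0
        assert "floored" in caplog.text
        assert anammox_ex2(1.0, 25.0, 0.5, clamp_negative=False) < 0

    def test_zero_fraction_rejected(self):
        with pytest.raises((DivisionDomainError, InputError)):
            anammox_ex1(5.0, 0.0)

    @given(
        d=st.floats(0, 200), a=st.floats(0, 50),
        f=st.floats(0.05, 1.0, exclude_max=False),
    )
    @settings(deadline=None, max_examples=300)
    def test_forward_inverse_roundtrip(self, d, a, f):
        """Pairing forward model followed by the partitioning equations is
        the identity on (D, A) to floating tolerance."""
        p29, p30 = forward_pairing(d, a, f)
        assert denit_ex2(p30, f) == pytest.approx(d, rel=1e-12, abs=1e-12)
        a_rec = anammox_ex2(p29, p30, f, clamp_negative=False)
        assert a_rec == pytest.approx(a, rel=1e-9, abs=1e-9 * max(1.0, d / f))


class TestInferFstar:
    def test_quadratic_roots_example(self):
        # forward model D=100, A=10, F=0.5: roots 0.5 and 10, only 0.5 admissible
        f = infer_fstar(55.0, 25.0, 10.0)
        assert f.value == pytest.approx(0.5)
        assert f.source == "inferred"
        # substitution check against the pairing equation
        assert anammox_ex2(55.0, 25.0, f) == pytest.approx(10.0)

    def test_linear_degenerate_case(self):
        assert infer_fstar(50.0, 25.0, 0.0).value == pytest.approx(0.5)

    def test_infeasible_carries_discriminant(self):
        with pytest.raises(InfeasibleInversionError) as exc:
            infer_fstar(0.0, 25.0, 100.0)
        assert exc.value.discriminant is not None and exc.value.discriminant < 0

    def test_identity_on_grid(self):
        """Composing the forward model with the inversion recovers F over a
        dense (F, D, A) grid."""
        for f in list(np.arange(0.1, 1.0, 0.05)) + [0.99]:
            for d in (1.0, 10.0, 50.0, 200.0):
                for a in (0.0, 1.0, 10.0, 50.0):
                    p29, p30 = forward_pairing(d, a, f)
                    got = infer_fstar(p29, p30, a, f_nominal=min(1.0, f * 1.05))
                    assert got.value == pytest.approx(f, abs=1e-6)

    def test_nominal_proximity_root_selection(self):
        # both roots admissible: A=40, p29/p30 built so roots are 0.25, 0.5
        # quadratic A F^2 - b F + 2 p30 with roots r1 r2: b=A(r1+r2), 2p30=A r1 r2
        a, r1, r2 = 40.0, 0.25, 0.5
        b = a * (r1 + r2)
        p30 = a * r1 * r2 / 2.0
        p29 = b - 2 * p30
        assert infer_fstar(p29, p30, a, f_nominal=0.3).value == pytest.approx(r1)
        assert infer_fstar(p29, p30, a, f_nominal=0.6).value == pytest.approx(r2)
        # without a nominal fraction the larger root wins
        assert infer_fstar(p29, p30, a).value == pytest.approx(r2)


class TestExcessNitrate:
    def test_no_dilution_no_excess(self):
        assert excess_nitrate(200.0, 0.8, 0.8, 2.0) == 0.0

    def test_known_dilution(self):
        # aqueous: 200*(1/0.5 - 1/0.8) = 150 µmol/l; unit factor 1 for clarity
        assert excess_nitrate(200.0, 0.5, 0.8, 1.0) == pytest.approx(150.0)

    def test_fstar_above_nominal_floored(self, caplog):
        with caplog.at_level("WARNING"):
            assert excess_nitrate(200.0, 0.9, 0.8, 1.0) == 0.0
        assert "floored" in caplog.text


class TestAnammoxFraction:
    @pytest.mark.parametrize("a,d,pct", [(0.21, 2.73, 7), (0.89, 1.46, 38)])
    def test_station_contributions(self, a, d, pct):
        assert round(100 * anammox_fraction(a, d)) == pct

    def test_zero_anammox(self):
        assert anammox_fraction(0.0, 5.0) == 0.0

    @given(a=st.floats(0.01, 10), d=st.floats(0.01, 10), k=st.floats(0.1, 100))
    @settings(deadline=None, max_examples=50)
    def test_scale_invariance(self, a, d, k):
        assert anammox_fraction(k * a, k * d) == pytest.approx(anammox_fraction(a, d))

    def test_undefined_for_zero_rates(self):
        with pytest.raises(UndefinedFractionError):
            anammox_fraction(0.0, 0.0)


class TestRiptNloss:
    def test_classical_limit(self):
        # ra = 0 must reproduce the classical pairing total D15 + D14
        obs = PairingObservation(50.0, 25.0, "umol_n2_m2_d")
        res = ript_nloss(obs, 0.0)
        d15 = 50.0 + 2 * 25.0
        d14 = (50.0 / (2 * 25.0)) * d15
        assert res.nloss_total * 1e3 == pytest.approx(d15 + d14)  # = 200
        assert res.anammox == 0.0

    def test_grid_recovery_against_forward_model(self):
        """Authoritative disambiguation: over a truth grid the estimator
        recovers D14 + D15 + A exactly (noise-free)."""
        for d14 in np.linspace(10, 400, 5):
            for d15 in np.linspace(10, 400, 5):
                for a in np.linspace(0, 200, 5):
                    d = d14 + d15
                    f = d15 / d
                    p29, p30 = 2 * f * (1 - f) * d + a * f, d * f * f
                    ra = a / (a + d)
                    res = ript_nloss(PairingObservation(p29, p30, "umol_n2_m2_d"), ra)
                    truth_atoms = 2.0 * (d + a)
                    assert res.nloss_total * 1e3 == pytest.approx(truth_atoms, rel=1e-9)
                    assert res.denit + res.anammox == pytest.approx(res.nloss_total, rel=1e-12)
                    assert res.anammox == pytest.approx(ra * res.nloss_total)

    def test_degenerate_p30(self):
        with pytest.raises(DegenerateRatioError):
            ript_nloss(PairingObservation(5.0, 0.0, "umol_n2_m2_d"), 0.2)

    def test_missing_channel(self):
        with pytest.raises(InputError):
            ript_nloss(PairingObservation(None, 5.0, "umol_n2_m2_d"), 0.2)


class TestDepthIntegrate:
    @pytest.mark.parametrize("rate,expected", [(136.0, 2.72), (73.0, 1.46)])
    def test_surface_layer_flux(self, rate, expected):
        assert depth_integrate([(0, 2, rate)], 2.0) == pytest.approx(expected)

    def test_zero_rates(self):
        assert depth_integrate([(0, 2, 0.0), (2, 4, 0.0)], 4.0) == 0.0

    def test_additive_over_partitions(self):
        whole = depth_integrate([(0, 4, 50.0)], 4.0)
        split = depth_integrate([(0, 1.5, 50.0), (1.5, 4, 50.0)], 4.0)
        assert whole == pytest.approx(split)

    @given(k=st.floats(0.1, 20))
    @settings(deadline=None, max_examples=25)
    def test_linear_in_rates(self, k):
        layers = [(0.0, 2.0, 30.0), (2.0, 4.0, 10.0)]
        scaled = [(t, b, k * r) for t, b, r in layers]
        assert depth_integrate(scaled, 4.0) == pytest.approx(
            k * depth_integrate(layers, 4.0), rel=1e-12
        )

    def test_integration_clips_to_depth(self):
        assert depth_integrate([(0, 2, 100.0), (2, 4, 100.0)], 2.0) == pytest.approx(2.0)

    def test_truncation_warning(self, caplog):
        with caplog.at_level("WARNING"):
            depth_integrate([(0, 2, 10.0)], 6.0)
        assert "truncated" in caplog.text

    def test_overlapping_layers_rejected(self):
        with pytest.raises(InputError):
            depth_integrate([(0, 2, 1.0), (1, 3, 1.0)], 3.0)
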