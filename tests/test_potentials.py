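"""Unit tests for the pairwise and external energy terms."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pipfep.constants import COULOMB_KCAL
from pipfep.potentials import (
    AlchemicalSystem,
    AlchemicalTag,
    FlatBottomWell,
    HarmonicWell,
    InteractionParams,
    coulomb_energy,
    elec_scaling,
    lj_energy,
    softcore_lj_energy,
    system_energy,
)

P = InteractionParams


class TestLennardJones:
    def test_zero_at_sigma(self):
        p = P(0.2, 3.0)
        assert lj_energy(3.0, (p, p)) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_is_minus_epsilon(self):
        p = P(0.2, 3.0)
        assert lj_energy(2 ** (1 / 6) * 3.0, (p, p)) == pytest.approx(-0.2)

    def test_hand_evaluated_point(self):
        # 4*0.2*(2^-12 - 2^-6) at r = 2 sigma
        p = P(0.2, 3.0)
        assert lj_energy(6.0, (p, p)) == pytest.approx(-0.0123046875, rel=1e-12)

    def test_lorentz_berthelot_combination(self):
        a, b = P(0.1, 2.0), P(0.4, 4.0)
        # combined eps = 0.2, sigma = 3.0 -> zero crossing at r = 3
        assert lj_energy(3.0, (a, b)) == pytest.approx(0.0, abs=1e-12)

    def test_cutoff_truncates(self):
        p = P(0.2, 3.0)
        assert lj_energy(12.5, (p, p), cutoff=12.0) == 0.0
        assert lj_energy(11.5, (p, p), cutoff=12.0) != 0.0

    def test_nonpositive_distance_rejected(self):
        p = P(0.2, 3.0)
        with pytest.raises(ValueError):
            lj_energy(0.0, (p, p))


class TestCoulomb:
    def test_switched_off(self):
        assert coulomb_energy(2.0, 1.0, -1.0, scale=0.0) == 0.0

    def test_zero_charge(self):
        assert coulomb_energy(2.0, 0.0, -1.0) == 0.0

    def test_hand_evaluated_point(self):
        assert coulomb_energy(3.32, 1.0, 1.0) == pytest.approx(COULOMB_KCAL / 3.32)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            coulomb_energy(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            coulomb_energy(1.0, 1.0, 1.0, scale=1.5)


class TestSoftcore:
    def test_fully_coupled_matches_plain_lj(self):
        p = P(0.11, 3.3)
        for r in np.linspace(2.0, 10.0, 30):
            assert softcore_lj_energy(r, 1.0, (p, p)) == pytest.approx(
                lj_energy(r, (p, p)), rel=1e-12
            )

    def test_decoupled_endpoint_is_zero(self):
        p = P(0.11, 3.3)
        for r in (0.0, 1.0, 3.3, 8.0):
            assert softcore_lj_energy(r, 0.0, (p, p)) == 0.0

    def test_finite_at_overlap_for_partial_coupling(self):
        p = P(0.1, 3.0)
        for lam in (0.001, 0.1, 0.5, 0.9, 0.999):
            assert math.isfinite(softcore_lj_energy(0.0, lam, (p, p)))

    def test_hand_evaluated_overlap_value(self):
        # lam=0.5, r=0: denom = alpha*(1-lam)*sig^6 = 0.25*729, s = 4
        # V = 4 * 0.1 * 0.5 * (16 - 4) = 2.4
        p = P(0.1, 3.0)
        assert softcore_lj_energy(0.0, 0.5, (p, p), alpha=0.5) == pytest.approx(2.4)

    def test_lambda_domain_error(self):
        p = P(0.1, 3.0)
        with pytest.raises(ValueError):
            softcore_lj_energy(1.0, 1.5, (p, p))


class TestElecScaling:
    def test_appearing_off_below_threshold(self):
        assert elec_scaling(0.05, AlchemicalTag.APPEARING) == 0.0
        assert elec_scaling(0.1, AlchemicalTag.APPEARING) == 0.0

    def test_endpoints(self):
        assert elec_scaling(1.0, AlchemicalTag.APPEARING) == pytest.approx(1.0)
        assert elec_scaling(0.95, AlchemicalTag.DISAPPEARING) == 0.0
        assert elec_scaling(0.0, AlchemicalTag.DISAPPEARING) == 1.0

    def test_linear_ramp_value(self):
        assert elec_scaling(0.55, AlchemicalTag.APPEARING) == pytest.approx(
            (0.55 - 0.1) / 0.9
        )

    def test_unperturbed_always_on(self):
        for lam in (0.0, 0.3, 1.0):
            assert elec_scaling(lam, AlchemicalTag.UNPERTURBED) == 1.0

    @given(lam=st.floats(0.0, 1.0))
    def test_bounded_for_all_tags(self, lam):
        for tag in AlchemicalTag:
            assert 0.0 <= elec_scaling(lam, tag) <= 1.0

    def test_piecewise_linear_continuity_at_knots(self):
        eps = 1e-9
        for tag, knot in [
            (AlchemicalTag.APPEARING, 0.1),
            (AlchemicalTag.DISAPPEARING, 0.9),
        ]:
            below = elec_scaling(knot - eps, tag)
            above = elec_scaling(knot + eps, tag)
            assert abs(below - above) < 1e-8


def _pairwise_oracle(system, coords, lam):
    """Independent pairwise evaluation of the coupling rules."""
    total = 0.0
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj = system.tags[i], system.tags[j]
            tags = {ti, tj}
            r = float(np.linalg.norm(np.asarray(coords[i]) - np.asarray(coords[j])))
            if {AlchemicalTag.APPEARING, AlchemicalTag.DISAPPEARING} <= tags:
                continue
            if AlchemicalTag.APPEARING in tags:
                lam_eff = lam
            elif AlchemicalTag.DISAPPEARING in tags:
                lam_eff = 1.0 - lam
            else:
                lam_eff = 1.0
            pair = (system.params[i], system.params[j])
            total += softcore_lj_energy(r, lam_eff, pair, alpha=system.alpha)
            scale = elec_scaling(lam, ti) * elec_scaling(lam, tj)
            total += coulomb_energy(
                r, system.params[i].charge, system.params[j].charge, scale
            )
    return total


class TestSystemEnergy:
    def test_noninteracting_system_is_external_only(self):
        system = AlchemicalSystem(
            coordinates=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
            params=[P(0.0, 1.0, 0.0), P(0.0, 1.0, 0.0)],
            tags=[AlchemicalTag.UNPERTURBED] * 2,
            wells=[[HarmonicWell.isotropic(2.0)], []],
        )
        e = system_energy(system, np.array([[1.0, 0.0, 0.0], [3.0, 0.0, 0.0]]), 0.3)
        assert e.elec == 0.0 and e.vdw == 0.0
        assert e.external == pytest.approx(0.5 * 2.0 * 1.0)
        assert e.total == pytest.approx(e.external)

    def test_unperturbed_pair_lambda_independent(self, charged_pair):
        e0 = system_energy(charged_pair, lam=0.0)
        e1 = system_energy(charged_pair, lam=1.0)
        assert e0.total == pytest.approx(e1.total, rel=1e-14)

    @pytest.mark.parametrize("lam", [0.0, 0.05, 0.1, 0.35, 0.7, 0.9, 0.999, 1.0])
    def test_matches_pairwise_oracle_over_lambda_sweep(self, lam):
        system = AlchemicalSystem(
            coordinates=np.array(
                [[0.0, 0.0, 0.0], [3.4, 0.0, 0.0], [1.0, 2.8, 0.0]]
            ),
            params=[P(0.15, 3.2, 0.3), P(0.2, 3.0, -0.35), P(0.1, 3.1, -0.2)],
            tags=[
                AlchemicalTag.UNPERTURBED,
                AlchemicalTag.APPEARING,
                AlchemicalTag.DISAPPEARING,
            ],
        )
        e = system_energy(system, lam=lam)
        assert e.elec + e.vdw == pytest.approx(
            _pairwise_oracle(system, system.coordinates, lam), rel=1e-10, abs=1e-12
        )

    def test_decomposition_sums_exactly(self):
        system = AlchemicalSystem(
            coordinates=np.array([[0.0, 0.0, 0.0], [3.0, 0.5, 0.0]]),
            params=[P(0.15, 3.2, 0.3), P(0.2, 3.0, -0.35)],
            tags=[AlchemicalTag.UNPERTURBED, AlchemicalTag.APPEARING],
            wells=[[], [FlatBottomWell(3.0, 1.0, (3.0, 0.0, 0.0))]],
        )
        for lam in (0.0, 0.2, 0.6, 1.0):
            e = system_energy(system, lam=lam)
            assert e.total - e.elec - e.vdw - e.external == pytest.approx(0.0, abs=1e-10)

    def test_size_mismatch_rejected(self, charged_pair):
        with pytest.raises(ValueError):
            system_energy(charged_pair, np.zeros((3, 3)), 0.0)


class TestTypes:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            P(-0.1, 3.0)
        with pytest.raises(ValueError):
            P(0.1, 0.0)
        with pytest.raises(ValueError):
            P(0.1, 3.0, vdw_radius=-1.0)

    def test_negative_force_constant_rejected(self):
        with pytest.raises(ValueError):
            HarmonicWell((-1.0, 0.0, 0.0), (0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            FlatBottomWell(-1.0, 0.5)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            AlchemicalSystem(
                coordinates=np.zeros((2, 3)),
                params=[P(0.1, 3.0)],
                tags=[AlchemicalTag.UNPERTURBED] * 2,
            )
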