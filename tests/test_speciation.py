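"""Unit and property tests for the charge-balance speciation engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from borealacid.speciation import (
    AL_MOLAR_MASS,
    DEFAULT_CONSTANTS,
    IonComposition,
    SpeciationError,
    UnsolvableCompositionError,
    aluminum_speciation,
    carbonate_charge,
    charge_balance_residual,
    organic_acid_charge,
    solve_pH,
)

from .conftest import random_composition


def grid_search_pH(comp, constants=DEFAULT_CONSTANTS, step=0.001):
    """Independent oracle: exhaustive scan of the residual sign change."""
    grid = np.arange(3.0, 10.0 + step / 2, step)
    res = charge_balance_residual(grid, comp, constants)
    idx = int(np.argmin(np.abs(res)))
    return float(grid[idx])


class TestAluminum:
    def test_free_ion_obeys_gibbsite_line(self):
        # pAl = s_al*pH - log_KAl: at pH 5 with the defaults, pAl = 6.9
        al = aluminum_speciation(5.0)
        assert math.isclose(-math.log10(al.al3 / 3e6), 6.9, rel_tol=1e-12)

    def test_cationic_mass_below_critical_at_4_8(self):
        # the critical 50 ug/L level is not reached above pH 4.8
        assert aluminum_speciation(4.8).al_i_mass <= 50.0

    @pytest.mark.parametrize("lo,hi", [(4.5, 5.5), (4.0, 4.5), (5.5, 6.5)])
    def test_cationic_mass_decreases_with_pH(self, lo, hi):
        assert aluminum_speciation(lo).al_i_mass > aluminum_speciation(hi).al_i_mass

    def test_mass_consistent_with_species_charges(self):
        al = aluminum_speciation(5.2)
        molar = al.al3 / 3 + al.aloh2 / 2 + al.aloh2p
        assert math.isclose(al.al_i_mass, molar * AL_MOLAR_MASS, rel_tol=1e-12)

    def test_out_of_range_pH_rejected(self):
        with pytest.raises(SpeciationError):
            aluminum_speciation(1.5)

    def test_disabled_solid_phase_gives_no_aluminum(self):
        consts = DEFAULT_CONSTANTS.with_(al_enabled=False)
        al = aluminum_speciation(4.5, consts)
        assert al.cationic_charge == 0 and al.aloh4 == 0


class TestCarbonate:
    def test_zero_pco2_gives_zero_bicarbonate(self):
        consts = DEFAULT_CONSTANTS.with_(pco2_fraction=0.0)
        for ph in (4.0, 7.0, 9.5):
            assert carbonate_charge(ph, consts) == 0.0

    def test_half_dissociation_at_pK1(self):
        # at pH = pK1, [HCO3-] equals dissolved CO2 in equivalents
        consts = DEFAULT_CONSTANTS.with_(carbonic_pK1=6.3)
        co2_ueq = 10.0 ** consts.henry_kH * consts.pco2_atm * 1e6
        assert math.isclose(carbonate_charge(6.3, consts), co2_ueq, rel_tol=1e-12)

    def test_closed_form_hand_value(self):
        # independent hand evaluation of K1*kH*pCO2/[H+] at pH 7:
        # 10**(7 - 6.3 - 1.5) * 0.00156 * 1e6 ueq/L
        expected = 10.0 ** (7.0 - 6.3 - 1.5) * 0.00156 * 1e6
        assert math.isclose(carbonate_charge(7.0), expected, rel_tol=1e-9)

    def test_monotone_in_pH(self):
        grid = np.linspace(3, 10, 50)
        vals = carbonate_charge(grid, DEFAULT_CONSTANTS)
        assert np.all(np.diff(vals) > 0)


class TestOrganicAcids:
    def test_no_toc_no_charge(self):
        for ph in (3.5, 5.0, 8.0):
            assert organic_acid_charge(ph, 0.0) == 0.0

    def test_full_dissociation_bound(self):
        # far above pK3 the charge approaches site_density*toc and never
        # exceeds it
        toc = 12.0
        bound = DEFAULT_CONSTANTS.oa_site_density * toc
        high = organic_acid_charge(11.9, toc)
        assert high == pytest.approx(bound, rel=1e-3)
        grid = np.linspace(2, 12, 200)
        assert np.all(organic_acid_charge(grid, toc) <= bound + 1e-9)

    def test_against_fraction_oracle(self):
        # independent brute-force evaluation of the triprotic ionisation
        # fractions at pH 5, toc 10
        c = DEFAULT_CONSTANTS
        h = 10.0 ** -5.0
        forms = np.array(
            [
                1.0,
                10.0 ** -c.oa_pK1 / h,
                10.0 ** (-c.oa_pK1 - c.oa_pK2) / h**2,
                10.0 ** (-c.oa_pK1 - c.oa_pK2 - c.oa_pK3) / h**3,
            ]
        )
        alpha = forms / forms.sum()
        a_total = c.oa_site_density * 10.0 / 3.0
        expected = a_total * (alpha[1] + 2 * alpha[2] + 3 * alpha[3])
        assert organic_acid_charge(5.0, 10.0) == pytest.approx(expected, rel=1e-10)


class TestChargeBalance:
    def test_neutral_water_balances_at_7(self):
        comp = IonComposition(na=50, cl=50)  # BC == SAA
        consts = DEFAULT_CONSTANTS.with_(
            pco2_fraction=0.0, al_enabled=False, oa_site_density=0.0
        )
        assert charge_balance_residual(7.0, comp, consts) == pytest.approx(0.0, abs=1e-9)

    def test_strong_acid_balances_at_5(self):
        comp = IonComposition(so4=10)  # SAA - BC = 10 ueq/L
        consts = DEFAULT_CONSTANTS.with_(
            pco2_fraction=0.0, al_enabled=False, oa_site_density=0.0
        )
        # residual(5.0) = OH(5.0) only ~ 1e-3 ueq; root within 1e-4 pH of 5
        assert charge_balance_residual(5.0, comp, consts) == pytest.approx(
            0.0, abs=2e-3
        )

    def test_sign_change_on_bracket(self, circumneutral_lake, acid_lake):
        for comp in (circumneutral_lake, acid_lake):
            assert charge_balance_residual(3.0, comp) > 0
            assert charge_balance_residual(10.0, comp) < 0

    def test_strictly_decreasing(self, circumneutral_lake):
        grid = np.linspace(3, 10, 400)
        res = charge_balance_residual(grid, circumneutral_lake)
        assert np.all(np.diff(res) < 0)


class TestSolver:
    def test_strong_acid_closed_form(self):
        comp = IonComposition(so4=10)
        consts = DEFAULT_CONSTANTS.with_(
            pco2_fraction=0.0, al_enabled=False, oa_site_density=0.0
        )
        assert solve_pH(comp, consts).pH == pytest.approx(5.0, abs=1e-3)

    def test_residual_within_tolerance(self, circumneutral_lake, acid_lake):
        for comp in (circumneutral_lake, acid_lake):
            result = solve_pH(comp, tolerance=1e-4)
            assert abs(result.residual) <= 1e-4

    def test_charge_conservation(self, circumneutral_lake):
        r = solve_pH(circumneutral_lake)
        lhs = r.positive_charge + circumneutral_lake.base_cations
        rhs = r.negative_charge + circumneutral_lake.strong_acid_anions
        assert lhs - rhs == pytest.approx(r.residual, abs=1e-9)

    def test_matches_grid_search_with_carbonate_only(self):
        comp = IonComposition(ca=50)  # BC - SAA = 50
        consts = DEFAULT_CONSTANTS.with_(al_enabled=False, oa_site_density=0.0)
        assert solve_pH(comp, consts).pH == pytest.approx(
            grid_search_pH(comp, consts), abs=0.01
        )

    def test_matches_grid_search_randomized(self):
        rng = np.random.default_rng(1234)
        for _ in range(25):
            comp = random_composition(rng)
            assert solve_pH(comp).pH == pytest.approx(grid_search_pH(comp), abs=0.01)

    def test_unsolvable_composition_names_lake(self):
        comp = IonComposition(so4=5000)  # H+ demand beyond the pH-3 bracket
        consts = DEFAULT_CONSTANTS.with_(
            pco2_fraction=0.0, al_enabled=False, oa_site_density=0.0
        )
        with pytest.raises(UnsolvableCompositionError, match="Stortjärn"):
            solve_pH(comp, consts, lake_id="Stortjärn")

    def test_aluminum_negligible_above_pH6(self):
        # cationic Al is under 1% of total positive charge whenever the
        # solved pH is above 6
        rng = np.random.default_rng(99)
        checked = 0
        while checked < 20:
            comp = random_composition(rng)
            r = solve_pH(comp)
            if r.pH <= 6.0:
                continue
            al_cat = r.al3 + r.aloh2 + r.aloh2p
            total_pos = r.h + comp.base_cations + al_cat
            assert al_cat < 0.01 * total_pos
            checked += 1


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    bc=st.floats(0, 500),
    saa=st.floats(0, 500),
    toc=st.floats(0, 32),
)
def test_solver_root_unique_and_consistent(bc, saa, toc):
    """Any nonnegative composition has one root matching the grid oracle."""
    comp = IonComposition(ca=bc, so4=saa, toc=toc)
    result = solve_pH(comp)
    assert 3.0 <= result.pH <= 10.0
    assert abs(result.residual) <= 1e-4
    assert result.pH == pytest.approx(grid_search_pH(comp), abs=0.01)


def test_invalid_composition_rejected():
    with pytest.raises(SpeciationError):
        IonComposition(ca=-1)
    with pytest.raises(SpeciationError):
        IonComposition(toc=float("nan"))
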