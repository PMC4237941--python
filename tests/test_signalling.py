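import pytest

from ctcsim.cell_model import CellType, LifeState, Variant, make_cell
from ctcsim.chemistry import BindingSystem, equilibrate_pair
from ctcsim.signalling import (
    Ledger, PoolState, RateConfig, SPECIES, decay_stores, degrade,
    intracellular_readout, secrete, uptake,
)

from conftest import bisect_pair_oracle

V = 1e-3


def make_pool(**totals):
    return PoolState(volume=V, **totals)


class TestSecrete:
    def test_no_cells_is_identity(self, rates, system):
        pool = make_pool(total_a=1e-10)
        assert secrete([], pool, rates) == pool

    def test_linearity(self, rates):
        cells = [make_cell(CellType.A, Variant.EC, id=i) for i in range(10)]
        pool = secrete(cells, make_pool(), rates)
        assert pool.total_a == pytest.approx(10 * rates.secretion_rate,
                                             rel=1e-12)
        assert pool.total_i == 0.0

    def test_hived_fraction_partition(self):
        rates = RateConfig(hived_fraction=0.2)
        cells = [make_cell(CellType.A, Variant.IC, id=i) for i in range(10)]
        pool = secrete(cells, make_pool(), rates, Variant.IC)
        r = rates.secretion_rate
        assert pool.total_a == pytest.approx(8 * r, rel=1e-12)
        assert sum(c.hived_self for c in cells) == pytest.approx(
            2 * r, rel=1e-12)

    def test_dormant_and_dead_do_not_secrete(self, rates):
        cells = [
            make_cell(CellType.A, Variant.EC, id=0,
                      life_state=LifeState.DORMANT),
            make_cell(CellType.A, Variant.EC, id=1,
                      life_state=LifeState.DEAD),
        ]
        assert secrete(cells, make_pool(), rates).total_a == 0.0

    def test_progenitors_secrete_nothing(self, rates):
        cells = [make_cell(CellType.O, Variant.EC, id=0)]
        pool = secrete(cells, make_pool(), rates)
        assert pool.total_a == 0.0 and pool.total_i == 0.0

    def test_boost_and_damp_flags(self):
        rates = RateConfig(boost_factor=0.5, damp_factor=0.25)
        boosted = make_cell(CellType.A, Variant.EC, id=0)
        boosted.boosted = True
        damped = make_cell(CellType.A, Variant.EC, id=1)
        damped.damped = True
        pool = secrete([boosted, damped], make_pool(), rates)
        r = rates.secretion_rate
        assert pool.total_a == pytest.approx(1.5 * r + 0.25 * r, rel=1e-12)

    def test_ledger_books_full_synthesis(self, rates):
        ledger = Ledger()
        cells = [make_cell(CellType.I, Variant.IC, id=0)]
        secrete(cells, make_pool(), rates, Variant.IC, ledger)
        assert ledger.secreted["i"] == pytest.approx(rates.secretion_rate)


class TestUptake:
    def test_no_matching_receptor_no_transfer(self, rates, system):
        # a pool holding only the cell's own species: nothing to take
        cell = make_cell(CellType.A, Variant.EC)
        pool = make_pool(total_a=1e-10)
        cell2, new_pool = uptake(cell, pool, rates, system)
        assert new_pool.total_a == pool.total_a
        assert cell2.internal_free_a == 0.0

    def test_a_cell_takes_partner_never_self(self, rates, system):
        cell = make_cell(CellType.A, Variant.EC)
        pool = make_pool(total_a=1e-10, total_i=1e-10)
        cell, new_pool = uptake(cell, pool, rates, system)
        assert cell.internal_free_i > 0
        assert cell.internal_free_a == 0.0
        # species a leaves the pool only inside internalized complex
        assert pool.total_a - new_pool.total_a == pytest.approx(
            cell.internal_complex_ai, rel=1e-12)

    def test_mass_conserved(self, rates, system):
        cell = make_cell(CellType.I, Variant.EC)
        pool = make_pool(total_a=2e-10, total_i=1e-10)
        before = {s: pool.total(s) + cell.species_content(s) for s in SPECIES}
        cell, pool = uptake(cell, pool, rates, system)
        after = {s: pool.total(s) + cell.species_content(s) for s in SPECIES}
        for s in SPECIES:
            assert after[s] == pytest.approx(before[s], rel=1e-12, abs=1e-30)

    def test_dead_cells_take_nothing(self, rates, system):
        cell = make_cell(CellType.I, Variant.EC,
                         life_state=LifeState.DEAD)
        pool = make_pool(total_a=1e-10)
        _, new_pool = uptake(cell, pool, rates, system)
        assert new_pool.total_a == pool.total_a

    def test_complex_uptake_scaled_by_scarcity(self, system):
        rates = RateConfig(uptake_rate=0.1)
        pool = make_pool(total_a=1e-10, total_i=1e-10)
        eq = pool.equilibrium(system)
        cell = make_cell(CellType.I, Variant.EC, tccR_count_scale=0.05)
        cell, _ = uptake(cell, pool, rates, system)
        expected = 0.1 * 0.05 * eq.complex_ai * V
        assert cell.internal_complex_ai == pytest.approx(expected, rel=1e-9)

    def test_analog_taken_through_mimicked_receptor(self, rates,
                                                    analog_system):
        pool = make_pool(total_analog=1e-10)
        i_cell = make_cell(CellType.I, Variant.EC, id=0)
        a_cell = make_cell(CellType.A, Variant.EC, id=1)
        i_cell, _ = uptake(i_cell, pool, rates, analog_system)
        a_cell, _ = uptake(a_cell, pool, rates, analog_system)
        assert i_cell.internal_analog > 0    # analog mimics species a
        assert a_cell.internal_analog == 0.0


class TestIntracellularReadout:
    def test_empty_stores(self, rates, system):
        cell = make_cell(CellType.A, Variant.EC)
        assert intracellular_readout(cell, system, Variant.EC, rates) == \
            (0.0, 0.0)

    def test_ec_single_species_cannot_form_complex(self, rates, system):
        cell = make_cell(CellType.A, Variant.EC)
        cell.internal_free_i = 4e-13
        partner, complex_ = intracellular_readout(cell, system, Variant.EC,
                                                  rates)
        assert partner == pytest.approx(4e-13 / rates.endosome_volume,
                                        rel=1e-12)
        assert complex_ == 0.0

    def test_ic_symmetric_equilibrium_matches_oracle(self, rates, system):
        """Hived own product equal to internalized partner: the endosome is
        the textbook equal-totals equilibrium."""
        amount = 1e-8 * rates.endosome_volume
        cell = make_cell(CellType.A, Variant.IC)
        cell.hived_self = amount
        cell.internal_free_i = amount
        partner, complex_ = intracellular_readout(cell, system, Variant.IC,
                                                  rates)
        expected_c = bisect_pair_oracle(1e-8, 1e-8, system.ka)
        assert complex_ == pytest.approx(expected_c, rel=1e-7)
        assert partner == pytest.approx(1e-8 - expected_c, rel=1e-7)

    def test_ec_complex_reequilibrates(self, rates, system):
        cell = make_cell(CellType.I, Variant.EC)
        cell.internal_free_a = 2e-13
        cell.internal_complex_ai = 1e-13
        partner, complex_ = intracellular_readout(cell, system, Variant.EC,
                                                  rates)
        v = rates.endosome_volume
        eq = equilibrate_pair(3e-13 / v, 1e-13 / v, system.ka)
        assert partner == pytest.approx(eq.free_a, rel=1e-9)
        assert complex_ == pytest.approx(eq.complex_ai, rel=1e-9)

    def test_zero_endosome_volume_is_a_config_error(self, system):
        with pytest.raises(ValueError, match="endosome_volume"):
            RateConfig(endosome_volume=0.0)

    def test_ec_readout_sign_matches_pool_imbalance(self, system):
        """With full-strength complex receptors, the internal (partner -
        complex) sign tracks the extracellular (free partner - complex)
        sign on fixed configurations."""
        rates = RateConfig(uptake_rate=0.05)
        for total_a, total_i in [(5e-9, 1e-10), (1e-10, 1e-10),
                                 (2e-10, 5e-9)]:
            pool = make_pool(total_a=total_a, total_i=total_i)
            eq = pool.equilibrium(system)
            cell = make_cell(CellType.I, Variant.EC, tccR_count_scale=1.0)
            cell, _ = uptake(cell, pool, rates, system)
            partner, complex_ = intracellular_readout(cell, system,
                                                      Variant.EC, rates)
            external = eq.free_a - eq.complex_ai
            internal = partner - complex_
            assert (internal > 0) == (external > 0)


class TestDegradeAndDecay:
    def test_zero_rate_is_identity(self):
        rates = RateConfig(degradation_rate=0.0)
        pool = make_pool(total_a=1e-10, total_i=2e-10)
        assert degrade(pool, rates) == pool

    def test_full_rate_empties_pool(self):
        rates = RateConfig(degradation_rate=1.0)
        pool = degrade(make_pool(total_a=1e-10), rates)
        assert pool.total_a == 0.0

    def test_compounding(self):
        rates = RateConfig(degradation_rate=0.3)
        pool = make_pool(total_a=1e-10)
        twice = degrade(degrade(pool, rates), rates)
        assert twice.total_a == pytest.approx(
            1e-10 * (1 - (1 - (1 - 0.3) ** 2)), rel=1e-12)

    def test_degradation_is_ledgered(self):
        rates = RateConfig(degradation_rate=0.5)
        ledger = Ledger()
        degrade(make_pool(total_a=1e-10), rates, ledger)
        assert ledger.degraded["a"] == pytest.approx(5e-11)

    def test_store_decay_conserves_into_ledger(self, system):
        rates = RateConfig(store_decay=0.25)
        ledger = Ledger()
        cell = make_cell(CellType.I, Variant.EC)
        cell.internal_free_a = 4e-12
        cell.internal_complex_ai = 8e-12
        before_a = cell.species_content("a")
        decay_stores([cell], rates, system, ledger)
        assert cell.species_content("a") + ledger.degraded["a"] == \
            pytest.approx(before_a, rel=1e-12)


class TestLedgerClosure:
    def test_closure_detects_leaks(self, system):
        ledger = Ledger()
        pool = make_pool(total_a=1e-10)
        errors = ledger.closure_errors(pool, [])
        assert errors["a"] > 1e-9   # mass appeared from nowhere
        ledger.book("injected", "a", 1e-10)
        errors = ledger.closure_errors(pool, [])
        assert errors["a"] < 1e-12
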