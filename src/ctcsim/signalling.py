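"""Extracellular pool, secretion/uptake/degradation, and the intracellular
readout that turns internalized material into a (partner, complex) signal.

Mass is tracked in amounts (mol); the pool converts to concentrations via
its volume, cells via the configured endosome volume.  Every transfer is
mirrored in an optional :class:`Ledger` so simulations can prove
conservation at each step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .cell_model import Cell, CellType, LifeState, Variant, secreted_species
from .chemistry import BindingSystem, EquilibriumResult, equilibrate_with_analog

__all__ = [
    "PoolState", "RateConfig", "Ledger", "secrete", "uptake",
    "intracellular_readout", "degrade", "decay_stores",
]

SPECIES = ("a", "i", "analog")


@dataclass
class PoolState:
    """Well-mixed extracellular compartment.  Totals are amounts in mol and
    include complexed material; the free/bound split is derived on demand."""

    volume: float
    total_a: float = 0.0
    total_i: float = 0.0
    total_analog: float = 0.0
    antigen_inflow_rate: float = 0.0   # mol/step of species a (singlet setups)

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"pool volume must be > 0, got {self.volume}")
        for name in ("total_a", "total_i", "total_analog",
                     "antigen_inflow_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def total(self, species: str) -> float:
        return getattr(self, f"total_{species}")

    def with_added(self, species: str, amount: float) -> "PoolState":
        return replace(self, **{f"total_{species}": self.total(species) + amount})

    def equilibrium(self, system: BindingSystem) -> EquilibriumResult:
        """Equilibrium concentrations (mol/L) of the current totals."""
        return equilibrate_with_analog(
            self.total_a / self.volume,
            self.total_i / self.volume,
            self.total_analog / self.volume,
            system,
        )


@dataclass
class RateConfig:
    secretion_rate: float = 1e-12      # mol/step per secreting cell
    boost_factor: float = 0.5          # extra fraction when boosted
    damp_factor: float = 0.25          # multiplier while starved
    uptake_rate: float = 0.01          # per-step fractional clearance/receptor
    degradation_rate: float = 0.05     # per-step pool fraction
    store_decay: float = 0.4           # per-step decay of internal stores
    hived_fraction: float = 0.2        # IC variant: synthesis kept in-cell
    endosome_volume: float = 1e-9      # L; the re-equilibration compartment

    def __post_init__(self) -> None:
        if self.secretion_rate < 0:
            raise ValueError("secretion_rate must be >= 0")
        if self.boost_factor < 0:
            raise ValueError("boost_factor must be >= 0")
        for name in ("damp_factor", "uptake_rate", "degradation_rate",
                     "store_decay", "hived_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.endosome_volume <= 0:
            raise ValueError("endosome_volume must be > 0")


@dataclass
class Ledger:
    """Cumulative per-species mass accounting.

    Closure invariant, per species: ``injected + secreted`` equals
    ``pool total + sum of cell stores + degraded + sunk + destroyed +
    removed`` to 1e-9 relative.
    """

    injected: dict = field(default_factory=lambda: dict.fromkeys(SPECIES, 0.0))
    secreted: dict = field(default_factory=lambda: dict.fromkeys(SPECIES, 0.0))
    degraded: dict = field(default_factory=lambda: dict.fromkeys(SPECIES, 0.0))
    sunk: dict = field(default_factory=lambda: dict.fromkeys(SPECIES, 0.0))
    destroyed: dict = field(default_factory=lambda: dict.fromkeys(SPECIES, 0.0))
    removed: dict = field(default_factory=lambda: dict.fromkeys(SPECIES, 0.0))
    analog_target: str = "i"

    def book(self, channel: str, species: str, amount: float) -> None:
        getattr(self, channel)[species] += amount

    def book_cell_stores(self, channel: str, cell: Cell) -> None:
        """Move a cell's entire internal content into a sink channel (used
        when a cell dies: its stores are degraded, not returned to the pool).
        """
        for s in SPECIES:
            amount = cell.species_content(s, self.analog_target)
            if amount:
                self.book(channel, s, amount)

    def cell_content(self, cells: Iterable[Cell], species: str) -> float:
        return sum(c.species_content(species, self.analog_target) for c in cells)

    def closure_errors(self, pool: PoolState,
                       cells: Iterable[Cell]) -> dict[str, float]:
        """Relative closure error per species."""
        cells = list(cells)
        errors = {}
        for s in SPECIES:
            sources = self.injected[s] + self.secreted[s]
            held = pool.total(s) + self.cell_content(cells, s)
            sinks = (self.degraded[s] + self.sunk[s] + self.destroyed[s]
                     + self.removed[s])
            scale = max(sources, 1e-30)
            errors[s] = abs(sources - held - sinks) / scale
        return errors


def _is_secreting(cell: Cell) -> bool:
    return (cell.life_state in (LifeState.CYCLING, LifeState.QUIESCENT)
            and secreted_species(cell.cell_type) is not None)


def secrete(cells: Iterable[Cell], pool: PoolState, config: RateConfig,
            variant: Variant = Variant.EC,
            ledger: Optional[Ledger] = None) -> PoolState:
    """One secretion phase.  Each live, non-dormant committed cell adds its
    species to the pool; boosted cells secrete more, starved cells less.  In
    the IC variant a fixed fraction of each cell's synthesis is hived off
    into the cell's own store instead of the pool.  Antigen inflow (if
    configured on the pool) is injected here as species ``a``."""
    added = dict.fromkeys(SPECIES, 0.0)
    for cell in cells:
        if not _is_secreting(cell):
            continue
        rate = config.secretion_rate
        if cell.boosted:
            rate *= 1.0 + config.boost_factor
        if cell.damped:
            rate *= config.damp_factor
        species = secreted_species(cell.cell_type)
        hived = 0.0
        if variant == Variant.IC:
            hived = config.hived_fraction * rate
            cell.hived_self += hived
        added[species] += rate - hived
        if ledger is not None:
            ledger.book("secreted", species, rate)
    new_pool = pool
    for s, amount in added.items():
        if amount:
            new_pool = new_pool.with_added(s, amount)
    if pool.antigen_inflow_rate > 0:
        new_pool = new_pool.with_added("a", pool.antigen_inflow_rate)
        if ledger is not None:
            ledger.book("injected", "a", pool.antigen_inflow_rate)
    return new_pool


def uptake(cell: Cell, pool: PoolState, config: RateConfig,
           system: BindingSystem) -> tuple[Cell, PoolState]:
    """Receptor-mediated internalization for one cell.

    A cell clears ``uptake_rate`` of the free partner-species amount through
    its partner receptor, the same fraction of free analog through that
    receptor when the analog mimics the partner species, and
    ``uptake_rate * tccR_count_scale`` of each complex through the scarce
    complex receptor.  Removed amounts move from the pool totals into the
    cell's internal stores; the pool is never driven negative.  Dead cells
    take nothing.
    """
    if not cell.alive:
        return cell, pool
    eq = pool.equilibrium(system)
    V = pool.volume
    u = config.uptake_rate
    r = cell.receptors

    d_free_a = u * eq.free_a * V if r.has_aR else 0.0
    d_free_i = u * eq.free_i * V if r.has_iR else 0.0
    mimic_receptor = r.has_aR if system.analog_mimics == "a" else r.has_iR
    d_analog = u * eq.free_analog * V if mimic_receptor else 0.0
    d_cai = d_cdi = 0.0
    if r.has_tccR:
        d_cai = u * r.tccR_count_scale * eq.complex_ai * V
        d_cdi = u * r.tccR_count_scale * eq.complex_di * V

    # pool totals by species; the analog complex carries one analog plus one
    # molecule of the analog's target species
    target = system.analog_target
    delta = {
        "a": d_free_a + d_cai + (d_cdi if target == "a" else 0.0),
        "i": d_free_i + d_cai + (d_cdi if target == "i" else 0.0),
        "analog": d_analog + d_cdi,
    }
    # clip defensively (cannot trigger for uptake_rate <= 1, kept as a guard)
    scale = 1.0
    for s in SPECIES:
        if delta[s] > pool.total(s) > 0:
            scale = min(scale, pool.total(s) / delta[s])
        elif delta[s] > 0 and pool.total(s) == 0:
            scale = 0.0
    if scale < 1.0:
        d_free_a *= scale
        d_free_i *= scale
        d_analog *= scale
        d_cai *= scale
        d_cdi *= scale
        delta = {s: delta[s] * scale for s in SPECIES}

    cell.internal_free_a += d_free_a
    cell.internal_free_i += d_free_i
    cell.internal_analog += d_analog
    cell.internal_complex_ai += d_cai
    cell.internal_complex_di += d_cdi
    new_pool = replace(
        pool,
        total_a=pool.total_a - delta["a"],
        total_i=pool.total_i - delta["i"],
        total_analog=pool.total_analog - delta["analog"],
    )
    return cell, new_pool


def intracellular_readout(cell: Cell, system: BindingSystem,
                          variant: Variant,
                          config: RateConfig) -> tuple[float, float]:
    """Re-equilibrate the cell's internal stores and return the
    (partner concentration, complex concentration) signal pair, in mol/L of
    the endosome compartment.

    EC variant: internalized free material and internalized complex mix and
    re-equilibrate, so the readout reflects the extracellular balance.
    IC variant: the hived-off own product mixes with the internalized
    partner species and the complex is formed in-cell.
    """
    V = config.endosome_volume
    if V <= 0:
        raise ValueError("endosome_volume must be > 0")

    own = secreted_species(cell.cell_type)
    if variant == Variant.IC:
        amt_a = cell.internal_free_a + (cell.hived_self if own == "a" else 0.0)
        amt_i = cell.internal_free_i + (cell.hived_self if own == "i" else 0.0)
        amt_d = cell.internal_analog
    else:
        amt_a = cell.internal_free_a + cell.internal_complex_ai
        amt_i = cell.internal_free_i + cell.internal_complex_ai
        amt_d = cell.internal_analog + cell.internal_complex_di
        if system.analog_target == "a":
            amt_a += cell.internal_complex_di
        else:
            amt_i += cell.internal_complex_di

    eq = equilibrate_with_analog(amt_a / V, amt_i / V, amt_d / V, system)
    complex_conc = eq.complex_ai + eq.complex_di
    if cell.cell_type == CellType.O:
        partner_conc = max(eq.free_a, eq.free_i)
    elif own == "a":
        partner_conc = eq.free_i + (
            eq.free_analog if system.analog_mimics == "i" else 0.0)
    else:
        partner_conc = eq.free_a + (
            eq.free_analog if system.analog_mimics == "a" else 0.0)
    return partner_conc, complex_conc


def degrade(pool: PoolState, config: RateConfig,
            ledger: Optional[Ledger] = None) -> PoolState:
    """First-order, species-uniform clearance of the pool."""
    d = config.degradation_rate
    if d == 0:
        return pool
    removed = {s: pool.total(s) * d for s in SPECIES}
    if ledger is not None:
        for s, amount in removed.items():
            ledger.book("degraded", s, amount)
    return replace(
        pool,
        total_a=pool.total_a - removed["a"],
        total_i=pool.total_i - removed["i"],
        total_analog=pool.total_analog - removed["analog"],
    )


_DECAY_FIELDS = (
    "internal_free_a", "internal_free_i", "internal_analog",
    "internal_complex_ai", "internal_complex_di",
)


def decay_stores(cells: Iterable[Cell], config: RateConfig,
                 system: BindingSystem,
                 ledger: Optional[Ledger] = None) -> None:
    """First-order turnover of internal stores (endosomal degradation).

    Keeps the readout tracking recent uptake instead of the whole history.
    The hived-off own store (IC variant) turns over at the same rate."""
    d = config.store_decay
    if d == 0:
        return
    target = system.analog_target
    for cell in cells:
        if not cell.alive:
            continue
        lost_a = (cell.internal_free_a + cell.internal_complex_ai) * d
        lost_i = (cell.internal_free_i + cell.internal_complex_ai) * d
        lost_d = (cell.internal_analog + cell.internal_complex_di) * d
        if target == "a":
            lost_a += cell.internal_complex_di * d
        else:
            lost_i += cell.internal_complex_di * d
        own = secreted_species(cell.cell_type)
        if cell.hived_self:
            if own == "a":
                lost_a += cell.hived_self * d
            elif own == "i":
                lost_i += cell.hived_self * d
        for name in _DECAY_FIELDS:
            setattr(cell, name, getattr(cell, name) * (1.0 - d))
        cell.hived_self *= 1.0 - d
        if ledger is not None:
            ledger.book("degraded", "a", lost_a)
            ledger.book("degraded", "i", lost_i)
            ledger.book("degraded", "analog", lost_d)
    return None
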