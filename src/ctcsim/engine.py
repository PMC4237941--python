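"""Time-stepped world loop: fixed phase order, event injection, trajectory
recording and a hard mass-ledger check every step.

Phase order within a step (fixed for reproducibility):
secrete -> degrade (pool + internal stores) -> uptake (cells in id order)
-> readouts -> decisions -> divisions -> due events -> ledger check ->
record.  All cells decide against the readout computed this step; a single
RNG stream seeded once is consumed in deterministic cell order.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .cell_model import (
    Action, Cell, CellType, LifeState, Variant, divide, make_cell,
)
from .chemistry import BindingSystem
from .decision import DecisionTable, decide, default_table, readout_levels, validate_table
from .signalling import (
    Ledger, PoolState, RateConfig, SPECIES, decay_stores, degrade,
    intracellular_readout, secrete, uptake,
)

__all__ = [
    "EventKind", "Event", "SimConfig", "SimState", "TimeSeries",
    "ConfigValidationError", "SimulationIntegrityError", "step", "run",
]

logger = logging.getLogger("ctcsim.engine")

LEDGER_RTOL = 1e-9


class EventKind(str, Enum):
    ADD_TREFONE = "ADD_TREFONE"
    SINK_TREFONE = "SINK_TREFONE"
    KILL_CYCLING = "KILL_CYCLING"
    MEDIUM_REPLACE = "MEDIUM_REPLACE"
    ANTIGEN_PULSE = "ANTIGEN_PULSE"


@dataclass(frozen=True)
class Event:
    at_step: int
    kind: EventKind
    species: str = "a"
    amount: float = 0.0
    #: MEDIUM_REPLACE only: the fresh-medium totals per species (mol)
    totals: Optional[dict] = None


class ConfigValidationError(ValueError):
    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n" + "\n".join(violations))


class SimulationIntegrityError(RuntimeError):
    """The per-step mass ledger failed to close."""


@dataclass
class SimConfig:
    variant: Variant = Variant.EC
    binding: BindingSystem = field(default_factory=lambda: BindingSystem(ka=1e10))
    rates: RateConfig = field(default_factory=RateConfig)
    table: DecisionTable = field(default_factory=default_table)
    initial_cells: dict = field(default_factory=dict)   # CellType -> count
    initial_life_state: dict = field(default_factory=dict)  # CellType -> LifeState
    volume: float = 1e-3
    initial_pool: dict = field(default_factory=dict)    # species -> mol
    antigen_inflow_rate: float = 0.0
    steps: int = 100
    seed: int = 0
    events: list = field(default_factory=list)
    tccR_count_scale: float = 0.05
    max_cells: int = 50_000

    def validate(self) -> list[str]:
        v: list[str] = []
        if self.steps < 1:
            v.append(f"steps must be >= 1, got {self.steps}")
        if self.seed is None:
            v.append("seed is mandatory")
        if self.volume <= 0:
            v.append(f"volume must be > 0, got {self.volume}")
        for ct, n in self.initial_cells.items():
            if n < 0:
                v.append(f"initial_cells[{CellType(ct).value}] must be >= 0")
        for s, amount in self.initial_pool.items():
            if s not in SPECIES:
                v.append(f"unknown pool species {s!r}")
            elif amount < 0:
                v.append(f"initial_pool[{s}] must be >= 0")
        for i, ev in enumerate(self.events):
            if not 0 <= ev.at_step < self.steps:
                v.append(f"events[{i}].at_step {ev.at_step} outside run "
                         f"[0, {self.steps})")
            if ev.amount < 0:
                v.append(f"events[{i}].amount must be >= 0")
            if ev.kind in (EventKind.ADD_TREFONE, EventKind.SINK_TREFONE,
                           EventKind.ANTIGEN_PULSE) and ev.species not in SPECIES:
                v.append(f"events[{i}].species {ev.species!r} unknown")
        v.extend(validate_table(self.table))
        return v

    def digest(self) -> str:
        """Stable hash of the full configuration, for provenance stamping."""
        payload = json.dumps(_config_fingerprint(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _config_fingerprint(config: SimConfig) -> dict:
    table = config.table
    return {
        "variant": config.variant.value,
        "binding": [config.binding.ka, config.binding.ka_analog,
                    config.binding.analog_target],
        "rates": [config.rates.secretion_rate, config.rates.boost_factor,
                  config.rates.damp_factor, config.rates.uptake_rate,
                  config.rates.degradation_rate, config.rates.store_decay,
                  config.rates.hived_fraction, config.rates.endosome_volume],
        "table": {
            "thresholds": [table.theta_partner_lo, table.theta_partner_hi,
                           table.theta_complex_lo, table.theta_complex_hi,
                           table.theta_complex_floor],
            "dwell": [table.dwell_required, table.escalation_dwell,
                      table.dediff_dwell],
            "basal_ascd_prob": table.basal_ascd_prob,
            "apo_on_extreme": table.apo_on_extreme,
            "rows": sorted(
                (ct.value, p, c, r.immediate_action.value,
                 r.prolonged_action.value, r.dwell_required, r.channel or "")
                for (ct, p, c), r in table.rows.items()
            ),
        },
        "initial_cells": sorted(
            (CellType(ct).value, n) for ct, n in config.initial_cells.items()),
        "initial_life_state": sorted(
            (CellType(ct).value, LifeState(ls).value)
            for ct, ls in config.initial_life_state.items()),
        "volume": config.volume,
        "initial_pool": sorted(config.initial_pool.items()),
        "antigen_inflow_rate": config.antigen_inflow_rate,
        "steps": config.steps,
        "seed": config.seed,
        "events": [
            (ev.at_step, ev.kind.value, ev.species, ev.amount,
             sorted((ev.totals or {}).items()))
            for ev in config.events
        ],
        "tccR_count_scale": config.tccR_count_scale,
    }


@dataclass
class SimState:
    cells: list
    pool: PoolState
    ledger: Ledger
    rng: np.random.Generator
    step_index: int = 0
    next_id: int = 0

    def take_id(self) -> int:
        i = self.next_id
        self.next_id += 1
        return i


_ACTION_COLUMNS = [f"act_{a.value}" for a in Action]
_LEDGER_CHANNELS = ("injected", "secreted", "degraded", "sunk",
                    "destroyed", "removed")


class TimeSeries:
    """Recorded trajectory: one row per step plus run-level summaries."""

    def __init__(self, config: SimConfig):
        self.rows: list[dict] = []
        self.action_totals: dict[tuple[CellType, Action], int] = {}
        self.config = config
        self.config_digest = config.digest()
        self.seed = config.seed
        self.final_cells: list[Cell] = []
        self.final_pool: Optional[PoolState] = None
        self.ledger: Optional[Ledger] = None

    def tally(self, cell_type: CellType, action: Action) -> None:
        key = (cell_type, action)
        self.action_totals[key] = self.action_totals.get(key, 0) + 1

    def action_count(self, cell_type: Optional[CellType] = None,
                     action: Optional[Action] = None) -> int:
        return sum(
            n for (ct, a), n in self.action_totals.items()
            if (cell_type is None or ct == cell_type)
            and (action is None or a == action)
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.columns())

    @staticmethod
    def columns() -> list[str]:
        cols = ["step"]
        cols += [f"n_{ct.value}" for ct in CellType]
        cols += ["n_cycling", "n_quiescent", "n_dormant", "n_dead", "n_alive"]
        cols += [f"total_{s}" for s in SPECIES]
        cols += ["free_a", "free_i", "free_analog", "complex_ai", "complex_di"]
        # per-type counts of the three decision-relevant readout classes
        for ct in CellType:
            cols += [f"n_pHi_cLo_{ct.value}", f"n_pLo_cLo_{ct.value}",
                     f"n_cHi_{ct.value}"]
        cols += _ACTION_COLUMNS
        cols += [f"cells_{s}" for s in SPECIES]   # summed internal stores
        for channel in _LEDGER_CHANNELS:
            cols += [f"{channel}_{s}" for s in SPECIES]
        return cols

    def summary(self) -> dict:
        last = self.rows[-1] if self.rows else {}
        return {
            "config_digest": self.config_digest,
            "seed": self.seed,
            "steps": len(self.rows),
            "final_counts": {ct.value: last.get(f"n_{ct.value}", 0)
                             for ct in CellType},
            "final_alive": last.get("n_alive", 0),
            "action_totals": {
                f"{ct.value}:{a.value}": n
                for (ct, a), n in sorted(self.action_totals.items(),
                                         key=lambda kv: (kv[0][0].value,
                                                         kv[0][1].value))
            },
            "ledger": {
                channel: dict(getattr(self.ledger, channel))
                for channel in _LEDGER_CHANNELS
            } if self.ledger is not None else {},
        }


def _initial_state(config: SimConfig) -> SimState:
    ledger = Ledger(analog_target=config.binding.analog_target)
    pool = PoolState(
        volume=config.volume,
        total_a=config.initial_pool.get("a", 0.0),
        total_i=config.initial_pool.get("i", 0.0),
        total_analog=config.initial_pool.get("analog", 0.0),
        antigen_inflow_rate=config.antigen_inflow_rate,
    )
    for s in SPECIES:
        if pool.total(s):
            ledger.book("injected", s, pool.total(s))
    cells: list[Cell] = []
    next_id = itertools.count()
    for ct in CellType:   # fixed type order for deterministic ids
        n = config.initial_cells.get(ct, config.initial_cells.get(ct.value, 0))
        life = config.initial_life_state.get(
            ct, config.initial_life_state.get(ct.value, LifeState.CYCLING))
        for _ in range(int(n)):
            cells.append(make_cell(
                ct, config.variant, id=next(next_id),
                tccR_count_scale=config.tccR_count_scale,
                life_state=LifeState(life),
            ))
    return SimState(
        cells=cells, pool=pool, ledger=ledger,
        rng=np.random.default_rng(config.seed),
        next_id=len(cells),
    )


def _apply_event(event: Event, state: SimState, config: SimConfig) -> None:
    pool, ledger = state.pool, state.ledger
    if event.kind in (EventKind.ADD_TREFONE, EventKind.ANTIGEN_PULSE):
        species = event.species if event.kind == EventKind.ADD_TREFONE else "a"
        state.pool = pool.with_added(species, event.amount)
        ledger.book("injected", species, event.amount)
    elif event.kind == EventKind.SINK_TREFONE:
        taken = min(event.amount, pool.total(event.species))
        state.pool = pool.with_added(event.species, -taken)
        ledger.book("sunk", event.species, taken)
    elif event.kind == EventKind.KILL_CYCLING:
        killed = 0
        for cell in state.cells:
            if cell.life_state == LifeState.CYCLING:
                ledger.book_cell_stores("destroyed", cell)
                _zero_stores(cell)
                cell.life_state = LifeState.DEAD
                killed += 1
        logger.info("step %d: KILL_CYCLING killed %d cells",
                    state.step_index, killed)
    elif event.kind == EventKind.MEDIUM_REPLACE:
        for s in SPECIES:
            ledger.book("removed", s, pool.total(s))
        totals = event.totals or {}
        state.pool = PoolState(
            volume=pool.volume,
            total_a=totals.get("a", 0.0),
            total_i=totals.get("i", 0.0),
            total_analog=totals.get("analog", 0.0),
            antigen_inflow_rate=pool.antigen_inflow_rate,
        )
        for s in SPECIES:
            if state.pool.total(s):
                ledger.book("injected", s, state.pool.total(s))
    else:  # pragma: no cover
        raise ValueError(f"unknown event kind {event.kind!r}")
    logger.info("step %d: fired %s", state.step_index, event.kind.value)


def _zero_stores(cell: Cell) -> None:
    cell.internal_free_a = cell.internal_free_i = cell.internal_analog = 0.0
    cell.internal_complex_ai = cell.internal_complex_di = 0.0
    cell.hived_self = 0.0


def step(state: SimState, config: SimConfig,
         timeseries: Optional[TimeSeries] = None) -> SimState:
    """Advance the world by one step (mutates and returns ``state``)."""
    ledger = state.ledger
    t = state.step_index

    # 1-2: secretion then clearance
    state.pool = secrete(state.cells, state.pool, config.rates,
                         config.variant, ledger)
    state.pool = degrade(state.pool, config.rates, ledger)
    decay_stores(state.cells, config.rates, config.binding, ledger)

    # 3-4: receptor-mediated uptake, deterministic id order
    for cell in sorted(state.cells, key=lambda c: c.id):
        if cell.alive:
            _, state.pool = uptake(cell, state.pool, config.rates,
                                   config.binding)

    # 5-6: readout and decision on this step's internal state
    actions_by_id: dict[int, Action] = {}
    for cell in sorted(state.cells, key=lambda c: c.id):
        if not cell.alive:
            continue
        partner_conc, complex_conc = intracellular_readout(
            cell, config.binding, config.variant, config.rates)
        p_level, c_level = readout_levels(partner_conc, complex_conc,
                                          config.table)
        actions_by_id[cell.id] = decide(cell, p_level, c_level,
                                        config.table, state.rng)

    # 7: apply fates
    action_tally = dict.fromkeys(Action, 0)
    new_cells: list[Cell] = []
    id_source = _StateIds(state)
    for cell in state.cells:
        if not cell.alive:
            new_cells.append(cell)     # corpses stay on the books
            continue
        action = actions_by_id[cell.id]
        action_tally[action] += 1
        if timeseries is not None:
            timeseries.tally(cell.cell_type, action)
        if action == Action.APO:
            ledger.book_cell_stores("destroyed", cell)
            _zero_stores(cell)
            cell.life_state = LifeState.DEAD
            new_cells.append(cell)     # now DEAD, kept for the record
        elif action == Action.DEDIFF:
            new_cells.append(divide_dediff(cell, config))
        else:
            new_cells.extend(divide(cell, action, state.rng,
                                    id_source=id_source))
    state.cells = new_cells
    if sum(1 for c in state.cells if c.alive) > config.max_cells:
        raise RuntimeError(
            f"population exceeded max_cells={config.max_cells} at step {t}")

    # 8: events scheduled for this step
    for event in config.events:
        if event.at_step == t:
            _apply_event(event, state, config)

    # 9: ledger integrity
    errors = ledger.closure_errors(state.pool, state.cells)
    worst = max(errors.values())
    if worst > LEDGER_RTOL:
        raise SimulationIntegrityError(
            f"mass ledger failed to close at step {t}: {errors}")

    if timeseries is not None:
        timeseries.rows.append(_record_row(state, config, action_tally))
    state.step_index += 1
    return state


class _StateIds:
    def __init__(self, state: SimState):
        self._state = state

    def __next__(self) -> int:
        return self._state.take_id()

    def __iter__(self):  # pragma: no cover
        return self


def divide_dediff(cell: Cell, config: SimConfig) -> Cell:
    from .cell_model import apply_dedifferentiation
    return apply_dedifferentiation(cell, dediff_dwell=config.table.dediff_dwell)


def _record_row(state: SimState, config: SimConfig,
                action_tally: dict) -> dict:
    eq = state.pool.equilibrium(config.binding)
    alive = [c for c in state.cells if c.alive]
    row: dict = {"step": state.step_index}
    for ct in CellType:
        row[f"n_{ct.value}"] = sum(1 for c in alive if c.cell_type == ct)
    for ls, name in ((LifeState.CYCLING, "n_cycling"),
                     (LifeState.QUIESCENT, "n_quiescent"),
                     (LifeState.DORMANT, "n_dormant"),
                     (LifeState.DEAD, "n_dead")):
        row[name] = sum(1 for c in state.cells if c.life_state == ls)
    row["n_alive"] = len(alive)
    for s in SPECIES:
        row[f"total_{s}"] = state.pool.total(s)
    row["free_a"] = eq.free_a
    row["free_i"] = eq.free_i
    row["free_analog"] = eq.free_analog
    row["complex_ai"] = eq.complex_ai
    row["complex_di"] = eq.complex_di
    for ct in CellType:
        of_type = [c for c in alive if c.cell_type == ct]
        row[f"n_pHi_cLo_{ct.value}"] = sum(
            1 for c in of_type
            if (c.last_partner_level, c.last_complex_level) == ("Hi", "Lo"))
        row[f"n_pLo_cLo_{ct.value}"] = sum(
            1 for c in of_type
            if (c.last_partner_level, c.last_complex_level) == ("Lo", "Lo"))
        row[f"n_cHi_{ct.value}"] = sum(
            1 for c in of_type if c.last_complex_level == "Hi")
    for a in Action:
        row[f"act_{a.value}"] = action_tally.get(a, 0)
    for s in SPECIES:
        row[f"cells_{s}"] = state.ledger.cell_content(state.cells, s)
    for channel in _LEDGER_CHANNELS:
        for s in SPECIES:
            row[f"{channel}_{s}"] = getattr(state.ledger, channel)[s]
    return row


def run(config: SimConfig) -> TimeSeries:
    """Run the full trajectory from the configured initial state."""
    violations = config.validate()
    if violations:
        raise ConfigValidationError(violations)
    started = time.perf_counter()
    state = _initial_state(config)
    ts = TimeSeries(config)
    for _ in range(config.steps):
        state = step(state, config, ts)
    ts.final_cells = state.cells
    ts.final_pool = state.pool
    ts.ledger = state.ledger
    logger.info(
        "run %s (seed %d): %d steps, %d cells alive, %.3fs",
        ts.config_digest, config.seed, config.steps,
        sum(1 for c in state.cells if c.alive),
        time.perf_counter() - started,
    )
    return ts
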