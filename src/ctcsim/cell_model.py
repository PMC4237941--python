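"""Cell agents: receptor profiles, marker strings and the division catalogue.

A couplet lineage starts from a progenitor (``O``) whose first asymmetric
division commits one child to each side of the couplet (``A`` and ``I``).
Each committed cell secretes one species and carries the receptor for the
*other* species — never for its own.  ``SINGLET`` cells are half-couplets:
they secrete the ``i``-like species (an antibody) against an exogenous
``a``-like species (an antigen) supplied by no cell.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Optional

__all__ = [
    "CellType", "Variant", "LifeState", "Action", "ReceptorProfile", "Cell",
    "make_cell", "marker_string", "parse_marker_string", "divide",
    "apply_dedifferentiation", "partner_species", "secreted_species",
]


class CellType(str, Enum):
    O = "O"
    A = "A"
    I = "I"
    SINGLET = "SINGLET"


class Variant(str, Enum):
    """EC senses the extracellular complex via a scarce membrane receptor;
    IC forms the complex intracellularly from a hived-off fraction of the
    cell's own product plus the internalized partner species."""

    EC = "EC"
    IC = "IC"


class LifeState(str, Enum):
    CYCLING = "CYCLING"
    QUIESCENT = "QUIESCENT"
    DORMANT = "DORMANT"
    DEAD = "DEAD"


class Action(str, Enum):
    BOOST_SECRETION = "BOOST_SECRETION"
    SCD_SRE = "SCD_SRE"                    # symmetric self-renewal
    ASCD_SELF_PARTNER = "ASCD_SELF_PARTNER"
    ASCD_PARTNER_PARTNER = "ASCD_PARTNER_PARTNER"
    ASCD_DUAL_LCDF = "ASCD_DUAL_LCDF"      # progenitor -> one of each side
    TD_SCD = "TD_SCD"                      # transdifferentiate + divide
    APO = "APO"
    QSC = "QSC"
    DEDIFF = "DEDIFF"


#: Actions that replace the parent with one or two offspring.
DIVISION_ACTIONS = frozenset({
    Action.SCD_SRE, Action.ASCD_SELF_PARTNER, Action.ASCD_PARTNER_PARTNER,
    Action.ASCD_DUAL_LCDF, Action.TD_SCD,
})

_PARTNER_TYPE = {CellType.A: CellType.I, CellType.I: CellType.A}

_PARTNER_SPECIES = {CellType.A: "i", CellType.I: "a", CellType.SINGLET: "a"}
_SECRETED_SPECIES = {CellType.A: "a", CellType.I: "i", CellType.SINGLET: "i"}


def partner_species(cell_type: CellType) -> Optional[str]:
    """Species this cell type listens to (None for the progenitor, which
    carries both receptors)."""
    return _PARTNER_SPECIES.get(cell_type)


def secreted_species(cell_type: CellType) -> Optional[str]:
    return _SECRETED_SPECIES.get(cell_type)


@dataclass(frozen=True)
class ReceptorProfile:
    has_aR: bool
    has_iR: bool
    has_tccR: bool
    #: relative abundance of the complex receptor; it is scarce by design
    tccR_count_scale: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.tccR_count_scale <= 1:
            raise ValueError(
                f"tccR_count_scale must be in [0, 1], got {self.tccR_count_scale}"
            )


@dataclass
class Cell:
    id: int
    cell_type: CellType
    variant: Variant
    receptors: ReceptorProfile
    # internal stores, in mol (amounts, not concentrations)
    internal_free_a: float = 0.0
    internal_free_i: float = 0.0
    internal_analog: float = 0.0
    internal_complex_ai: float = 0.0
    internal_complex_di: float = 0.0
    hived_self: float = 0.0        # IC variant: retained own product
    dwell_hi: int = 0              # consecutive steps of Hi stimulatory readout
    dwell_starved: int = 0         # consecutive steps of Lo/Lo readout
    life_state: LifeState = LifeState.CYCLING
    generation: int = 0
    boosted: bool = False          # secretion boost flag, set by the decider
    damped: bool = False           # secretion damping flag (starvation)
    last_partner_level: str = "Lo"
    last_complex_level: str = "Lo"

    @property
    def alive(self) -> bool:
        return self.life_state != LifeState.DEAD

    def species_content(self, species: str, analog_target: str = "i") -> float:
        """Total internal amount of one species, counting bound molecules.

        The couplet complex holds one molecule of each couplet species; the
        analog complex holds one analog plus one molecule of whichever
        couplet species the analog targets."""
        if species == "a":
            return (
                self.internal_free_a + self.internal_complex_ai
                + (self.internal_complex_di if analog_target == "a" else 0.0)
                + (self.hived_self
                   if secreted_species(self.cell_type) == "a" else 0.0)
            )
        if species == "i":
            return (
                self.internal_free_i + self.internal_complex_ai
                + (self.internal_complex_di if analog_target == "i" else 0.0)
                + (self.hived_self
                   if secreted_species(self.cell_type) == "i" else 0.0)
            )
        if species == "analog":
            return self.internal_analog + self.internal_complex_di
        raise ValueError(f"unknown species {species!r}")


def _profile_for(cell_type: CellType, variant: Variant,
                 tccR_count_scale: float) -> ReceptorProfile:
    has_tccR = variant == Variant.EC
    if cell_type == CellType.A:
        return ReceptorProfile(has_aR=False, has_iR=True, has_tccR=has_tccR,
                               tccR_count_scale=tccR_count_scale)
    if cell_type in (CellType.I, CellType.SINGLET):
        return ReceptorProfile(has_aR=True, has_iR=False, has_tccR=has_tccR,
                               tccR_count_scale=tccR_count_scale)
    if cell_type == CellType.O:
        # progenitor convention: both receptors present (weakly) so the cell
        # can respond to either species
        return ReceptorProfile(has_aR=True, has_iR=True, has_tccR=has_tccR,
                               tccR_count_scale=tccR_count_scale)
    raise ValueError(f"unknown cell type {cell_type!r}")


def make_cell(cell_type: CellType | str, variant: Variant | str, *,
              id: int = 0, tccR_count_scale: float = 0.05,
              life_state: LifeState = LifeState.CYCLING,
              generation: int = 0) -> Cell:
    """Build a cell with the receptor profile implied by its type/variant."""
    cell_type = CellType(cell_type)
    variant = Variant(variant)
    return Cell(
        id=id, cell_type=cell_type, variant=variant,
        receptors=_profile_for(cell_type, variant, tccR_count_scale),
        life_state=life_state, generation=generation,
    )


def marker_string(cell: Cell) -> str:
    """Render the receptor profile as an ASCII marker string, e.g.
    ``"iR+ aR- tccR+"``."""
    r = cell.receptors
    return (
        f"iR{'+' if r.has_iR else '-'} "
        f"aR{'+' if r.has_aR else '-'} "
        f"tccR{'+' if r.has_tccR else '-'}"
    )


_MARKER_RE = re.compile(r"^iR([+-]) aR([+-]) tccR([+-])$")


def parse_marker_string(text: str, tccR_count_scale: float = 0.05) -> ReceptorProfile:
    m = _MARKER_RE.match(text.strip())
    if m is None:
        raise ValueError(f"not a marker string: {text!r}")
    return ReceptorProfile(
        has_iR=m.group(1) == "+",
        has_aR=m.group(2) == "+",
        has_tccR=m.group(3) == "+",
        tccR_count_scale=tccR_count_scale,
    )


_STORE_FIELDS = (
    "internal_free_a", "internal_free_i", "internal_analog",
    "internal_complex_ai", "internal_complex_di", "hived_self",
)


def _child(parent: Cell, cell_type: CellType, cell_id: int, share: float) -> Cell:
    child = make_cell(
        cell_type, parent.variant, id=cell_id,
        tccR_count_scale=parent.receptors.tccR_count_scale,
        generation=parent.generation + 1,
    )
    for name in _STORE_FIELDS:
        setattr(child, name, getattr(parent, name) * share)
    # the hived store is labelled by the secreting type; a child of another
    # type keeps the molecules but as plain internal free material of the
    # parent's species, so the mass ledger stays species-correct
    if parent.hived_self and secreted_species(cell_type) != \
            secreted_species(parent.cell_type):
        moved = child.hived_self
        child.hived_self = 0.0
        if secreted_species(parent.cell_type) == "a":
            child.internal_free_a += moved
        elif secreted_species(parent.cell_type) == "i":
            child.internal_free_i += moved
    # starvation memory is inherited so that prolonged deprivation can
    # escalate across a division; the stimulatory dwell is reset
    child.dwell_starved = parent.dwell_starved
    child.dwell_hi = 0
    return child


def divide(cell: Cell, action: Action, rng=None, *,
           id_source: Optional[Iterator[int]] = None) -> list[Cell]:
    """Apply a fate action and return the resulting cell list.

    Division actions replace the parent by offspring (internal stores split
    equally); APO returns an empty list and marks the parent DEAD; QSC and
    BOOST_SECRETION leave the parent untouched.  ``rng`` is accepted for
    interface stability (all current fates are deterministic given the
    action)."""
    if not cell.alive:
        raise ValueError(f"cell {cell.id} is DEAD and cannot act")
    if id_source is None:
        id_source = itertools.count(cell.id * 1000 + 1)

    if action in (Action.QSC, Action.BOOST_SECRETION):
        return [cell]
    if action == Action.APO:
        cell.life_state = LifeState.DEAD
        return []
    if action == Action.DEDIFF:
        return [apply_dedifferentiation(cell, dediff_dwell=cell.dwell_starved)]

    t = cell.cell_type
    if action == Action.SCD_SRE:
        types = [t, t]
    elif action == Action.ASCD_DUAL_LCDF:
        if t != CellType.O:
            raise ValueError("ASCD_DUAL_LCDF is reserved for O-cells")
        types = [CellType.A, CellType.I]
    elif action in (Action.ASCD_SELF_PARTNER, Action.ASCD_PARTNER_PARTNER,
                    Action.TD_SCD):
        partner = _PARTNER_TYPE.get(t)
        if partner is None:
            raise ValueError(f"{action.value} undefined for cell type {t.value}")
        if action == Action.ASCD_SELF_PARTNER:
            types = [t, partner]
        else:  # both ASCD_PARTNER_PARTNER and TD_SCD extinguish the parent type
            types = [partner, partner]
    else:  # pragma: no cover
        raise ValueError(f"unknown action {action!r}")

    return [_child(cell, ct, next(id_source), 0.5) for ct in types]


def apply_dedifferentiation(cell: Cell, dediff_dwell: int = 0) -> Cell:
    """Return the cell reverted to the progenitor state.

    Preserves id, generation and internal stores (mass is conserved); resets
    receptors to the progenitor profile and clears dwell counters.  Calling
    this on a cell whose starvation dwell has not reached ``dediff_dwell``
    is a contract violation.  O-cells pass through unchanged.
    """
    if cell.cell_type == CellType.O:
        return cell
    if cell.dwell_starved < dediff_dwell:
        raise ValueError(
            f"dedifferentiation requires dwell_starved >= {dediff_dwell}, "
            f"cell {cell.id} has {cell.dwell_starved}"
        )
    reverted = replace(
        cell,
        cell_type=CellType.O,
        receptors=_profile_for(CellType.O, cell.variant,
                               cell.receptors.tccR_count_scale),
        dwell_hi=0,
        dwell_starved=0,
        boosted=False,
        damped=False,
    )
    # progenitors secrete nothing: relabel any hived store as plain internal
    # material of the formerly secreted species (mass stays on the books)
    if reverted.hived_self:
        own = secreted_species(cell.cell_type)
        if own == "a":
            reverted.internal_free_a += reverted.hived_self
        elif own == "i":
            reverted.internal_free_i += reverted.hived_self
        reverted.hived_self = 0.0
    return reverted
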