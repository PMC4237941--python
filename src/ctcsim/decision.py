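"""The decision table: (cell type, partner level, complex level) -> action.

The two readout channels are discretized independently.  The partner
channel is an absolute endosomal concentration.  The complex channel is the
*fraction* of the readout held in complex, ``complex / (partner + complex)``
— a cell judges its complex level relative to the free partner signal, in
the spirit of ratio-sensing receptors, so "Hi complex" means "the couplet
is saturated", not "a lot of complex in absolute terms".

Semantics of a row: ``immediate_action`` applies as soon as the readout
matches; ``prolonged_action`` fires once the matching readout has persisted
for ``dwell_required`` consecutive steps.  Two dwell channels exist:

* ``hi``     — consecutive steps with a Hi partner readout (stimulation);
  the counter resets when the prolonged action fires.
* ``starved``— consecutive steps of Lo/Lo readout (deprivation); the
  counter does *not* reset on firing, so deprivation can escalate:
  produce-a-partner division, then partner-only division, then
  dedifferentiation back to the progenitor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .cell_model import (
    Action, Cell, CellType, DIVISION_ACTIONS, LifeState,
)
from .chemistry import LEVELS, discretize_level

__all__ = [
    "DecisionRow", "DecisionTable", "default_table", "decide",
    "validate_table", "readout_levels",
]

_COMMITTED = (CellType.A, CellType.I, CellType.SINGLET)


@dataclass(frozen=True)
class DecisionRow:
    immediate_action: Action
    prolonged_action: Action
    dwell_required: int = 1
    channel: Optional[str] = None      # "hi", "starved" or None (no dwell)

    def __post_init__(self) -> None:
        # a division row with dwell_required < 1 is representable but
        # ill-formed; validate_table reports it
        if self.channel not in (None, "hi", "starved"):
            raise ValueError(f"unknown dwell channel {self.channel!r}")


@dataclass
class DecisionTable:
    rows: dict[tuple[CellType, str, str], DecisionRow] = field(default_factory=dict)
    default_row: Optional[DecisionRow] = field(
        default_factory=lambda: DecisionRow(Action.QSC, Action.QSC))
    # partner channel thresholds (endosomal mol/L)
    theta_partner_lo: float = 5e-4
    theta_partner_hi: float = 1.2e-3
    # complex channel thresholds (dimensionless bound fraction)
    theta_complex_lo: float = 0.25
    theta_complex_hi: float = 0.6
    # absolute floor (endosomal mol/L): below it the complex channel reads
    # Lo no matter the bound fraction — an emptying endosome is a Lo-complex
    # endosome even if what little remains is mostly bound
    theta_complex_floor: float = 2e-4
    dwell_required: int = 5
    escalation_dwell: int = 15         # Lo/Lo: partner-only division fires here
    dediff_dwell: int = 50             # Lo/Lo: dedifferentiation fires here
    basal_ascd_prob: float = 0.0       # Mid/Mid homeostatic basal AsCD
    apo_on_extreme: bool = True        # Hi/Hi prolonged -> apoptosis

    def __post_init__(self) -> None:
        if not 0 <= self.basal_ascd_prob <= 1:
            raise ValueError("basal_ascd_prob must be in [0, 1]")

    def lookup(self, cell_type: CellType, partner_level: str,
               complex_level: str) -> DecisionRow:
        row = self.rows.get((cell_type, partner_level, complex_level))
        if row is None:
            row = self.default_row
        if row is None:
            raise KeyError(
                f"no decision row for ({cell_type.value}, {partner_level}, "
                f"{complex_level}) and no default row"
            )
        return row


def default_table(*, dwell_required: int = 5, basal_ascd_prob: float = 0.02,
                  apo_on_extreme: bool = True, **thresholds) -> DecisionTable:
    """The built-in rule set for committed couplet cells and progenitors.

    Committed cells (A, I and the immune singlet):

    * Hi partner, Lo/Mid complex — the partner family is abundant relative
      to the couplet complex: boost secretion now, divide symmetrically
      once the stimulus has persisted.
    * Lo/Lo — deprivation: damp secretion, then divide asymmetrically to
      regenerate the missing partner family, escalating to a partner-only
      division and finally to dedifferentiation.
    * Hi complex — the couplet is saturated: quiesce; a prolonged Hi/Hi
      extreme triggers apoptosis (configurable).
    * Mid/Mid — homeostasis: quiesce, with a small basal asymmetric
      division probability.

    Progenitors (O) commit via a dual lineage division whenever either
    species is sensed, and otherwise wait.
    """
    table = DecisionTable(
        dwell_required=dwell_required,
        escalation_dwell=3 * dwell_required,
        dediff_dwell=10 * dwell_required,
        basal_ascd_prob=basal_ascd_prob,
        apo_on_extreme=apo_on_extreme,
        **thresholds,
    )
    rows = table.rows
    qsc = DecisionRow(Action.QSC, Action.QSC)
    for ct in _COMMITTED:
        grow = DecisionRow(Action.BOOST_SECRETION, Action.SCD_SRE,
                           dwell_required=dwell_required, channel="hi")
        rows[(ct, "Hi", "Lo")] = grow
        rows[(ct, "Hi", "Mid")] = grow
        rows[(ct, "Hi", "Hi")] = DecisionRow(
            Action.QSC, Action.APO if apo_on_extreme else Action.QSC,
            dwell_required=dwell_required, channel="hi")
        # a singlet has no partner type to regenerate: it just waits out
        # deprivation; couplet cells escalate through the starvation ladder
        rows[(ct, "Lo", "Lo")] = DecisionRow(
            Action.QSC,
            Action.QSC if ct == CellType.SINGLET else Action.ASCD_SELF_PARTNER,
            dwell_required=dwell_required, channel="starved")
        rows[(ct, "Mid", "Mid")] = DecisionRow(
            Action.QSC, Action.QSC)  # basal AsCD sampled in decide()
        for key in (("Lo", "Mid"), ("Lo", "Hi"), ("Mid", "Lo"), ("Mid", "Hi")):
            rows[(ct, *key)] = qsc
    o_commit = DecisionRow(Action.QSC, Action.ASCD_DUAL_LCDF,
                           dwell_required=1, channel="hi")
    for p in LEVELS:
        for c in LEVELS:
            rows[(CellType.O, p, c)] = qsc if (p, c) == ("Lo", "Lo") else o_commit
    return table


def readout_levels(partner_conc: float, complex_conc: float,
                   table: DecisionTable) -> tuple[str, str]:
    """Discretize the raw readout pair into table levels."""
    partner_level = discretize_level(
        partner_conc, table.theta_partner_lo, table.theta_partner_hi)
    if complex_conc < table.theta_complex_floor:
        return partner_level, "Lo"
    total = partner_conc + complex_conc
    bound_fraction = complex_conc / total if total > 0 else 0.0
    complex_level = discretize_level(
        bound_fraction, table.theta_complex_lo, table.theta_complex_hi)
    return partner_level, complex_level


def decide(cell: Cell, partner_level: str, complex_level: str,
           table: DecisionTable, rng) -> Action:
    """Update the cell's dwell counters and secretion flags, and return the
    action for this step.  Pure in its inputs: byte-identical cell state,
    levels, table and RNG state give the identical action."""
    if not cell.alive:
        raise ValueError(f"cell {cell.id} is DEAD")
    cell.last_partner_level = partner_level
    cell.last_complex_level = complex_level

    if cell.life_state == LifeState.DORMANT:
        if partner_level == "Hi":
            cell.life_state = LifeState.CYCLING   # reawakening
        else:
            return Action.QSC

    row = table.lookup(cell.cell_type, partner_level, complex_level)

    # dwell bookkeeping: each channel counts consecutive matching steps
    if row.channel == "hi":
        cell.dwell_hi += 1
        cell.dwell_starved = 0
    elif row.channel == "starved":
        cell.dwell_starved += 1
        cell.dwell_hi = 0
    else:
        cell.dwell_hi = 0
        cell.dwell_starved = 0

    action = row.immediate_action
    if row.channel == "hi":
        if cell.dwell_hi >= row.dwell_required:
            action = row.prolonged_action
            cell.dwell_hi = 0
    elif row.channel == "starved" and row.prolonged_action in DIVISION_ACTIONS:
        # escalation ladder on an unreset counter; divisions fire once at
        # each rung, dedifferentiation is the terminal state
        if cell.dwell_starved >= table.dediff_dwell:
            action = Action.DEDIFF
        elif cell.dwell_starved == table.escalation_dwell:
            action = Action.ASCD_PARTNER_PARTNER
        elif cell.dwell_starved == row.dwell_required:
            action = row.prolonged_action
    elif (cell.cell_type in (CellType.A, CellType.I)
            and (partner_level, complex_level) == ("Mid", "Mid")
            and table.basal_ascd_prob > 0):
        if rng.random() < table.basal_ascd_prob:
            action = Action.ASCD_SELF_PARTNER

    cell.damped = (row.channel == "starved" and action == Action.QSC)
    cell.boosted = action == Action.BOOST_SECRETION
    return action


def validate_table(table: DecisionTable) -> list[str]:
    """Return diagnostics; empty iff the table is well-formed."""
    diagnostics: list[str] = []
    if table.default_row is None:
        for ct in CellType:
            for p in LEVELS:
                for c in LEVELS:
                    if (ct, p, c) not in table.rows:
                        diagnostics.append(
                            f"missing row ({ct.value}, {p}, {c}) "
                            "and no default row"
                        )
    for key, row in table.rows.items():
        if (row.prolonged_action in DIVISION_ACTIONS
                and row.dwell_required < 1):
            diagnostics.append(
                f"row {key}: division action {row.prolonged_action.value} "
                "with dwell_required < 1"
            )
        if (row.prolonged_action != row.immediate_action
                and row.channel is None):
            diagnostics.append(
                f"row {key}: prolonged action "
                f"{row.prolonged_action.value} is unreachable "
                "(no dwell channel)"
            )
    if not (0 <= table.theta_partner_lo < table.theta_partner_hi):
        diagnostics.append("partner thresholds must satisfy 0 <= lo < hi")
    if not (0 <= table.theta_complex_lo < table.theta_complex_hi):
        diagnostics.append("complex thresholds must satisfy 0 <= lo < hi")
    if not table.dwell_required >= 1:
        diagnostics.append("dwell_required must be >= 1")
    if not (table.escalation_dwell > table.dwell_required):
        diagnostics.append("escalation_dwell must exceed dwell_required")
    if not (table.dediff_dwell > table.escalation_dwell):
        diagnostics.append("dediff_dwell must exceed escalation_dwell")
    return diagnostics
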