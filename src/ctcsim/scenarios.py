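"""Canned scenario configurations and their assertion harnesses.

Each scenario builds a frozen configuration (config + seed are the
regression fixture), runs the engine, evaluates its assertions and returns
a :class:`ScenarioReport`.  Every scenario with an A/I asymmetry accepts
``mirror=True``, which swaps the two couplet roles everywhere (species,
receptors, initial populations, event species) and must pass identically.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Optional

from .cell_model import (
    Action, CellType, Variant, divide, make_cell,
)
from .cli_io import ConfigDocument, config_to_document
from .decision import readout_levels
from .engine import TimeSeries, run
from .signalling import intracellular_readout

__all__ = [
    "ScenarioAssertion", "ScenarioReport", "SCENARIOS",
    "scenario_balanced_perturbation", "scenario_monoculture_conversion",
    "scenario_analog_potency", "scenario_trefone_sink",
    "scenario_blastomere_lineage", "scenario_persisters",
    "scenario_singlet_immune", "run_scenario",
]


@dataclass
class ScenarioAssertion:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class ScenarioReport:
    scenario: str
    seed: int
    mirrored: bool = False
    config_digests: dict = field(default_factory=dict)
    assertions: list = field(default_factory=list)
    observables: dict = field(default_factory=dict)
    timeseries: dict = field(default_factory=dict, repr=False)

    @property
    def passed(self) -> bool:
        return all(a.passed for a in self.assertions)

    def check(self, name: str, condition: bool, detail: str = "") -> None:
        self.assertions.append(ScenarioAssertion(name, bool(condition), detail))

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "seed": self.seed,
            "mirrored": self.mirrored,
            "passed": self.passed,
            "config_digests": dict(self.config_digests),
            "assertions": [
                {"name": a.name, "passed": a.passed, "detail": a.detail}
                for a in self.assertions
            ],
            "observables": self.observables,
        }


# --------------------------------------------------------------------------
# document plumbing

def _deep_set(doc: dict, dotted: str, value) -> None:
    parts = dotted.split(".")
    node = doc
    for key in parts[:-1]:
        node = node.setdefault(key, {})
    node[parts[-1]] = value


def _apply_overrides(doc: dict, overrides: Optional[dict]) -> dict:
    if overrides:
        for key, value in overrides.items():
            _deep_set(doc, key, value)
    return doc


_SWAP_TYPE = {"A": "I", "I": "A"}
_SWAP_SPECIES = {"a": "i", "i": "a"}


def _mirror_doc(doc: dict) -> dict:
    """Swap the two couplet roles throughout a config document."""
    doc = copy.deepcopy(doc)
    for section in ("initial_cells", "initial_life_state"):
        if section in doc:
            doc[section] = {
                _SWAP_TYPE.get(k, k): v for k, v in doc[section].items()
            }
    pool = doc.get("pool", {})
    a, i = pool.get("total_a", 0.0), pool.get("total_i", 0.0)
    pool["total_a"], pool["total_i"] = i, a
    doc["pool"] = pool
    binding = doc.get("binding", {})
    binding["analog_target"] = _SWAP_SPECIES.get(
        binding.get("analog_target", "i"))
    doc["binding"] = binding
    for ev in doc.get("events", []):
        ev["species"] = _SWAP_SPECIES.get(ev.get("species", "a"),
                                          ev.get("species", "a"))
        if ev.get("totals"):
            t = ev["totals"]
            ev["totals"] = {
                "a": t.get("i", 0.0), "i": t.get("a", 0.0),
                **({"analog": t["analog"]} if "analog" in t else {}),
            }
    for row in doc.get("table", {}).get("rows", []):
        row["cell_type"] = _SWAP_TYPE.get(row["cell_type"], row["cell_type"])
    return doc


def _build_and_run(doc: dict, report: ScenarioReport, label: str) -> TimeSeries:
    document = config_to_document(doc)
    config = document.build()
    ts = run(config)
    report.config_digests[label] = ts.config_digest
    report.timeseries[label] = ts
    return ts


def _roles(mirror: bool) -> dict:
    """Role mapping: 'grown' names the side whose species was spiked away
    from, i.e. the responder population."""
    if not mirror:
        return {"spike_species": "a", "responder": "I", "other": "A"}
    return {"spike_species": "i", "responder": "A", "other": "I"}


# --------------------------------------------------------------------------
# baseline homeostatic configuration (shared by several scenarios)

HOMEOSTASIS_N = 24
SECRETION_RATE = 1e-12
DEGRADATION_RATE = 0.05
STEADY_TOTAL = HOMEOSTASIS_N * SECRETION_RATE / DEGRADATION_RATE


def homeostasis_doc(seed: int, steps: int, *, n: int = HOMEOSTASIS_N) -> dict:
    """Equal couplet populations preloaded at their steady pool totals."""
    total = n * SECRETION_RATE / DEGRADATION_RATE
    return {
        "seed": seed,
        "steps": steps,
        "variant": "EC",
        "initial_cells": {"A": n, "I": n},
        "pool": {"total_a": total, "total_i": total},
    }


# --------------------------------------------------------------------------
# scenarios

def scenario_balanced_perturbation(overrides: Optional[dict] = None,
                                   seed: int = 1,
                                   mirror: bool = False) -> ScenarioReport:
    """Balanced mix at the homeostatic point, then one species is added in
    excess; the partner population must rise, the mix must rebalance, and
    the terminal pool must again be complex-dominated with low, nearly
    equal free levels."""
    roles = _roles(mirror)
    spike_step, spike_amount, steps = 20, 2e-9, 240
    report = ScenarioReport("balanced_perturbation", seed, mirror)
    doc = homeostasis_doc(seed, steps)
    doc["events"] = [{"at_step": spike_step, "kind": "ADD_TREFONE",
                      "species": roles["spike_species"],
                      "amount": spike_amount}]
    _apply_overrides(doc, overrides)
    ts = _build_and_run(doc, report, "main")
    df = ts.to_dataframe()

    resp, other = f"n_{roles['responder']}", f"n_{roles['other']}"
    n0 = int(df.loc[spike_step, resp])
    window = df.loc[spike_step + 1: spike_step + 8, resp]
    report.check(
        "responder population rises within the dwell window",
        int(window.max()) > n0,
        f"{resp} {n0} -> max {int(window.max())} in steps "
        f"{spike_step + 1}..{spike_step + 8}",
    )

    last = df.iloc[-1]
    na, ni = int(last[other]), int(last[resp])
    imbalance = abs(na - ni) / max(na + ni, 1)
    report.check(
        "terminal imbalance below 0.1",
        imbalance < 0.1,
        f"|{na} - {ni}| / {na + ni} = {imbalance:.3f}",
    )

    free_hi = max(last["free_a"], last["free_i"])
    free_gap = abs(last["free_a"] - last["free_i"]) / max(free_hi, 1e-30)
    complex_dominant = last["complex_ai"] >= 5 * free_hi
    report.check(
        "terminal pool complex-dominated with low, near-equal free levels",
        complex_dominant and free_gap <= 0.5,
        f"complex {last['complex_ai']:.3e} vs free "
        f"({last['free_a']:.3e}, {last['free_i']:.3e}), gap {free_gap:.2f}",
    )
    report.observables.update({
        "imbalance_end": imbalance,
        "responder_peak": int(df[resp].max()),
        "final_counts": {"A": na if roles["other"] == "A" else ni,
                         "I": ni if roles["responder"] == "I" else na},
    })
    return report


def scenario_monoculture_conversion(overrides: Optional[dict] = None,
                                    seed: int = 1,
                                    mirror: bool = False) -> ScenarioReport:
    """One cell type alone plus its own species added: the missing partner
    type must emerge through asymmetric division and both types persist."""
    own_type = "A" if not mirror else "I"
    own_species = "a" if not mirror else "i"
    partner = "I" if not mirror else "A"
    steps = 200
    report = ScenarioReport("monoculture_conversion", seed, mirror)
    doc = {
        "seed": seed, "steps": steps, "variant": "EC",
        "initial_cells": {own_type: 24},
        "events": [{"at_step": 2, "kind": "ADD_TREFONE",
                    "species": own_species, "amount": 2e-9}],
    }
    _apply_overrides(doc, overrides)
    ts = _build_and_run(doc, report, "main")
    df = ts.to_dataframe()
    last = df.iloc[-1]

    report.check(
        "partner type emerges",
        int(df[f"n_{partner}"].max()) > 0,
        f"max n_{partner} = {int(df[f'n_{partner}'].max())}",
    )
    report.check(
        "both types persist at run end",
        int(last[f"n_{own_type}"]) > 0 and int(last[f"n_{partner}"]) > 0,
        f"final n_{own_type}={int(last[f'n_{own_type}'])}, "
        f"n_{partner}={int(last[f'n_{partner}'])}",
    )
    ascd = (ts.action_count(CellType(own_type), Action.ASCD_SELF_PARTNER)
            + ts.action_count(CellType(own_type), Action.ASCD_PARTNER_PARTNER))
    report.check(
        "conversion occurred via asymmetric division",
        ascd > 0,
        f"{own_type}-cell AsCD count = {ascd}",
    )
    report.observables.update({
        "final_counts": {t: int(last[f"n_{t}"]) for t in ("A", "I")},
        "ascd_count": ascd,
    })
    return report


def scenario_analog_potency(overrides: Optional[dict] = None,
                            seed: int = 1,
                            mirror: bool = False) -> ScenarioReport:
    """Equal doses of the couplet species versus its low-affinity analog
    into a partner-cell culture: the analog escapes sequestration, reads as
    partner abundance with little complex, and triggers at least as many
    symmetric divisions."""
    responder = "I" if not mirror else "A"
    dose_species = "a" if not mirror else "i"
    n, steps, dose = 16, 50, 3e-10
    base_total = n * SECRETION_RATE / DEGRADATION_RATE
    report = ScenarioReport("analog_potency", seed, mirror)

    def doc_for(arm: str) -> dict:
        doc = {
            "seed": seed, "steps": steps, "variant": "EC",
            "binding": {"ka": 1e10, "ka_analog": 1e7,
                        "analog_target": "i" if not mirror else "a"},
            "initial_cells": {responder: n},
            "pool": {("total_i" if not mirror else "total_a"): base_total},
            "events": [{"at_step": 2, "kind": "ADD_TREFONE",
                        "species": dose_species if arm == "wild"
                        else "analog",
                        "amount": dose}],
        }
        return _apply_overrides(doc, copy.deepcopy(overrides) if overrides
                                else None)

    ts_wild = _build_and_run(doc_for("wild"), report, "wild")
    ts_analog = _build_and_run(doc_for("analog"), report, "analog")

    scd_wild = ts_wild.action_count(CellType(responder), Action.SCD_SRE)
    scd_analog = ts_analog.action_count(CellType(responder), Action.SCD_SRE)
    report.check(
        "analog dose drives at least as many symmetric divisions",
        scd_analog >= scd_wild,
        f"SCD({responder}): analog {scd_analog} vs wild-type {scd_wild}",
    )
    report.check(
        "analog dose drives strictly more symmetric divisions",
        scd_analog > scd_wild,
        f"SCD({responder}): analog {scd_analog} vs wild-type {scd_wild}",
    )
    report.observables.update({
        "scd_wild": scd_wild, "scd_analog": scd_analog,
        "final_responders_wild": int(ts_wild.rows[-1][f"n_{responder}"]),
        "final_responders_analog": int(ts_analog.rows[-1][f"n_{responder}"]),
    })
    return report


def scenario_trefone_sink(overrides: Optional[dict] = None,
                          seed: int = 1,
                          mirror: bool = False) -> ScenarioReport:
    """From the homeostatic point one species is acutely destroyed each
    step: the pool complex collapses, the deprived side damps its output,
    and the other side reads Hi partner with Lo complex."""
    sunk_species = "a" if not mirror else "i"
    maker_type = "A" if not mirror else "I"      # secretes the sunk species
    listener_type = "I" if not mirror else "A"   # deprived of it
    sink_start, steps, sink_amount = 60, 85, 5e-10
    report = ScenarioReport("trefone_sink", seed, mirror)
    doc = homeostasis_doc(seed, steps)
    doc["events"] = [
        {"at_step": t, "kind": "SINK_TREFONE", "species": sunk_species,
         "amount": sink_amount}
        for t in range(sink_start, steps)
    ]
    _apply_overrides(doc, overrides)
    ts = _build_and_run(doc, report, "main")
    df = ts.to_dataframe()

    pre = df.loc[sink_start - 1]
    last = df.iloc[-1]
    report.check(
        "pool complex collapses",
        last["complex_ai"] < 0.1 * pre["complex_ai"],
        f"complex {pre['complex_ai']:.3e} -> {last['complex_ai']:.3e}",
    )

    sec_col = f"secreted_{'i' if not mirror else 'a'}"
    pre_rate = (df.loc[sink_start - 1, sec_col]
                - df.loc[sink_start - 6, sec_col]) / 5
    end_rate = (df.iloc[-1][sec_col] - df.iloc[-6][sec_col]) / 5
    per_cell_pre = pre_rate / max(df.loc[sink_start - 1, f"n_{listener_type}"], 1)
    per_cell_end = end_rate / max(last[f"n_{listener_type}"], 1)
    report.check(
        "deprived side damps its per-cell output",
        per_cell_end < 0.5 * per_cell_pre,
        f"per-cell secretion {per_cell_pre:.3e} -> {per_cell_end:.3e}",
    )

    # acute phase: at some point during the sink, essentially every cell of
    # the maker type must read Hi partner / Lo complex
    window = df.loc[sink_start:]
    frac = (window[f"n_pHi_cLo_{maker_type}"]
            / window[f"n_{maker_type}"].clip(lower=1))
    report.check(
        "makers read Hi partner / Lo complex during the sink",
        float(frac.max()) >= 0.9,
        f"peak (Hi, Lo) fraction among {maker_type}-cells = {frac.max():.2f}",
    )
    report.observables.update({
        "complex_before": float(pre["complex_ai"]),
        "complex_after": float(last["complex_ai"]),
        "hi_lo_fraction_peak": float(frac.max()),
    })
    return report


def scenario_blastomere_lineage(overrides: Optional[dict] = None,
                                seed: int = 1,
                                first_division: Action = Action.ASCD_DUAL_LCDF,
                                ) -> ScenarioReport:
    """Deterministic early lineage: one progenitor divides asymmetrically
    into the two couplet types, then every cleavage is symmetric.  At the
    2-, 4- and 8-cell stages, exactly half the cells carry the
    partner-species receptor pattern of the committed responder
    (aR+ / iR-), matching receptor staining of half the blastomeres."""
    report = ScenarioReport("blastomere_lineage", seed)
    ids = iter(range(1, 100))
    progenitor = make_cell(CellType.O, Variant.EC, id=0)
    stage = divide(progenitor, first_division, id_source=ids)
    fractions = {}
    positive = {}
    for n_cells in (2, 4, 8):
        pos = sum(1 for c in stage
                  if c.receptors.has_aR and not c.receptors.has_iR)
        fractions[n_cells] = pos / len(stage)
        positive[n_cells] = pos
        if n_cells < 8:
            stage = [child for cell in stage
                     for child in divide(cell, Action.SCD_SRE, id_source=ids)]

    report.check(
        "exactly half the blastomeres are receptor-positive at each stage",
        all(positive[n] == n // 2 for n in (2, 4, 8)),
        f"positives: {positive}",
    )
    values = set(fractions.values())
    report.check(
        "the three stage fractions agree",
        len(values) == 1,
        f"fractions: {fractions}",
    )
    report.observables.update({
        "fractions": {str(k): v for k, v in fractions.items()},
        "percent_positive": 100.0 * fractions[8],
    })
    return report


def scenario_persisters(overrides: Optional[dict] = None,
                        seed: int = 1,
                        mirror: bool = False) -> ScenarioReport:
    """Cycling cells grow in partner-species-rich medium while their
    couplet partners sit dormant; an antibiotic-like event kills every
    cycling cell; fresh medium reawakens the dormant survivors, which
    regrow and regenerate the killed type.  A control without dormant
    cells goes extinct."""
    grower = "A" if not mirror else "I"           # killed by the antibiotic
    persister = "I" if not mirror else "A"        # dormant survivor
    kill_step, replace_step, steps = 15, 16, 55
    medium = {"total_i" if not mirror else "total_a": 1e-8}
    fresh = {"a" if not mirror else "i": 2e-9}
    report = ScenarioReport("persisters", seed, mirror)

    def doc_for(with_persisters: bool) -> dict:
        doc = {
            "seed": seed, "steps": steps, "variant": "EC",
            "initial_cells": {grower: 8,
                              **({persister: 8} if with_persisters else {})},
            "initial_life_state": {persister: "DORMANT"},
            "pool": dict(medium),
            "events": [
                {"at_step": kill_step, "kind": "KILL_CYCLING"},
                {"at_step": replace_step, "kind": "MEDIUM_REPLACE",
                 "totals": dict(fresh)},
            ],
        }
        return _apply_overrides(doc, copy.deepcopy(overrides) if overrides
                                else None)

    ts = _build_and_run(doc_for(True), report, "main")
    ts_control = _build_and_run(doc_for(False), report, "control")
    df = ts.to_dataframe()

    at_kill = df.loc[kill_step]
    report.check(
        "only former dormant cells survive the kill",
        int(at_kill["n_cycling"]) == 0
        and int(at_kill["n_alive"]) == int(at_kill["n_dormant"]) > 0,
        f"post-kill: alive={int(at_kill['n_alive'])}, "
        f"dormant={int(at_kill['n_dormant'])}",
    )

    last = df.iloc[-1]
    post = df.loc[kill_step + 1:]
    scd_post = int(post["act_SCD_SRE"].sum())
    ascd_post = int(post["act_ASCD_SELF_PARTNER"].sum()
                    + post["act_ASCD_PARTNER_PARTNER"].sum())
    report.check(
        "survivors regrow and regenerate the killed type",
        int(last["n_alive"]) > int(at_kill["n_alive"])
        and int(last[f"n_{grower}"]) > 0
        and scd_post > 0 and ascd_post > 0,
        f"alive {int(at_kill['n_alive'])} -> {int(last['n_alive'])}, "
        f"n_{grower}={int(last[f'n_{grower}'])}, "
        f"post-kill SCD={scd_post}, AsCD={ascd_post}",
    )

    control_last = ts_control.to_dataframe().iloc[-1]
    report.check(
        "no regrowth without dormant cells",
        int(control_last["n_alive"]) == 0,
        f"control final alive = {int(control_last['n_alive'])}",
    )
    report.observables.update({
        "alive_post_kill": int(at_kill["n_alive"]),
        "alive_end": int(last["n_alive"]),
        "grower_end": int(last[f"n_{grower}"]),
    })
    return report


def scenario_singlet_immune(overrides: Optional[dict] = None,
                            seed: int = 1) -> ScenarioReport:
    """A half-couplet immune cell secretes an antibody-like species against
    an exogenous antigen inflow: it proliferates while the immune-complex
    readout stays low relative to antigen, and stops once the complex
    dominates."""
    steps = 60
    report = ScenarioReport("singlet_immune", seed)
    doc = {
        "seed": seed, "steps": steps, "variant": "EC",
        "initial_cells": {"SINGLET": 4},
        "pool": {"antigen_inflow_rate": 4e-11},
        "events": [{"at_step": 3, "kind": "ANTIGEN_PULSE", "amount": 1e-9}],
        # the brake is quiescence, not death
        "table": {"apo_on_extreme": False},
    }
    _apply_overrides(doc, overrides)
    ts = _build_and_run(doc, report, "main")
    df = ts.to_dataframe()
    last = df.iloc[-1]

    report.check(
        "singlet population expands",
        int(last["n_SINGLET"]) > 4,
        f"n_SINGLET 4 -> {int(last['n_SINGLET'])}",
    )
    tail = df.iloc[-10:]
    report.check(
        "divisions cease (plateau)",
        int(tail["act_SCD_SRE"].sum()) == 0
        and tail["n_SINGLET"].nunique() == 1,
        f"final-10-step SCD={int(tail['act_SCD_SRE'].sum())}, "
        f"counts={sorted(tail['n_SINGLET'].unique())}",
    )

    config = report.timeseries["main"].config
    singlets = [c for c in ts.final_cells
                if c.alive and c.cell_type == CellType.SINGLET]
    hi_complex = 0
    for cell in singlets:
        p, c = intracellular_readout(cell, config.binding, config.variant,
                                     config.rates)
        _, cl = readout_levels(p, c, config.table)
        if cl == "Hi":
            hi_complex += 1
    report.check(
        "terminal complex readout is Hi",
        singlets and hi_complex >= 0.9 * len(singlets),
        f"{hi_complex}/{len(singlets)} singlets read Hi complex",
    )
    report.observables.update({
        "singlet_end": int(last["n_SINGLET"]),
        "singlet_peak": int(df["n_SINGLET"].max()),
    })
    return report


SCENARIOS: dict[str, Callable[..., ScenarioReport]] = {
    "balanced_perturbation": scenario_balanced_perturbation,
    "monoculture_conversion": scenario_monoculture_conversion,
    "analog_potency": scenario_analog_potency,
    "trefone_sink": scenario_trefone_sink,
    "blastomere_lineage": scenario_blastomere_lineage,
    "persisters": scenario_persisters,
    "singlet_immune": scenario_singlet_immune,
}

#: scenarios with an A/I asymmetry, i.e. those that accept mirror=True
MIRRORABLE = (
    "balanced_perturbation", "monoculture_conversion", "analog_potency",
    "trefone_sink", "persisters",
)


def run_scenario(name: str, overrides: Optional[dict] = None,
                 seed: int = 1, mirror: bool = False) -> ScenarioReport:
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; "
                       f"choose from {sorted(SCENARIOS)}")
    fn = SCENARIOS[name]
    if mirror:
        if name not in MIRRORABLE:
            raise ValueError(f"scenario {name!r} has no mirrored form")
        return fn(overrides=overrides, seed=seed, mirror=True)
    return fn(overrides=overrides, seed=seed)
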