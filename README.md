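# ctcsim

An agent-based simulator of two coupled cell populations that exchange a
pair of soluble signalling molecules forming a binary complex.

Two committed cell types (`A` and `I`), born of one asymmetric division of
a progenitor (`O`), each secrete one species into a shared well-mixed pool
and carry the receptor for the *other* species — never their own.  The two
species associate reversibly (`a + i <=> a:i`, association constant `ka`),
and each cell internalizes free partner material plus (via a scarce
complex receptor) the complex itself.  After re-equilibration in an
endosomal compartment, the discretized (partner level, complex level)
readout drives a rule table of whole-cell fates: secretion boost, symmetric
self-renewal, asymmetric divisions, transdifferentiation, quiescence,
apoptosis and dedifferentiation back to the progenitor.  The negative
feedback through the complex keeps the two populations numerically
balanced; the packaged scenarios exercise perturbation recovery,
monoculture conversion, low-affinity analog dosing, acute species sinks, a
deterministic embryonic lineage, antibiotic persistence, and a half-couplet
immune "singlet".

Two sensing variants exist: `EC` (the extracellular complex is sampled by a
scarce membrane receptor) and `IC` (a hived-off fraction of the cell's own
product meets the internalized partner species inside the cell).

## Layout

| module | contents |
|---|---|
| `ctcsim.chemistry` | closed-form pair equilibrium, competitive-analog solver, level discretization |
| `ctcsim.cell_model` | cell agents, receptor profiles, marker strings, the division/fate catalogue |
| `ctcsim.signalling` | pool state, secretion / uptake / degradation, intracellular readout, mass ledger |
| `ctcsim.decision` | the (type, partner level, complex level) → action table and dwell semantics |
| `ctcsim.engine` | stepped world loop, events, trajectory recording, per-step ledger checks |
| `ctcsim.scenarios` | frozen scenario fixtures and their assertion harnesses |
| `ctcsim.cli_io` | YAML config schema, validation, CSV/JSON run serialization |

## CLI

```bash
ctc-sim run configs/example.yaml --out out/        # run a config
ctc-sim validate configs/example.yaml              # schema + constraint check
ctc-sim scenario balanced_perturbation --seed 1    # canned thought experiment
ctc-sim scenario trefone_sink --mirror             # roles swapped
ctc-sim scenario analog_potency --override binding.ka_analog=1e8
ctc-sim equilibrate --ka 1e10 --total-a 1e-8 --total-i 1e-8
```

Exit codes: 0 success, 1 scenario assertion failure, 2 validation error.
Every trajectory CSV and summary JSON embeds the config digest and seed, so
artifacts are regenerable from their own metadata.

Scenarios: `balanced_perturbation`, `monoculture_conversion`,
`analog_potency`, `trefone_sink`, `blastomere_lineage`, `persisters`,
`singlet_immune`.  All A/I-asymmetric scenarios also pass with the couplet
roles mirrored (`--mirror`).

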