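# Test fixtures

All files here are **synthetic**, produced by `cashde.simulate.generate_dataset`
with `SimulationConfig(n_genes=20, n_case=6, n_control=6, frac_de=0.3,
effect_size=3.0, penetrance=1.0, seed=2024)` and frozen so that the CLI
determinism test has a stable on-disk input.

- `fixture_expr.tsv` — 20-gene x 12-sample log2 expression matrix
- `fixture_sheet.tsv` — sample sheet (6 case / 6 control)
- `fixture_truth.tsv` — planted ground truth (6 DE genes)
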