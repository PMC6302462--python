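# mwct

Genetic-algorithm minimization of the Wilson Central Terminal (WCT) for
ECG limb leads.

The WCT — the simple average of the left-arm, right-arm and left-leg
electrode potentials — is not the negligible reference it is often assumed
to be. This package searches for a constrained weight tern `(alpha, beta,
gamma)` on the open 2-simplex (each weight in `(0, 1)`, summing to one)
whose weighted mean of the three limb potentials — the minimized terminal,
M-WCT — has minimal mean absolute amplitude. It reports WCT and M-WCT
amplitude as a percentage of Einthoven lead II over five consecutive beats,
together with QRS-orientation polarity labels (`positive`, `negative`, or
`N` when neither deflection dominates).

## Layout

- `mwct.core` — recording/weight types, WCT / M-WCT / lead II computation,
  the logarithmic fitness score (`log` base `1e-5` of the mean absolute
  amplitude in volts), and simplex constraint repair.
- `mwct.ga` — the genetic algorithm: population of 80 terns seeded with the
  uniform `(1/3, 1/3, 1/3)` chromosome, tournament selection, single-point
  and averaging crossover chosen at random, permutation mutation
  (probability 0.1), elitism, uniform-chromosome preservation in every
  generation, plus a brute-force lattice `grid_search_oracle`.
- `mwct.metrics` — beat detection on lead II, five-beat peak-to-peak
  amplitude as a percentage of lead II, polarity classification.
- `mwct.synth` — synthetic limb recordings: a 3-D cardiac dipole built from
  Gaussian P-QRS-T wavelets projected onto per-limb lead vectors, with the
  left-leg vector constructed so a known planted tern exactly nulls the
  weighted mean (recoverable ground truth), plus drift and noise.
- `mwct.io` / `mwct.cli` — CSV recording dialect
  (`time_s,phi_L_V,phi_R_V,phi_F_V`, volts), JSON result documents, and the
  `mwct` command-line tool.

## CLI

Generate a synthetic cohort with a ground-truth manifest:

```sh
mwct synth --n 3 --seed 1 --output-dir cohort/
```

Minimize one recording and write a JSON result document:

```sh
mwct minimize --input cohort/synthetic-000.csv --seed 1 --output result.json
```

`--mode windowed --window-seconds 1` runs the GA independently per
non-overlapping window and reports the renormalized across-window average
tern. All flags can also be given in a YAML file via `--config`; explicit
CLI flags win. Runs are deterministic for a fixed seed: identical inputs
produce byte-identical outputs.

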