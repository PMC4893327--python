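# thermoreg

Thermoregulation analysis for ectotherm field studies: preferred
(set-point) temperature ranges, the Hertz–Huey–Stevenson indices with a
bootstrap confidence-interval engine, habitat thermal-suitability
profiling, and microhabitat selection-versus-availability tests.

It is written for thermal ecologists comparing how well lizard (or other
ectotherm) populations thermoregulate in a shared habitat — for example a
cold-adapted mountain specialist and a widespread thermal generalist
living in syntopy — from four standard field datasets:

1. **gradient-trial selected temperatures** (T_pref): hourly cloacal
   temperatures of individuals in a laboratory thermal gradient;
2. **field body temperatures** (T_b): cloacal temperatures at capture,
   with the capture microhabitat context;
3. **operative temperatures** (T_e): hollow copper lizard models with
   thermocouples logging every 5 minutes across microhabitats — the
   temperature a non-thermoregulating lizard would reach at each site;
4. **use/availability microhabitat frequencies**.

## The model

The preferred temperature range (PTR) is the central 50% of
gradient-selected temperatures — the interquartile range of T_pref.
Against it, with d(T) the absolute deviation of a temperature from the
PTR (zero inside, distance to the nearer bound outside):

- **accuracy of thermoregulation**  d̄_b = mean d(T_b) — higher is *worse*;
- **thermal quality of habitat**    d̄_e = mean d(T_e) — higher is *worse*;
- **effectiveness of thermoregulation**  **E = 1 − d̄_b / d̄_e** — near 1
  for effective thermoregulators, near 0 for thermoconformers; undefined
  in a thermally ideal habitat (d̄_e = 0), negative under active
  avoidance of the set-point range.

Uncertainty comes from a nonparametric bootstrap (default 100
iterations): T_b and T_e are independently resampled with replacement at
their original sizes, the three indices recomputed each time, and the
pseudo-distributions summarised as mean ± sd with percentile CIs.
Around this core: Kruskal–Wallis with Nemenyi post-hoc letters for
multi-group T_e and use-vs-availability comparisons, exact (Fisher /
Monte-Carlo conditional) frequency tests, and a four-way cold / mild /
warm / very-warm classification of microhabitats relative to the two
species' PTRs.

A synthetic-study generator (diel T_e curves per microhabitat, Normal
T_pref distributions, and a tunable thermoregulator with regulation
strength k ∈ [0, 1]) makes the whole pipeline runnable and testable with
no external data.

## Worked example

Simulate a study (two species over a 16-category microhabitat landscape)
and run the full pipeline:

```sh
thermoreg simulate --seed 5 --out csvs --days 1
cat > study.yaml <<EOF
species: [specialist, generalist]
inputs:
  tpref: csvs/tpref.csv
  body: csvs/body.csv
  operative: csvs/operative.csv
  availability: csvs/availability.csv
  counts: csvs/counts.csv
EOF
thermoreg run --config study.yaml --out out
```

which prints

```
report bundle written to /tmp/demo/out
  specialist: d_b=0.43 d_e=5.32 E=0.92
  generalist: d_b=0.60 d_e=4.88 E=0.88
```

Both synthetic species are strong thermoregulators (generator k = 0.9):
their body temperatures deviate from their set-point ranges by under
0.7 °C on average, while the habitat at large deviates by ~5 °C, so
E lands near 0.9.  The bundle under `out/` holds `report.json`
(versioned schema with PTRs, bootstrap CIs, all test statistics),
`suitability.csv` (share of T_e below/within/above each species' PTR per
microhabitat, e.g. full-sun grass is 100% above the specialist's range),
`thermal_groups.csv` (the cold/mild/warm/very-warm classification),
`te_letter_groups.csv` (Nemenyi compact letters) and
`selection_tests.csv`.

Individual stages are also subcommands (`thermoreg ptr`, `indices`,
`habitat`, `selection`, `selection-freq`) and plain functions
(`thermoreg.estimate_ptr`, `thermoreg.bootstrap_indices`, …).

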