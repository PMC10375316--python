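# steroidscreen

Analysis pipeline for coupled steroidogenesis / reporter-gene (CALUX)
96-well plate assays: a hormone-producing plate (H295R cells on one half,
cell-free "sham" wells on the other) is read out by diluting its
supernatant onto ERα and AR reporter plates, so that one experiment
measures changes in estrogen/androgen biosynthesis *and* direct
receptor-mediated activity of the test chemical at the same time.

The package covers the full desk side of such an experiment:

- **`plates`** — well-level data model, 96-well layout, long-format CSV
  I/O (schema in `src/steroidscreen/data/schema.yaml`), treated/sham
  pairing, dilution schemes and standard-curve specs.
- **`normalize`** — % viability, background-subtracted % relative
  induction (%RI) against the standard-curve reference, re-normalization
  to basal hormone production, dilution-corrected concentrations.
- **`qc`** — LOQ, induction factor, Z-factor, 4PL standard-curve fits with
  AC50-window and R² criteria, control-substance checks, replicate CVs,
  and the plate verdict with its 10%-of-threshold tolerance rescue.
- **`npstats`** — pooled (n = 9) Kruskal–Wallis + two-sided Mann–Whitney U
  testing (exact at small tie-free samples, tie/continuity-corrected
  normal approximation otherwise), significance star/hash bins, and a
  Shapiro–Wilk screen (diagnostic only).
- **`classify`** — positivity rule (2 consecutive significant
  concentrations and/or the highest noncytotoxic one), LOEC derivation,
  biphasic direction profiles, direct receptor calls from sham wells, and
  masking of apparent steroidogenic effects by direct receptor activity or
  cytotoxicity.
- **`evaluate`** — direction-aware confusion matrices against reference
  classifications (validation study, combined known in-vitro activities,
  in vivo data), equivocal-call resolution, sensitivity/specificity/
  accuracy under the minimum-4-substances rule.
- **`simulate`** — synthetic five-plate experiments with known ground
  truth: Hill-shaped effects on basal hormone output, additive ER
  agonist-equivalents, competitive AR antagonism, per-cell-type
  cytotoxicity, standard curves and log-normal measurement noise.
- **`pipeline` / `cli`** — orchestration and a `steroidscreen` command.

## CLI

```sh
# simulate a known inhibitor and analyze it end to end
steroidscreen simulate --preset prochloraz_like --seed 7 --out runs/sim
steroidscreen analyze  --input runs/sim --out runs/out
cat runs/out/classification.csv

# or in one step, and QC / evaluation on their own
steroidscreen analyze --preset bpa_like --seed 7 --out runs/bpa
steroidscreen qc --preset inactive --seed 1
steroidscreen evaluate --out runs/eval   # confusion matrices + metrics
```

Presets: `prochloraz_like`, `forskolin_like`, `letrozole_like`,
`bpa_like`, `benomyl_like`, `cadmium_like`, `inactive`,
`threshold_inhibitor`.

Exit codes: 0 success, 2 QC failure, 3 input error.

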