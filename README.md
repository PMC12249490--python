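# turnoverkit

Protein turnover rates from deuterated-water (²H₂O) metabolic labeling time
courses, starting from peptide-level monoisotopic relative-abundance (RA)
tables.

Heavy-water labeling depletes a peptide's monoisotopic RA as deuterium is
incorporated; fitting the depletion time course yields the protein turnover
rate *k* (day⁻¹). The classical single-exponential RA model makes the fitted
rate depend systematically on the peptide's number of exchangeable hydrogens
(N_EH), inflating the spread of rates across peptides of one protein.
`turnoverkit` implements both the classical model and a corrected two-step
workflow:

1. **debias** — at every labeling duration, regress the excess deuterium
   enrichment p_X(t) on N_EH (per protein or globally) and subtract the
   linear component about the regression centroid, preserving residuals and
   the per-timepoint mean;
2. **rescaled fit** — fit the kinetics with p_X(t) replaced by p_X(t)/N_EH,
   which makes the recovered rate practically independent of N_EH.

A seeded simulator generates realistic peptide time-course tables (with
matching truth tables) so the full pipeline is testable without any
instrument data.

## Modules

| module | contents |
|---|---|
| `turnoverkit.chemistry` | residue → N_EH table (packaged default, overridable), N_EH summation, natural monoisotopic abundance |
| `turnoverkit.enrichment` | RA ↔ enrichment conversion (verbatim and exact inversion modes) |
| `turnoverkit.kinetics` | classical RA / enrichment fits, N_EH-rescaled fit, analytic half-life ratio diagnostics, Taylor-limit form |
| `turnoverkit.debias` | per-timepoint N_EH regression and residual-preserving adjustment |
| `turnoverkit.protein_stats` | protein summaries, SD comparison, k-vs-N_EH slope test, two-condition Welch t-test |
| `turnoverkit.simulate` | `LabelingDesign`, `simulate_dataset`, packaged classical-vs-proposed benchmark |
| `turnoverkit.io_cli` | CSV readers/writers, run config, CLI |

## CLI

```sh
# generate a synthetic dataset (observations.csv + truth.csv)
turnoverkit simulate --seed 1 --n-proteins 10 --peptides-per-protein 8 --out sim/

# fit both models (classical + debias/rescaled), per-peptide and per-protein tables
turnoverkit fit --input sim/observations.csv --model both --scope global --out fits/

# enrichment adjustment only, with the per-timepoint regression audit trail
turnoverkit adjust --input sim/observations.csv --scope protein --out adj/

# Welch t-test of peptide rates between two fitted result sets
turnoverkit compare --input fits_liver/peptide_fits.csv --input-b fits_kidney/peptide_fits.csv --out cmp/

# end-to-end bias study: classical vs proposed on one simulation
turnoverkit benchmark --seed 1 --out bench/
```

Common flags: `--pw` (body-water enrichment, default 0.04), `--ph` (natural
²H abundance, default 0.000115), `--residue-table` (custom residue → N_EH
file), `--exact-inversion` (use the exact algebraic RA→enrichment inverse),
`--min-timepoints`, `--config` (key = value file supplying defaults).

Input format: CSV with columns `protein_id, peptide_sequence, time_days, i0`
plus optional `i0_natural, neh, charge, p_w`. When `neh` is absent it is
computed from the sequence with the residue table.

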