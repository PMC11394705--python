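# quenchbind

Analysis pipeline for ligand–enzyme interaction studies built on
fluorescence quenching titrations:

- **Inhibition assay** — percent inhibition from control/sample absorbances
  and IC50 estimation (bounded four-parameter logistic fit, log-linear
  interpolation cross-check, optional bootstrap CI).
- **Spectral preprocessing** — inner-filter-effect correction
  (`F = F_init · base^((A_ex + A_em)/2)`, base *e* by default with a base-10
  option), peak location with optional quadratic smoothing, peak-shift
  tracking across a titration, synchronous-scan (Δλ = 15/60 nm) residue
  comparison, and excitation–emission-matrix peak picking with Rayleigh
  scatter masking.
- **Binding analysis** — Stern–Volmer fit (`F0/F = 1 + K_SV[Q]`,
  `K_q = K_SV/τ0`), quenching-mechanism classification against the
  2.0 × 10¹⁰ L/(mol·s) collisional limit, and the double-logarithmic fit
  (`lg[(F0−F)/F] = lg K_A + n·lg[Q]`) for the binding constant and
  binding-site number.
- **Thermodynamics** — Van't Hoff fit of ln K_A vs 1/T for ΔH and ΔS,
  Gibbs free energy ΔG = ΔH − TΔS, and sign-based driving-force
  classification.
- **Synthetic data** — seeded generators for every input kind with exact
  generative truth, so all stages are testable without instrument data.

## CLI

All stages are exposed under a single `quenchbind` entry point:

```sh
# full pipeline from a flat YAML config
quenchbind run --config pipeline.yaml --out results/

# individual stages
quenchbind thermo --ka 303=5.52e6 --ka 310=1.86e4
quenchbind ic50 dose_response.csv --bootstrap 500
quenchbind sternvolmer titration.csv
quenchbind binding titration.csv
quenchbind shifts titration.csv
quenchbind shifts --synchronous sync15.csv
quenchbind eem-peaks eem.csv
quenchbind correct-ife titration.csv --out corrected.csv
quenchbind --seed 1 simulate --kind titration --out sim/
```

Input tables are plain CSV with `#`-prefixed metadata lines; see the
docstrings in `quenchbind.datamodel` for the exact dialects. `run` writes a
`report.json` (full-precision, reproducible byte-for-byte) plus per-stage
CSV tables.

Example pipeline config:

```yaml
titration_tables: [titr303.csv, titr310.csv]
sync15_table: sync15.csv
sync60_table: sync60.csv
eem_table: eem.csv
dose_response_table: dose.csv
tau0_s: 1.0e-8        # fluorophore lifetime, s
kq_limit: 2.0e10      # collisional quenching limit, L/(mol s)
ife_base: e           # inner-filter correction base ('e' or 10)
```

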