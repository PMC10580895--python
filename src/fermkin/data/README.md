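# Packaged reference data

Small delimited fixtures transcribed from a published study of
biosurfactant production by *Aspergillus niger* SA1 in submerged batch
fermentation on waste frying oil.  They are shipped so the examples and
the validation workflow run without any external download.

- `reference_design.csv` — the 22 printed runs of the five-factor,
  three-level optimization design (pH, temperature, oil load, agitation
  rate, incubation time) with the biosurfactant yield response.  The
  design called for 23 runs; run 22 was not printed and is therefore
  absent here (no imputation).
- `reference_kinetics.json` — the kinetic parameter set reported for the
  fermentation (logistic growth, growth-associated product line,
  substrate balance).  Note the reported `y_ps` (1.8736) does not equal
  `alpha * y_xs` (1.8137); both printed values are kept and the relation
  is exposed as a consistency check in the library.
- `reference_validation.csv` — the experimental-vs-calculated comparison
  table (5 time points, biomass and product).  The `*_printed` error
  columns hold the errors exactly as published; the product error at
  168 h is printed as 1.56 although recomputation from the adjacent
  columns gives 1.50.
- `factors.yaml` — factor ranges and the selected-term variants of the
  response-surface model (the source is internally inconsistent about
  two interaction labels, so both readings ship).
- `surface_activity.csv` — replicate summaries (mean, SD) of the
  surface-activity assays before and after optimization, for the
  documentation examples.

All values are transcribed verbatim, including internal inconsistencies;
nothing here is output of this package.
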