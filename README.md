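# fluxquant

Quantification of **autophagic flux** from tandem mCherry-EGFP-LC3B
fluorescence microscopy, plus **2^−ΔΔCt** relative gene-expression analysis
and **RECIST-adapted** zebrafish-xenograft response scoring. Built for
researchers running tandem-reporter flux assays who want the counting,
classification and statistics steps automated, deterministic, and
benchmarked against ground truth.

## The science in brief

The tandem reporter fuses LC3B to an acid-stable red (mCherry) and an
acid-quenched green (EGFP) fluorophore. An autophagosome (AP) fluoresces
red ∧ green; after fusion with a lysosome the acidic lumen quenches EGFP,
so an autolysosome (AL) is red-only. With per-cell counts
`AP = n_AP / n_nuclei` and `AL = n_AL / n_nuclei` per field of view, a
drug ± bafilomycin A1 design is read as:

* **flux induced**: AL↑ (drug vs control) *and* AP↑ (drug+baf vs baf),
  both Tukey-adjusted p < 0.05 in the stated direction;
* **flux blocked**: AP↑ (drug vs control) without AL↑;
* **indeterminate** otherwise.

qPCR fold changes follow 2^−ΔΔCt with ΔCt = Ct(target) − mean Ct(SDHA,
HPRT) and ΔΔCt referenced to the control condition. Xenograft response uses
volume-based thresholds: PD ≥ +20% change, PR ≤ −30%, SD between, both
boundaries inclusive.

A full synthetic-data stack (`fluxquant.synthcells`) renders fields with
known nuclei and spot positions, Ct tables with known fold changes, and
volume tables with known responses, so every stage is testable end to end.

## Worked example

```python
from fluxquant import synthcells as sc, puncta as pk, fluxstats as fs

base = sc.SimFieldParams(poisson_noise=True, gaussian_noise_sd=7.5)
spec = sc.CohortEffectSpec.flux_induced(n_fields=6, seed=1)
fields, sheet = sc.generate_cohort(spec, base)
sc.write_cohort(fields, sheet, "cohort/")

results, errors = pk.quantify_batch(sheet, "cohort/")
for s in fs.summarize_conditions(results):
    print(f"{s.condition:9s} mean AP/cell={s.mean_per_cell_ap:5.2f}"
          f"  mean AL/cell={s.mean_per_cell_al:5.2f}")
print("verdict:", fs.interpret_flux_table(results).verdict)
```

prints

```
baf       mean AP/cell= 9.67  mean AL/cell= 0.83
control   mean AP/cell= 3.11  mean AL/cell= 3.03
drug      mean AP/cell= 1.72  mean AL/cell= 9.47
drug_baf  mean AP/cell=22.92  mean AL/cell= 0.67
verdict: flux_induced
```

Read: the drug triples autolysosomes relative to control (3.03 → 9.47 per
cell) while autophagosomes fall, and with lysosomal fusion blocked by
bafilomycin the drug more than doubles autophagosome accumulation (9.67 →
22.92) — the two significant contrasts that together call induced flux.

The same pipeline is available from the shell:

```sh
fluxquant simulate cohort --seed 1 --effect flux_induced --out cohort/
fluxquant quantify --images cohort/ --sheet cohort/sample_sheet.csv --out quant/
fluxquant fluxstats --results quant/field_quantification.csv --out stats/
fluxquant qpcr --ct ct_table.csv --targets GABARAPL1,WIPI1 --refs SDHA,HPRT \
    --control control --out qpcr/
fluxquant xeno --volumes volumes.csv --out response/
```

Each subcommand writes a `provenance.json` (config, version, seed); a fixed
seed reproduces every output byte for byte.

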