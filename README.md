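# nbpanel

Targeted-panel tumor sequencing analysis toolkit, built around an 83-gene
pediatric solid-tumor panel workflow:

- **Somatic variant filtering** — merge calls from multiple callers (union,
  median allele fraction), remove alignment artifacts (exact binomial
  strand-bias test, 3-in-10-bp cluster rule) and likely germline variants
  (VAF ≥ 97% unless hotspot; population AF ≥ 1%; panel-of-normals ≥ 3% of 480).
- **Copy-number calling with tumor-purity adjustment** — median-normalized
  exon coverage against a normal reference, log2 ratios, grid-search purity
  estimation from coverage + B-allele frequencies under the mixture model
  `r = (p·CN + 2(1−p))/2`, and per-gene CN classification
  (loss: CN < 1, gain: CN > 4, strict).
- **MYCN FISH scoring** — summed MYCN/CEP2 signal ratio over 50 nuclei,
  amplified at ≥ 10-fold.
- **Actionability** — patient × gene alteration matrix and a packaged,
  editable drug-matching rule set (ALK hotspots/gain, BRCA1 truncating,
  ATM/STK11 loss, HRAS Q61R, MET exon-14 skip, ERBB2 gain).
- **Cohort statistics** — prevalence tables, Kaplan-Meier with Greenwood
  standard errors, G-group log-rank tests, three-stratum survival summaries
  and an ARID1-family × MYCN mutual-exclusivity check (Fisher exact).
- **Synthetic cohort simulator** — calibrated per-gene alteration
  prevalences, negative-binomial exon depths scaled by purity-mixed copy
  number, binomial BAF draws, per-caller outputs with injected artifact
  false positives, Poisson FISH counts and stratum-specific exponential
  survival. Everything is a pure function of (config, seed).

## Tests

```sh
python -m pytest tests/
```

The suite includes property tests (hypothesis), brute-force oracles for the
survival statistics (`tests/oracles.py`) and `tests/test_acceptance.py`,
which runs the full acceptance criteria including a 2000-cohort
end-to-end recovery simulation (a few minutes on one CPU).

## CLI

```sh
nbpanel simulate --seed 1 --out run/           # simulate + analyze a cohort
nbpanel filter-variants --calls a.tsv --calls b.vcf --out out/
nbpanel call-cnv --coverage cov.tsv --baf baf.tsv --reference ref.tsv --out out/
nbpanel score-fish --counts fish.csv
nbpanel report --cohort run/
```

Thresholds live in a YAML config (`--config`); defaults are packaged in
`src/nbpanel/data/default_config.yaml`.

## Layout

```
src/nbpanel/
  panel_io.py         # BED/VCF/TSV/CSV readers+writers, PipelineConfig, report
  synthetic_cohort.py # cohort truth, coverage/BAF, caller, FISH, survival simulators
  variant_filter.py   # merge, artifact filter, germline filter, annotation
  cnv_purity.py       # normalization, purity grid search, CN calling
  fish_mycn.py        # FISH amplification scoring
  actionability.py    # alteration matrix + drug-matching rules
  cohort_survival.py  # prevalence, KM, log-rank, exclusivity, stratification
  pipeline.py         # end-to-end orchestration
  cli.py              # click entry points
  data/               # packaged panel, resources, rules, default config
```
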