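# foodprofiler

Packaged foods can be judged "healthy" by very different yardsticks: nutrient
profiling models score what a product *contains*, while processing-based
systems such as NOVA classify what was *done* to it. `foodprofiler` implements
both kinds of engine for the Thai policy landscape and measures how much they
agree, so that researchers comparing classification systems on market data
(e.g. Mintel-GNPD-style product feeds) can run the whole pipeline — curation,
fiber imputation, classification, agreement statistics — reproducibly from
configuration files.

The package implements four classifiers over a per-100 g/ml nutrient panel and
an ordered ingredient list:

* **DOH** (Thai Department of Health style): per-category point scores with
  Group A (score ≥ 80% of the category maximum), Group B (60–<80%) and
  Group C (<60%), plus auto-prohibited categories and an independent
  marketing-criteria layer;
* **WHO SEA** (WHO South-East Asia style): marketing is prohibited if the
  product exceeds *any one* of its category's thresholds for total fat,
  saturated fat, total sugars, added sugars or sodium;
* **HCL** (Healthier Choice Logo style): logo eligibility requires *every*
  criterion of the food category to hold;
* **NOVA**: ultra-processed (UPF) if the ingredient list contains a marker —
  a substance of no culinary use or a cosmetic additive class — otherwise
  processed culinary ingredient (PCI), processed (P), or minimally
  processed (MP) via a fixed cascade.

Outcomes are dichotomized (Group A / marketing permitted / logo eligible /
non-UPF = healthy) and pairwise agreement on the complete-case sample is
Cohen's kappa on the 2×2 cross-tabulation,

    po = (n11 + n22) / n
    pe = [(n11+n12)(n11+n21) + (n21+n22)(n12+n22)] / n²
    κ  = (po − pe) / (1 − pe)

with the conventional interpretation bands (0.01–0.20 none to slight,
0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80 substantial, 0.81–1.00 almost
perfect).

The threshold tables shipped under `src/foodprofiler/fixtures/` are clearly
labeled **synthetic test configurations** — the engines are fully
config-driven and official rulesets can be supplied as YAML files of the same
schema. A seeded synthetic-data module generates Mintel-like product sets
(per-category log-normal nutrient panels, lexicon-assembled ingredient lists,
injected duplicates and blank panels) and labeled benchmarks whose intended
outcome under every fixture ruleset is attainable by construction.

## Worked example

```python
from foodprofiler import (curate_products, impute_fiber, classify_doh, classify_whosea,
                          classify_hcl, classify_nova, dichotomize, restrict_to_complete,
                          crosstab_2x2, cohen_kappa)
from foodprofiler.synthetic import GeneratorSpec, generate_products

raw = generate_products(GeneratorSpec(n_products=4000, seed=1))
curated, report = curate_products(raw)
print(f"raw records: {len(raw)}")
print(f"curated: {report.n_output} (removed {report.n_removed_no_nutrients} blank panels, "
      f"{report.n_removed_duplicates} duplicates, "
      f"{report.n_removed_excluded_category} excluded categories)")

products, fiber_report = impute_fiber(curated)
print(f"fiber imputed for {fiber_report.total - fiber_report.n_declared_kept} products")

flags = [dichotomize(p.product_id, classify_doh(p), classify_whosea(p),
                     classify_hcl(p), classify_nova(p)) for p in products]
complete = restrict_to_complete(flags)
print(f"classifiable by all four systems: {len(complete)}")

res = cohen_kappa(crosstab_2x2(complete, "DOH", "NOVA"))
print(f"DOH vs NOVA: kappa={res.kappa_3dp:.3f} "
      f"({res.percent_agreement:.2f}% agreement, {res.band.value})")
```

prints

```
raw records: 4117
curated: 2177 (removed 1887 blank panels, 53 duplicates, 0 excluded categories)
fiber imputed for 1299 products
classifiable by all four systems: 614
DOH vs NOVA: kappa=-0.045 (71.17% agreement, negative)
```

The generator emits a raw feed, so nearly half the records arrive without a
nutrient panel and are dropped at curation, together with verbatim duplicates.
Fiber is then estimated for products that do not declare it, each product is
classified under all four systems, and agreement statistics run on the
products every system could classify. The kappa here describes agreement
between the *fixture* rulesets on *synthetic* data — it is expected to differ
from values observed on real market data with official thresholds.

The same pipeline is available from the shell:

```bash
foodprofiler simulate --n 4000 --seed 1 --out products.csv
foodprofiler curate products.csv --out curated.csv
foodprofiler impute-fiber curated.csv --out imputed.csv
foodprofiler classify imputed.csv --system all --out labels.csv
foodprofiler compare labels.csv --out-dir report/
```

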