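# fediv — functional-entity diversity for categorical trait data

`fediv` analyses the functional structure of species assemblages that are
described by categorical traits, the setting typical of regional reef-fish
faunas: each species carries a handful of categorical trait values (body-size
class, diet, mobility, gregariousness, activity period, vertical position),
and every unique combination of values defines a **functional entity (FE)**.
The package builds the entities, embeds them in a multidimensional trait
space, and quantifies, per regional assemblage and for the pooled fauna:

- **FRic** — functional richness: the volume of the convex hull of an
  assemblage's entities on the retained PCoA axes, as a percentage of the
  pooled hull volume;
- **FR** — functional redundancy: the mean number of species per entity,
  FR = S/FE, with its standard error across entities;
- **FV** — functional vulnerability: the percentage of entities supported by
  exactly one species, equivalently
  FV = 100·(FE − Σᵢ min(nᵢ−1, 1))/FE;
- **FOR** — functional over-redundancy: the percentage of species packed into
  entities richer than the mean, FOR = 100·Σᵢ max(nᵢ − FR, 0)/S;
- the contribution of regionally **unique species** (present in exactly one
  region) to FV.

The trait space is built from pairwise Gower dissimilarities between entities
(0/1 mismatches for nominal traits, rank-range-normalized differences for
ordered ones) followed by principal coordinates analysis with a Cailliez
correction for negative eigenvalues; its fidelity is reported as the mean
squared deviation (mSD) between input and embedded distances and a permutation
Mantel test. Observed FV and FOR are tested against a constrained null model
that keeps S and FE fixed: every entity is seeded with one species and the
remaining S − FE species are scattered uniformly, yielding a bilateral
Monte-Carlo p-value and a standardized effect size (SES). A fine-to-crude
category collapse reruns everything at coarser trait resolution as a
sensitivity analysis. A synthetic-data generator produces species tables with
the right-skewed entity-occupancy distribution and nested richness gradient
such faunas exhibit, so the whole pipeline runs without any data download.

## Worked example

```python
import fediv

cfg = fediv.SyntheticConfig(n_species=300, seed=1)
df, truth = fediv.generate(cfg, csv_path="species.csv")
schema = fediv.default_fine_schema()
records = fediv.load_trait_table("species.csv", schema)
entities = fediv.build_entities(records, schema, truth["region_names"])

D = fediv.gower_matrix(entities, schema)
space = fediv.pcoa_cailliez(D, m=4)
quality = fediv.space_quality(D, space, permutations=999, seed=0)
print(f"entities: {entities.n_entities}  mSD: {quality.msd:.3f}  "
      f"Mantel r: {quality.mantel_r:.2f} (p = {quality.mantel_p:.3f})")

report = fediv.report_frame(fediv.summarize(entities, space))
print(report.to_string(index=False))

nulls = fediv.run_null_tests(entities, n_sims=999, seed=0)
print(nulls[["assemblage", "statistic", "observed", "sim_mean",
             "p_two_sided", "ses"]].round(3).to_string(index=False))
```

prints

```
entities: 84  mSD: 0.016  Mantel r: 0.77 (p = 0.001)
assemblage   S  FE  FRic_pct  FR  FR_se  FV_pct  FOR_pct  uniqueFV_pct
     South 300  84     100.0 3.6    0.4    32.1     33.3           8.3
      East 207  60      89.2 3.4    0.5    28.3     34.0           0.0
      West 150  57      80.9 2.6    0.4    47.4     34.0           0.0
     North 126  49      75.8 2.6    0.4    44.9     33.3           0.0
    pooled 300  84     100.0 3.6    0.4    32.1     33.3           8.3
assemblage statistic  observed  sim_mean  p_two_sided    ses
     South        FV    32.143     7.571        0.002  9.905
     South       FOR    33.286    18.142        0.002 10.900
      East        FV    28.333     8.315        0.002  6.389
      East       FOR    34.034    18.304        0.002  9.512
      West        FV    47.368    19.263        0.002  6.886
      West       FOR    34.000    19.685        0.002  8.352
     North        FV    44.898    20.204        0.002  5.512
     North       FOR    33.333    19.786        0.002  7.452
    pooled        FV    32.143     7.519        0.002  9.412
    pooled       FOR    33.286    17.995        0.002 10.970
```

Reading the report: the 300 synthetic species collapse into 84 entities, so on
average FR ≈ 3.6 species back up each trait combination, yet 32% of the pooled
entities rest on a single species (FV) while a third of all species are packed
into already well-covered entities (FOR). The richest region spans the whole
trait space (FRic 100%), and the poorest still spans three quarters of it —
richness loss erodes redundancy before it erodes the breadth of trait
combinations. Every observed FV and FOR sits far outside the constrained null
(p = 0.002, the smallest value 999 simulations can resolve; SES 5–11), so the
packing of species into few entities is strongly non-random.

The same pipeline runs from the shell:

```bash
fediv simulate --n-species 300 --seed 1 --outdir data/
fediv run --input data/species.csv --seed 0 --nsims 9999 --collapse --outdir out/
fediv nulltest --input data/species.csv --nsims 999 --seed 0 --outdir out-null/
```

`fediv run` writes the entity table, PCoA coordinates and eigenvalues, the
diversity report (CSV and full-precision JSON), the null-model results, the
space-quality record, and a manifest that pins every seed and parameter;
`--collapse` adds the crude-categorization rerun (`crude_*` files).

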