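# tepuidiet

Diet-composition analysis for stomach-content studies of small
insectivorous anurans — written around the dietary ecology of the
tepui-summit toads *Oreophrynella quelchii* and *O. nigra*, but usable
for any per-prey-item gut-content table.

Dietary studies of small amphibians share a standard analysis surface:
dissected guts are classified (analyzable / empty / unidentifiable
matter only), identifiable prey items are assigned to coarse taxonomic
categories and measured, and the diet is summarized per category as

- **%FO** — frequency of occurrence: stomachs containing the category /
  analyzable stomachs × 100;
- **%N** — numerical percentage: items of the category / all
  identifiable items × 100;
- **%V** — volumetric percentage, with per-item volume estimated from
  maximum length *L* and width *W* by the ellipsoid approximation
  V = (4π/3)(L/2)(W/2)²  (mm³);
- **IRI** — index of relative importance, classically
  IRI = %FO × (%N + %V), normalized to **%IRI** shares.

Diet specialization is quantified by standardized Levins niche breadth

    B = 1 / Σ pⱼ²,    B_st = (B − 1) / (n − 1) ∈ [0, 1],

where pⱼ is the proportion of prey individuals in category *j* and *n*
the number of categories (B_st ≈ 0: specialist; ≈ 1: generalist), and
per-specimen richness and Shannon–Wiener diversity H′ = −Σ p ln p are
compared between sexes or species with two-sided
Mann–Whitney–Wilcoxon tests (exact by complete enumeration up to
n₁ + n₂ = 20, mid-ranks for ties; tie-corrected normal approximation
with continuity correction beyond).

A synthetic gut-content generator reproduces the statistical structure
of such studies (multinomial category composition, zero-truncated
per-stomach item counts, truncated-lognormal prey sizes, empty and
unidentifiable-only guts, fragmented items), so the entire pipeline is
testable and calibratable without access to raw field data. See
`docs/methods.md` for model details and limitations.

Both IRI conventions found in the literature (`multiplicative`, the
default, and `additive_as_printed`) are implemented, and
`implied_volume_feasibility` turns the choice into a checkable
statement about whether published %IRI values could have arisen from a
given convention.

## Worked example

```python
from tepuidiet import (default_config, generate_dataset, filter_analyzable,
                       iri_table, standardized_niche_breadth, compare_groups)
from tepuidiet.composition import metrics_frame

cfg = default_config("quelchii")          # 111 specimens, 13 categories
ds = generate_dataset(cfg, seed=42)
filtered, summary = filter_analyzable(ds)
print(f"specimens: {summary.n_total}  empty: {summary.n_empty} ({summary.pct_empty}%)  "
      f"unidentifiable-only: {summary.n_unidentifiable_only} "
      f"({summary.pct_unidentifiable_only}%)  analyzable: {summary.n_analyzable}")

m = metrics_frame(iri_table(filtered))
print(m[["category", "n_items", "FO_pct", "N_pct", "V_pct", "IRI_pct"]]
      .head(5).round(1).to_string(index=False))

counts = filtered.prey["category"].value_counts()
b = standardized_niche_breadth((counts / counts.sum()).to_numpy())
print(f"B = {b.B:.3f}  B_st = {b.B_st:.3f}  (n = {b.n} categories)")

cmp = compare_groups(filtered, "sex", "H")
print(f"sex comparison: W = {cmp.W:.1f}, p = {cmp.p_value:.3f} ({cmp.method})")
```

prints (seed 42):

```
specimens: 111  empty: 6 (5.4%)  unidentifiable-only: 17 (15.3%)  analyzable: 88
                  category  n_items  FO_pct  N_pct  V_pct  IRI_pct
                     Acari       94    64.8   39.8    2.0     40.5
                Coleoptera       49    42.0   20.8   28.7     31.1
                  Annelida       22    22.7    9.3   39.1     16.5
Hemiptera_excl_Heteroptera       25    25.0   10.6    4.6      5.7
                   Diptera       10    11.4    4.2    8.1      2.1
B = 4.372  B_st = 0.307  (n = 12 categories)
sex comparison: W = 2101.5, p = 0.399 (normal_approximation)
```

Reading: 88 of 111 simulated guts were analyzable; mites (Acari)
dominate numerically (39.8 % of items) and by relative importance
(40.5 % of the summed IRI) while soft-bodied, larger Annelida dominate
volumetrically; B_st ≈ 0.31 indicates a moderately narrow dietary
niche; per-specimen Shannon diversity does not differ between the sexes
(p = 0.40). Mites are tiny, so their %V is small despite numerical
dominance — exactly the divergence between %N and %V that motivates the
composite IRI.

The same analysis runs from the shell:

```sh
tepuidiet simulate --species quelchii --seed 42 --out sim/
tepuidiet summarize --specimens sim/specimens.csv --prey sim/prey.csv --out report/
```

`report/` then holds per-species category-metrics TSVs (one-decimal
rendering plus full-precision CSV copies), per-specimen diversity,
niche breadth and the pairwise rank-sum comparisons, with the seed and
analysis modes recorded in `run_info.json`.

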