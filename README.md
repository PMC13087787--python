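# fdshift

Decadal change in the functional diversity of a species assemblage —
who drove it, and through what: species turnover or trait shifts?

`fdshift` implements, as one reproducible pipeline, the analysis chain
used to ask that question of a two-period (1990 vs 2020) fish resurvey
of a tropical montane river basin:

1. **Trait standardization** — ten strictly positive morphological
   traits, natural-log transformed and Z-scored over the pooled species
   of both periods, so both periods live in one functional space.
2. **Paired trait tests** — per-site community-weighted means
   (CWM = Σᵢ Pᵢ Xᵢ) compared across periods with assumption gating
   (Shapiro–Wilk + Brown–Forsythe → paired t, else Wilcoxon signed-rank)
   and paired Cohen's d = mean(diff)/sd(diff).
3. **Functional space and indices** — PCoA of Euclidean trait distances
   (automatic Lingoes correction); per-site FRic (convex-hull volume),
   FEve (minimum-spanning-tree evenness) and FDiv (divergence from the
   hull centroid) on the first four axes.
4. **Kernel hypervolumes** — Gaussian-mixture density in the full
   10-trait space (per-dimension Silverman bandwidth), volume of the 95%
   superlevel set by importance sampling, Sørensen overlap
   2V∩/(V_A+V_B) between status/period groups, a 999-permutation label
   null and a 999-replicate species bootstrap.
5. **Counterfactual decomposition** — per-site ΔFRic split into native
   turnover (X1), native trait shift (X2), non-native turnover (X3) and
   non-native trait shift (X4) by swapping exactly one ingredient to its
   second-period state; variation partitioning over all 15 subsets with
   adjusted R², unique/shared fractions by inclusion–exclusion
   (cross-checked against `vegan::varpart`).
6. **Spatial GLS drivers** — ΔCWM and Δindices against nine scaled
   environmental predictors; Moran's I screening, exponential / Gaussian /
   spherical correlation structures fitted by ML (validated against
   `nlme::gls`), VIF < 5 filtering, all-subsets AIC dredging capped at
   ⌊n/3⌋ parameters, ΔAIC < 2 Akaike-weight model averaging, predictors
   retained at importance > 0.5.

A synthetic-survey generator with known ground truth (species losses,
trait shifts, environment–trait links, spatial error) makes every stage
testable end-to-end without any download; see `docs/methods.md` for the
model and its limits.

## Worked example

```python
from fdshift import SyntheticScenario, generate_scenario
from fdshift.decomposition import build_components, build_shared_space, variation_partition
from fdshift.hypervolume import survey_overlap_table

pair, sites, truth = generate_scenario(SyntheticScenario(rng_seed=1))
fs, st = build_shared_space(pair)          # pooled log/Z + PCoA

print(f"PCoA axes 1-2: {100 * fs.proportion_explained[:2].sum():.1f}% of variation")

vp = variation_partition(build_components(pair, fs=fs))
print({k: round(v, 3) for k, v in vp.marginal_r2.items()})

tab = survey_overlap_table(st, n_perm=99, n_boot=99, seed=1,
                           samples_per_point=200,
                           resample_samples_per_point=50)
print(tab[["comparison", "sorensen", "p_null"]].round(3).to_string(index=False))
```

prints

```
PCoA axes 1-2: 42.6% of variation
{'X1': 0.606, 'X2': -0.054, 'X3': 0.681, 'X4': 0.074}
              comparison  sorensen  p_null
     native_1990_vs_2020     0.139    0.01
  nonnative_1990_vs_2020     0.001    0.37
native_vs_nonnative_1990     0.000    0.33
native_vs_nonnative_2020     0.023    0.02
```

Reading: in this synthetic basin the first two ordination axes carry
~43% of trait variation; the loss of native species (X1, marginal
adjusted R² ≈ 0.61) and the arrival of non-natives (X3 ≈ 0.68) dominate
the change in per-site functional richness, while trait shifts
contribute little (a mean shift is mostly a translation of the cloud,
which cannot change hull volume; only its per-species scatter can);
natives' functional space retains only ~14% overlap across the three
decades, significantly less than random relabelling would produce
(p = 0.01).

The same pipeline runs from the shell:

```bash
fdshift simulate --seed 1 --outdir survey/        # or bring your own CSVs
fdshift run --seed 1 --outdir out/                # full pipeline + manifest
fdshift decompose --indir survey/ --out vp.json   # single stages
fdshift overlap --indir survey/ --out overlaps.csv
fdshift report --outdir out/
```

### Input schema

`traits_<period>.csv`: `species_id,status,BodyMass,BD_SL,BD_BW,CFd_CPd,HL_SL,HD_BD,SnL_HD,Mo_HD,EH_HD,ED_HD`
(status ∈ {native, non_native}; raw positive trait values).
`community_<period>.csv`: `site_id` plus one column per species.
`sites.csv`: `site_id,x,y,MAP,MAT,ChlA,DO,EC,Forest,Dam,POP,Intro`
(projected coordinates; predictors are scaled internally).

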