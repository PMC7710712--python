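# parabias

**Sex-biased parasitism and sex-specific mortality in birds: a phylogenetic
meta-analysis and PGLS pipeline.**

Across many bird species, published surveys report parasite prevalence
(the proportion of examined individuals that are infected) separately for
males and females. Two comparative questions follow: *do males carry more
parasites than females?*, and *does the sex that is more parasitized also
die at a higher annual rate?* Answering either requires combining hundreds
of heterogeneous studies while accounting for the shared evolutionary
history of the host species. `parabias` implements that analysis as a
tested, reusable Python library with a thin command-line front end, for
comparative ecologists and parasitologists working from study-level
prevalence tables, species-level trait tables, and candidate phylogenies
(e.g. from birdtree.org).

## What it computes

**Sex-bias effect sizes.** Each study's 2×2 table (infected/uninfected ×
male/female) yields a log odds ratio

y<sub>i</sub> = ln[(a/b)/(c/d)],  v<sub>i</sub> = 1/a + 1/b + 1/c + 1/d,

with the Haldane–Anscombe continuity correction (+0.5 to all four cells)
applied only to tables containing a zero cell. Positive y<sub>i</sub> means
male-biased prevalence.

**Phylogenetic multilevel meta-analysis.** Effect sizes are modelled as

y = Xβ + Z<sub>p</sub>u<sub>p</sub> + Z<sub>s</sub>u<sub>s</sub> + e,  u<sub>p</sub> ~ N(0, σ²<sub>phylo</sub> R),  u<sub>s</sub> ~ N(0, σ²<sub>study</sub> I),  e<sub>i</sub> ~ N(0, v<sub>i</sub>),

where R is the species correlation matrix derived from the phylogeny, X
carries the intercept plus sampling-period and detection-method moderators,
and variance components are estimated by REML. The pipeline reports the
pooled estimate with Wald Z and 95% CI, residual-heterogeneity Q, Egger's
regression test for publication bias (the effect's standard error added as
a moderator; asymmetry called at P < 0.10), leave-one-out influence
diagnostics, and an outlier-excluded refit when asymmetry is flagged.

**PGLS with maximum-likelihood Pagel's λ.** Species-level regressions of
logit annual mortality (and the mortality sex bias, log(male/female)) on
logit prevalence (and the prevalence sex bias, SSD = log mass ratio, and
the polygamy-score difference), with residual covariance σ²·C(λ) where
C(λ) scales the phylogenetic covariances by λ ∈ [0, 1] estimated by
profile maximum likelihood. Per parasite class the phylogeny is a 50%
majority-rule consensus of a seeded subsample of candidate trees, with
polytomies resolved by inserting 10⁻⁸-length branches.

**Synthetic data.** A seeded generator produces ultrametric trees,
study tables with binomial counts, and trait tables with the exact
statistical structure the models assume, so every stage has a no-download
test bed and parameter-recovery oracle.

## Worked example

Simulate a 40-species blood-parasite dataset and run the whole analysis:

```bash
parabias simulate --seed 7 --n-species 40 --out sim
# wrote 106 studies, 40 species to sim
parabias all --config cfg.yaml        # cfg.yaml points at sim/, outdir: out
```

A single study's effect size, from the library:

```python
>>> from parabias.data_io import StudyRecord
>>> from parabias.effect_sizes import compute_log_or
>>> rec = StudyRecord(study_id="S1", species="Parus major",
...                   parasite_class="blood", parasite_category="Haemoproteus",
...                   males_examined=20, males_infected=15,
...                   females_examined=20, females_infected=5,
...                   period="breeding", detection="microscopy")
>>> e = compute_log_or(rec)
>>> print(f"yi={e.yi:.5f} vi={e.vi:.5f}")
yi=2.19722 vi=0.53333
```

15/20 infected males versus 5/20 females is an odds ratio of 9, i.e. a
strongly male-biased log odds ratio of 2.197 with sampling variance 0.533.

The run directory then contains `meta_results.csv` (one row per parasite
class and category), e.g.

```
analysis,group,k,n_species,n_studies,estimate,ci_low,ci_high,Z_or_t,P,Q,Q_df,Q_P,...
blood,overall,106,40,106,0.14083431,-0.095106133,0.37677475,1.1699146,0.24203533,344.4691,101,2.5159108e-28,,
```

— 106 effect sizes over 40 species give a pooled sex-bias log odds ratio of
0.141 (95% CI −0.095 to 0.377): no significant sex bias (Z = 1.17,
P = 0.24), but strong residual heterogeneity (Q = 344.5 on 101 df).
`pgls_results.csv` holds the six-model PGLS suite per class, e.g.

```
blood:male_single,logit_prev_m,40,40,,0.0094372335,...,0.93254971,,,,0.87143022,-0.026119773
```

— male mortality is unrelated to male prevalence (slope 0.009, P = 0.93)
with substantial phylogenetic signal in the residuals (λ = 0.871), as this
dataset was simulated without a prevalence–mortality link.

Other outputs: per-study and per-species effect-size CSVs, consensus trees
(Newick), forest- and scatter-plot data files, a verbatim config copy and a
manifest with input checksums — enough to reproduce any run exactly.

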