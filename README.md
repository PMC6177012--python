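# midflux

Analysis pipeline for targeted GC-MS stable-isotope-tracer metabolomics
of pooled *Drosophila* larval samples — built around the question of how
mitochondrial citrate transport (the *SLC25A1*/*sea* carrier) restrains
glycolytic flux and L-2-hydroxyglutarate (L-2HG) accumulation.

The package covers the full computational chain such a study needs:

1. **Natural-abundance correction.** A measured mass-isotopomer
   distribution (MID) mixes tracer labeling with naturally occurring
   heavy isotopes (1.07% ¹³C, 0.2% ¹⁸O, …). For a fragment with known
   elemental formula we build the column-stochastic matrix `A` with
   `A[i,j] = P(molecule with j tracer atoms observed at mass shift m+i)`
   and recover the labeling distribution `x` from the raw vector `v` by
   solving `A·x ≈ v` with non-negative least squares (Moore–Penrose
   pseudo-inverse available as an alternative).
2. **Flux estimation.** With dietary tracer enrichment `p` (here 50%
   ¹³C₆-glucose) and labeling time `t` (2 h), a single well-mixed pool
   follows `X^L/X^T = p·(1 − exp(−f_x·t/X^T))`, where `X^L` is the
   tracked labeled isotopologue (lactate/pyruvate m+3, 2HG/citrate m+2)
   and `X^T` the total pool. The closed-form inverse
   `f_x = −(X^T/t)·ln(1 − (X^L/X^T)/p)` gives a per-sample relative flux;
   enrichment at or above `p` is flagged saturated rather than clipped.
3. **Cohort statistics.** Normalization to sample mass and a d4-succinate
   internal standard, fold change vs a control genotype, two-tailed
   Student's *t*-tests with Bonferroni correction across the metabolite
   panel, Pearson correlation between metabolite pools, and PCA of the
   normalized profiles.
4. **Synthetic cohorts.** A seeded generator emulating the study designs:
   5–6 replicate pools per genotype, multiplicative group effects,
   log-normal noise, a lactate→2HG coupling with analytically known
   Pearson r, and labeling experiments whose raw MIDs carry
   natural-abundance convolution — so every stage is testable end to end
   without deposited raw data.

## Worked example

```sh
midflux simulate --scenario glucose_labeling_flux --seed 2 --out-dir demo
midflux correct --mid-table demo/mid_table.csv --out demo/corrected.csv
midflux flux --corrected-mids demo/corrected_enrichment.csv \
             --pools demo/pool_table.csv \
             --reference-group sea_prec_df --out demo/flux.csv
```

or, equivalently, the numbered drivers under `analysis/`:

```sh
python analysis/01_simulate_cohorts.py
python analysis/03_flux_analysis.py
```

which prints (seed 1):

```
32 flux estimates, 0 saturated
          2HG: flux ratio 1.16 (p_adj = 0.227)
 *    citrate: flux ratio 0.80 (p_adj = 0.0356)
 *    lactate: flux ratio 1.69 (p_adj = 9.62e-05)
     pyruvate: flux ratio 1.28 (p_adj = 0.0697)
```

Reading: in the simulated mutant-vs-control labeling experiment the
mutant's glucose-to-lactate flux is ~1.7× control (significant after
Bonferroni), citrate labeling is slightly but significantly reduced, and
the pyruvate/2HG increases are modest — the signature of de-repressed
glycolysis with intact TCA input. `analysis/02_steady_state_comparison.py`
runs the steady-state track for every genotype preset, and
`analysis/04_lactate_2hg_coupling.py` checks the measured lactate–2HG
correlation against its configured analytic value (r ≈ 0.973).

A full pipeline run from one YAML config (both tracks, provenance log,
deterministic outputs):

```sh
midflux run --config config.yaml
```

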