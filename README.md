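# ratemaps

Fine-scale **mutation- and recombination-rate maps** for the aye-aye
(*Daubentonia madagascariensis*), an endangered strepsirrhine primate and one
of the earliest splits in the primate clade. The package implements, as a
tested and fully synthetic-data-exercisable pipeline:

1. **Divergence-based mutation-rate maps.** In neutral regions the per-site
   substitution rate equals the mutation rate (Kimura), so single-lineage
   divergence *d* accumulated over *T* years at generation time *G* satisfies
   *d = μ·(T/G)*. Sliding-window divergence (divergent sites / accessible
   sites, with segregating polymorphisms excluded from the numerator and
   10 kb flanks around functional regions masked) converts directly into
   per-window *μ*, and pedigree-based *μ* estimates convert back into
   divergence times.
2. **LD-based recombination-rate maps.** Per-window population recombination
   rates *ρ = 4Nₑr* are estimated from phased haplotype panels by maximizing
   a **pairwise composite likelihood**: every SNP pair within a 30-SNP span
   is scored against a demography-aware **two-locus lookup table**
   P(config | ρ, n) built by Monte-Carlo coalescent sampling under the
   species' bottleneck-decline history. ρ is converted to *r* (and cM/Mb,
   with 1e-8 crossovers/bp/gen ≡ 1 cM/Mb) through Watterson's
   θ̂ = S/(H₍ₙ₋₁₎L) and a user-specified mutation rate; extreme outlier
   windows (>100× the genome mean) are removed and the map is rescaled so
   its total genetic length matches the pedigree-based map (1525 cM),
   preserving relative rates.
3. **An estimator benchmark** under the study design: bottleneck-decline
   (11,695 → 1,285 diploids over the final 1,133 generations) vs equilibrium
   demographies × mutation rates {0.4e-8, 1.1e-8} × 10 replicates at a true
   rate of 0.85 cM/Mb with five diploids sampled.
4. **Haar-wavelet multi-scale correlations** of recombination against
   nucleotide diversity, divergence, GC-content and exon-content in 1 kb
   bins: orthonormal Haar detail coefficients per 2ʲ kb scale, pairwise
   Kendall rank correlations (1% two-tailed level), and through-origin
   linear models with uncentered adjusted R².

All inputs can be generated synthetically — including haplotype panels from
a built-in SMC' coalescent-with-recombination simulator (cross-validated
against msprime in the test suite) — so every stage runs without downloads.

## Layout

- `src/ratemaps/` — the library: `synthdata`/`coalescent` (generators),
  `divmut` (divergence & mutation maps), `twolocus`/`ldrec` (recombination
  estimation), `wavescale` (wavelet analysis), `variants` (SNP filters),
  `io`, `pipeline`, `cli`.
- `analysis/` — numbered drivers (`01_simulate_inputs.py` …
  `06_wavelet_analysis.py`) that run each stage on synthetic data and write
  tables under `results/`.
- `ratemaps` console command — `simulate | filter | divmut | ldrec |
  wavescale | benchmark | all` over a YAML config.

## Worked example

```bash
python analysis/03_mutation_rate_map.py
```

prints (4 Mb synthetic scaffold, divergence generator targeting d = 0.043):

```
genome-wide divergence d = 0.0459 (generator target 0.043)
1 Mb windows: 7; relative RMSE of recovered mu vs truth: 0.033
conversion table (d = 0.043):
 G_years  T_mya_at_mu_4e-09  T_mya_at_mu_1.1e-08  T_mya_at_mu_2e-08  mu_at_T_54.9mya  mu_at_T_74.7mya
     3.0               32.3                 11.7               6.45     2.350000e-09     1.730000e-09
     5.0               53.8                 19.5              10.80     3.920000e-09     2.880000e-09
```

The left half converts three pedigree-based mutation rates into divergence
times (e.g. μ = 4e-9 and G = 5 y imply a split ~53.8 Mya, consistent with
the earliest primates in the fossil record); the right half converts two
divergence-time bounds into mutation rates (1.73e-9–3.92e-9 /bp/gen,
supporting comparatively low mutation rates in this lineage). And

```bash
python analysis/05_estimator_benchmark.py
```

reports, per demography × mutation rate, the median estimated rate, bias
and ratio-to-truth of the composite-likelihood estimator before rescaling
(e.g. equilibrium medians within ~15% of the 0.85 cM/Mb truth on 200 kb
regions; the direction of bias under decline is reported, not asserted).

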