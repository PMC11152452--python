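# transinv

Analysis toolkit for **trans-species chromosomal inversion polymorphisms** in
population genotype data — inversions whose alternative arrangements still
segregate in several descendant species of a radiation. Written for
population geneticists working with multi-population biallelic SNP call sets
(VCF) plus an outgroup, it covers the full inference chain:

1. **Detection** — sliding-window Hudson/Bhatia F_ST scans; an inversion is
   called as the block of windows above a threshold, with a buffer separating
   it from the collinear remainder of the chromosome.
2. **Genotyping** — local PCA inside the span; karyotypes AA/AD/DD are read
   off the trimodal PC1 distribution by deterministic 1-D k-means, with
   degeneracy diagnostics so plain population structure is not mistaken for
   an inversion.
3. **Validation** — heterozygosity excess and more negative F_IS
   (heterozygote excess) in heterokaryotypes.
4. **Polarization** — ancestral (A) vs. derived (D) arrangement by counting
   variants shared with an outgroup in 50-SNP windows (the derived
   arrangement starts as a single haplotype and carries almost no ancestral
   variation); neighbor-joining d_xy trees over homokaryotype groups provide
   the trans-species evidence.
5. **Dating** — π, d_xy, net divergence d_a = d_xy − (π_x+π_y)/2,
   t = d_a/(2µ) in years (default µ = 2.45×10⁻⁹ per site and year) and
   τ = d_xy/θ − 1 in coalescent units with θ = (π_x+π_y)/2; the
   inverted-vs-collinear contrast t_inv − t_out dates the inversion relative
   to speciation.
6. **Neutral expectation** — the probability that a neutral polymorphism is
   still shared by two populations t generations after a clean split,

   E[shared] = e^(−((N1+N2)/(N1·N2))·t/2) · (4/3)·µ·Na,
   E[total]  = (22/3)·µ·Na + 4·t·µ,
   fraction  = 2·e^(−((N1+N2)/(N1·N2))·t/2) / (11 + 6·t/Na),

   which equals 2/11 ≈ 0.18 at t = 0, plus a refined variant accounting for
   coalescence inside the daughter populations, and a structured-coalescent
   Monte-Carlo simulator that validates both.
7. **Selection** — unfolded-SFS statistics (Tajima's D, Fu & Li's D and F,
   normalized Fay & Wu's H, Zeng's E) per karyotype group, and isolation by
   distance/ecology: multiple regression on distance matrices (MRM) of
   arrangement-frequency differentiation on great-circle distance and
   environmental contrasts, with significance from a per-SNP null
   distribution built from the collinear genome (Bonferroni-corrected) and a
   slope contrast between inversion and collinear F_ST.

A fully seeded synthetic-data generator (`transinv.simulate`) produces
radiations with a trans-species inverted region, arrangement bottleneck,
environmental clines, an outgroup and missing data, so every stage is
testable without sequencing data.

## Worked example: is a trans-species inversion plausible under neutrality?

Suppose two species sharing an inversion polymorphism split τ = 0.28
coalescent units ago (τ = t/(2N)). What fraction of neutral polymorphisms
would still be shared?

```python
from transinv import CoalescentModel, trans_poly_fraction, \
    trans_poly_fraction_refined, simulate_partition

for tau in (0.28, 1.14):
    m = CoalescentModel.from_tau(tau)
    print(f"tau={tau}: plain={trans_poly_fraction(m):.4f} "
          f"refined={trans_poly_fraction_refined(m):.4f}")

m = CoalescentModel.from_tau(0.28, mu=1e-6)
p = simulate_partition(m, 200_000, seed=1)
print(f"simulated fraction={p.shared_fraction:.4f} +/- {p.shared_fraction_se():.4f}")
```

prints

```
tau=0.28: plain=0.0796 refined=0.0871
tau=1.14: plain=0.0083 refined=0.0109
simulated fraction=0.0875 +/- 0.0022
```

Reading: even at the shallow split τ = 0.28 only ~9% of polymorphisms are
expected to remain shared under drift alone (the supremum is 2/11 ≈ 0.18 for
populations that never split), and at τ = 1.14 — a typical whole-genome
divergence for a young radiation — the probability drops to ~1%. Observing
*several* large inversions all segregating trans-specifically is therefore
unlikely without balancing selection. The Monte-Carlo partition (independent
structured-coalescent genealogies, infinite sites) agrees with the refined
closed form within its standard error.

The same analysis is available from the shell:

```bash
transinv neutrality --tau 0.28 --simulate 200000 --seed 1
```

and the rest of the pipeline as
`transinv simulate | scan | genotype | validate | polarize | tree | date | sfs-stats | ibe`
(see `--help` on each subcommand).

## Scope notes

The package consumes called genotypes; read mapping, genotype-likelihood
estimation and ancestral-genome construction are upstream of it. Results
that depend on real whole-genome resequencing data — inversion spans in Mb
on a particular assembly, per-population-pair divergence-time tables,
variance-explained percentages — require those data and are outside the
test surface; see `docs/methods.md` for what the synthetic benchmarks do
and do not establish.
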