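# wasppop

Multi-scale population-structure and dispersal analysis for the northern
paper wasp (*Polistes fuscatus*) and similar lattice-dwelling insects:
from a multi-sample SNP VCF, a mitochondrial gene alignment and sample
coordinates to diversity statistics, pairwise F_ST, isolation-by-distance
(IBD) regression, Rousset dispersal-distance estimation, a sex-biased
dispersal test, classical MDS and minimum-spanning haplotype networks —
together with a forward-time stepping-stone simulator so every stage can
be verified against known ground truth.

## Who this is for

Population geneticists asking how far a philopatric, cooperatively
breeding insect actually disperses, when direct tracking is impractical.
The package turns genome-wide differentiation into a dispersal distance
and asks whether males and females disperse differently, at spatial
scales from a single forest to a subcontinent.

## The core inference

1. **Differentiation.** Nuclear pairwise F_ST between regions uses the
   Weir–Cockerham (1984) weighted estimator; mitochondrial F_ST uses
   Hudson's 1 − H_w/H_b on concatenated mitochondrial genes. Diversity
   (π, H_e, H_o, F_IS) is computed in 10-kb physical windows.
2. **Isolation by distance.** Ordinary least squares of linearized
   differentiation F_ST/(1 − F_ST) on great-circle distance between
   population centroids gives a slope *b* (per km); a seeded Mantel
   permutation p accompanies the OLS p because pairwise points are not
   independent.
3. **Dispersal.** Rousset's relation for a one-dimensional transect
   converts the slope into the mean squared parent–offspring axial
   dispersal distance:

       σ² = 1 / (4π · D_e · b)

   with D_e the effective breeder density (approximated by nest density,
   per km²). σ is reported in meters.
4. **Sex bias.** Under equal male and female dispersal in a diploid
   population, F_ST(mito) = 4F/(1 + 3F) with F the nuclear F_ST.
   A one-sample t-test on per-pair (observed − expected) differences
   detects sex-biased dispersal; excess mitochondrial structure indicates
   female philopatry with male-biased gene flow.

The simulator (`wasppop.synthetic_data`) embodies the same model: demes
of breeding females on a torus lattice, discretized-Gaussian dispersal
kernels with separate female and male axial SDs, diploid unlinked nuclear
SNPs, a maternally inherited mitochondrial sequence, and optional
haplodiploidy (haploid males). Its truth record predicts the IBD slope,
so parameter recovery is testable end to end.

## Worked example

Simulate a 20-deme ring (30 breeding females per deme, 1 km spacing,
σ_f = σ_m = 0.5 km), then run the inference chain:

```python
import wasppop as wp

cohort = wp.simulate(wp.SimulationConfig(seed=1))
pops = cohort.samples.groups("region_label")
fst = wp.pairwise_wc_fst(cohort.genotypes, pops)
geo = wp.geo_distance_matrix(cohort.samples, "region_label")
reg = wp.ibd_regression(fst, geo, permutations=999, seed=1)
print(f"slope b = {reg.slope_b:.4g} per km")
print(f"R^2 = {reg.r_squared:.2f}, Mantel p = {reg.mantel_p:.3g}")
est = wp.rousset_sigma(reg.slope_b, cohort.truth["De_females_per_km2"])
print(f"sigma_hat = {est.sigma_m:.0f} m")
```

prints

```
slope b = 0.01282 per km
R^2 = 0.87, Mantel p = 0.001
sigma_hat = 455 m
```

The fitted slope is close to the theoretical 0.01061 per km implied by
the simulation's density (30 females/km²) and dispersal (σ = 0.5 km), and
the recovered dispersal distance of 455 m sits within 10% of the true
500 m — noise from drift, finite sampling and the ring geometry accounts
for the rest.

The same chain runs from files via the command line:

```sh
wasppop simulate --seed 1 --out cohort/
wasppop run --config analysis.json        # filter -> prune -> stats -> FST -> IBD -> MDS -> network
wasppop dispersal --slope 1.27e-4 --density 1080 --density 2500
```

The last command evaluates the Rousset formula at a slope of
1.27×10⁻⁴ km⁻¹ for two density estimates and prints σ = 761.7 m and
σ = 500.6 m.

## Layout

| module | contents |
| --- | --- |
| `wasppop.io_metadata` | genotype/haplotype/metadata containers, VCF/FASTA/TSV IO, missingness + MAC filters, physical thinning |
| `wasppop.relatedness` | KING-robust kinship, greedy relatedness pruning |
| `wasppop.popgen_stats` | windowed π/H_e/H_o/F_IS, Weir–Cockerham and Hudson F_ST |
| `wasppop.ibd_dispersal` | distances, IBD regression, Rousset σ, sex-bias test |
| `wasppop.structure_viz` | IBS distances, classical MDS, haplotype networks |
| `wasppop.synthetic_data` | stepping-stone simulator with truth record |
| `wasppop.pipeline` | one-config orchestration and report bundle |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
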