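# mirage — miRNA-centred aging transcriptomics toolkit

`mirage` implements the computational core of a common experimental design
in aging biology: a microRNA (the miR-29 family is the motivating case)
rises strongly with age in neurons, and its loss of function — induced with
a transgenic *sponge* decoy — is compared against normal brain aging at the
transcriptome level. The package provides, as a tested reusable library:

- **Small-RNA read annotation** — quality/N filtering, mismatch-tolerant 3'
  adapter trimming, 18–33 nt size selection, and an exact two-phase
  annotator against a mature-miRNA reference: phase 1 places each whole
  read inside a mature sequence (sense strand, ungapped, ≤ 2 mismatches);
  phase 2 rescues 3'-extended isomiRs by placing a whole mature sequence
  inside the read.
- **Seed-site tools** — canonical 8mer / 7mer-m8 / 7mer-A1 site scanning on
  3'-UTRs, deterministic 3-nt binding-site mutagenesis, and bulged sponge
  construct design (tandem antisense sites, miRNA positions 9–12 unpaired).
- **Target anticorrelation statistic** — per-target Pearson correlation
  with the miRNA across samples, a size-matched bootstrap null from
  non-target genes, and a two-sample Kolmogorov–Smirnov comparison.
- **Enrichment consensus** — binomial, one-sided Fisher and hypergeometric
  overrepresentation tests of miRNA target sets in gene clusters, each
  Hochberg-adjusted across miRNAs, with a call only when all three
  adjusted p-values fall below α.
- **DEG concordance typing** — intersection of aging and sponge
  differential-expression tables, type 1–4 classification by fold-change
  signs (up/up, up/down, down/down, down/up), concordance percentage with
  a χ² test, fold-change correlation, and Fisher set-overlap tests.
- **Synthetic-data generator** — seeded, byte-reproducible simulators for
  every input above, emulating the study design (5 age groups × 5 animals,
  a miRNA rising 15-fold with age, log-normal expression noise, reads with
  adapter and isomiR structure, DEG tables with a planted typing).

## The statistic at the core

For a miRNA expression vector $m$ over samples and a target set $T$,
compute $r_t = \mathrm{corr}(x_t, m)$ for each target gene $t$, and a null
sample $r_0$ by pooling $B$ draws of $|T|$ non-target genes. The test
statistic is the two-sample KS distance

$$D = \sup_x |\hat F_{r_t}(x) - \hat F_{r_0}(x)|,$$

with p-value from the asymptotic two-sample formula at effective sizes
$(|T|, P)$, where $P$ is the number of *distinct* non-target genes — the
pooled bootstrap values are not independent, and using their raw count
would overstate the evidence. A left shift of $r_t$ (negative excess
correlation) is the signature of miRNA-mediated repression.

## Worked example

```python
from mirage import AnticorrConfig, SimulationConfig, anticorrelation_test, simulate_expression

expr, mirna, truth = simulate_expression(SimulationConfig(rng_seed=7))
res = anticorrelation_test(expr, mirna, truth.target_gene_ids,
                           AnticorrConfig(B=1000, rng_seed=7))
print(res.D, res.p)
```

Running `python examples/03_target_anticorrelation.py` prints:

```
miRNA mean by age (weeks): 3w=47, 9w=97, 15w=196, 21w=306, 27w=649
mean target r = -0.695  mean bootstrap-null r = -0.008
KS D = 1.000, p = 9.02e-157 (effective null size 1800 non-target genes)
```

The miRNA mean rises ~15-fold from 3 to 27 weeks; target correlations pile
up near −0.7 while the bootstrap null sits at 0, so the KS distance is
essentially 1 and the null is rejected overwhelmingly — the simulated
repression is recovered. `examples/05_deg_concordance.py` shows the other
headline computation: with intersection type counts (225, 34, 231, 34),
456 genes (87%) are concordant and 68 (13%) discordant, χ² p < 10⁻¹⁶.

Each `examples/*.py` script is a short narrative demo of one capability;
the `mirage` command (`mirage simulate|preprocess|annotate|seedscan|sponge|anticorr|enrich|intersect|run`)
exposes the same operations from the shell.

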