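# rostrum

Mitogenome clade assignment and source-admixture inference for medieval
Atlantic walrus (*Odobenus rosmarus rosmarus*) ivory.

Medieval European workshops consumed walrus ivory traded south as partial
skulls ("rostrums") with tusks in place. Atlantic walrus mitogenomes fall
into two monophyletic maternal clades: an *eastern* clade found throughout
the Northeast Atlantic (anchored by Svalbard specimens) and a *western*
clade restricted to western Greenland and Arctic Canada. Because the
western clade was accessible only via Norse Greenland, the clade
composition of dated archaeological finds traces the geography of the
ivory trade through time.

`rostrum` packages that inference chain for whole-mitogenome alignments:

1. **SNP matrix** — variable sites from a FASTA alignment with an outgroup;
   gap columns excluded, per-site missingness filtered (`seqio`).
2. **Clade assignment** — smartPCA-style principal components with SNP
   loadings; specimens split by the sign of PC1, the anchor specimen's
   group named "eastern"; clade-diagnostic SNPs as fixed differences
   (`clades`).
3. **Genealogy and dating** — neighbour-joining tree rooted on the
   outgroup, Fitch parsimony substitution counts per branch, and
   strict-clock TMRCA point estimates under a fast
   (7.5 × 10⁻⁸ subs/site/yr) and a slow (7 × 10⁻⁹) rate (`clades`).
4. **Marker reinterpretation** — which diagnostic SNPs create or destroy
   restriction-enzyme (RFLP) recognition motifs, and scoring of the
   control-region haplotype at positions 15 564 / 15 760 / 15 779 (the
   "ACC" haplotype, fixed in Northwest Greenland, absent from the
   Northeast Atlantic) with regional tabulation (`markers`).
5. **Source admixture** — dated specimens partitioned at the founding of
   the Greenlandic bishopric (ca 1125 CE); for each period the probability
   of the observed western/eastern counts under a variable western-source
   contribution *w*, where a western-source specimen is eastern-clade with
   probability 0.48 and a Northeast Atlantic specimen always is:

   p_east(w) = w · 0.48 + (1 − w) · 1.0,&emsp;L(w) ∝ Binomial(k_east | n, p_east(w)),

   normalized over a grid on [0, 1]; plus a Fisher exact test on the
   period × clade table (`provenance`).

A synthetic-data generator (`simulate`) produces two-clade alignments,
dated specimen metadata, and regional control-region tables with exactly
this structure, so the whole pipeline runs and is tested without any
external data.

## Worked example

```python
from rostrum.provenance import PeriodCounts, mixture_posterior, fisher_exact

post_b = mixture_posterior(PeriodCounts("before", n_western=1, n_eastern=6))
post_a = mixture_posterior(PeriodCounts("after", n_western=10, n_eastern=2))
fr = fisher_exact(((1, 6), (10, 2)))
print(f"before 1125: MAP w = {post_b.map_w:.3f}")
print(f"after 1125:  MAP w = {post_a.map_w:.3f}")
print(f"Fisher exact p = {fr.p_two_sided:.5f} (2 s.f.: {fr.p_rounded})")
```

prints

```
before 1125: MAP w = 0.275
after 1125:  MAP w = 1.000
Fisher exact p = 0.00627 (2 s.f.: 0.0063)
```

Before the bishopric's founding the most likely western-source contribution
is ~27% — the early ivory trade drew mostly on Northeast Atlantic hunting
grounds. Afterwards the maximum sits at the 100% boundary: the later
specimens are consistent with an exclusively Greenlandic source. The
Fisher test shows the shift in clade composition between periods is
unlikely under a fixed source (p ≈ 0.0063).

The full pipeline runs from one config file:

```sh
rostrum all -c config.yaml     # simulate -> snps -> clades -> genealogy -> markers -> provenance
```

writing, per stage, the alignment FASTA, variant table, clade and
diagnostic-SNP TSVs, Newick tree with substitution-count branch lengths,
RFLP site-change and control-region region tables, the chronology report
(`report.json`, `periods.tsv`, per-period posterior TSVs), and a manifest
with the config hash.

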