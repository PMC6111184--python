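# Methods

## The model

A traded specimen is drawn from one of two sources: western
Greenland/Canada (contribution *w*) or the Northeast Atlantic (1 − *w*).
Each source has a fixed eastern-clade frequency: 1.0 for the Northeast
Atlantic (the western clade does not occur there) and 0.48 for the western
source (the eastern-clade fraction of the modern West Greenland population
as measured by RFLP surveys; taken as a config value, not re-estimated).
A specimen is therefore eastern-clade with probability

    p_east(w) = w * 0.48 + (1 - w) * 1.0,

affine and decreasing in *w*. For a period with *n* dated specimens of
which *k* are eastern-clade, the likelihood is Binomial(*k* | *n*,
p_east(*w*)), evaluated on a uniform grid over [0, 1] (default step 0.001,
endpoints included) and normalized to sum to one per period — a posterior
under a flat prior on the grid. The MAP is the grid argmax, smallest *w*
on exact ties. The analytic optimum is the binomial MLE mapped through the
affine link and clipped to the boundary:

    w* = clip((f_e - k/n) / (f_e - f_w), 0, 1),   f_e = 1.0, f_w = 0.48,

which the grid argmax approaches as the step shrinks; the test suite checks
this at step 1e-4. For the early counts (1 western, 6 eastern),
w* = (1/7)/0.52 ≈ 0.2747 (MAP 0.275 on the default grid); for the late
counts (10 western, 2 eastern) the unconstrained optimum exceeds 1, the
likelihood is increasing on the whole interval, and the MAP is exactly 1.

The reported 95% interval is the smallest grid set, greedy by probability
mass, containing ≥ 0.95 — an extra summary beyond the MAP, labelled as
such; it is a highest-density set, not a central interval.

The temporal shift is tested with a two-sided Fisher exact test on the
period × clade 2 × 2 table, defined by the point-probability criterion:
the sum of hypergeometric probabilities of all tables with the observed
margins whose probability does not exceed the observed table's, with a
relative tolerance of 1e-7 on the comparison to make float ties behave
like exact ties (the common convention; implementations differ here).
A zero margin forces p = 1 by convention and is flagged.

Period assignment uses the date-range midpoint: midpoint < 1125 CE is
"before", in [1125, 1400) "after", ≥ 1400 excluded as a post-Norse
outlier. Midpoints are a modelling choice — contextual per-specimen
judgement is also defensible — and the rule is logged per specimen.

## Clade inference

PCA follows the smartPCA recipe: missing genotypes imputed to the column
mean, columns centred, optional 1/sqrt(p(1-p)) scaling (sites treated as
haploid biallelic), eigendecomposition via SVD. Component signs are
canonicalized (largest-magnitude loading positive) so outputs are
reproducible. Specimens split by the sign of the PC1 score; scores at
numerical zero are assigned to the anchor's clade and flagged. The clade
containing the anchor specimen — a control of known provenance, e.g. a
Svalbard specimen — is named "eastern". Diagnostic SNPs are sites whose
non-missing allele sets are disjoint between the label groups (a
fixed-difference definition tolerant of missing data); PC1 loadings are
reported per site separately.

The genealogy is a neighbour-joining tree on missing-data-corrected
Hamming distances (differences scaled by the inverse fraction of jointly
called sites; no multiple-hit correction, since ascertained SNP matrices
make any correction arbitrary), rooted on the outgroup. Q-criterion ties
break on the lexicographically smallest cluster-label pair, so the
topology is deterministic. Substitutions are counted by Fitch parsimony
per site (missing data = full state set at the leaf, so it never forces a
substitution), with per-branch counts from the standard top-down
refinement — one most-parsimonious labelling; where several exist the
refinement picks states deterministically (smallest allele index). The
substitutions separating each clade from the ingroup MRCA are summed over
the path from the ingroup root to the clade's ancestral node. Divergence
converts to time as years = substitutions / genome length / rate, under a
fast (7.5e-8 subs/site/yr) and a slow (7e-9) rate. These are strict-clock
point estimates on a distance tree: they are *not* comparable to Bayesian
posterior medians with HPD intervals and are labelled accordingly in the
pipeline output.

## Marker reinterpretation

Restriction motifs are IUPAC-degenerate strings scanned by sliding window
on both strands by default (whether the original single- or double-strand
convention applies is not documented; the flag is configurable);
reverse-strand hits are reported against forward coordinates and
palindromic double-hits collapse to one. 'N' in the subject never matches
any code: missingness cannot fabricate a restriction site. For each
diagnostic SNP × motif, only the window within one motif length of the SNP
is rescanned under each clade allele; a hit covering the SNP under exactly
one allele is a clade-specific site gain ("created", with the carrying
clade recorded as direction — equivalently a loss in the other clade).
The default enzyme panel is a documented set of common cutters; the panel
is configuration, not a result. Gene-region labels (ND1 etc.) are
user-supplied intervals, since no annotation is bundled.

Control-region classification concatenates the genotypes at 15 564,
15 760, 15 779; the target haplotype is "ACC". Any missing genotype makes
the call UNDETERMINED — never silently non-target — and undetermined calls
are excluded from both numerator and denominator of regional frequencies,
reported in their own column. The nominal 499 bp context window
[15 328, 15 827] actually spans 500 positions; the pipeline logs this
discrepancy and classification depends only on the three scored positions.

## Synthetic data

The generator emulates the data structure the analyses assume, on a
16 565 bp reference with uniform base composition:

- two clades separated by `n_diagnostic` fixed SNPs (default 39, matching
  the two observed clade stems of 21 and 18 substitutions); each site's
  derived allele lands on a uniformly random clade, so the fixed
  differences split across both stems while always summing to
  `n_diagnostic`;
- within-clade polymorphism at `n_private_per_clade` sites (default 20 per
  clade, a free parameter — real within-clade diversity is not calibrated
  here). Carrier sets are drawn from one random within-clade genealogy
  (nested subsets), because mtDNA is clonal and every variant has a single
  origin; all simulated sites are therefore compatible with one tree, and
  noise-free runs reach the parsimony lower bound exactly;
- an outgroup differing at `outgroup_divergence` further sites (default
  250);
- default specimen counts 11 western / 8 eastern, matching the dated
  archaeological set, with metadata date ranges drawn strictly inside
  (800, 1125) and (1125, 1400) so midpoint classification reproduces the
  1W:6E / 10W:2E composition by construction;
- regional control-region tables with ACC frequency 1.0 in Northwest
  Greenland, 0.0 in the Northeast Atlantic and intermediate values
  elsewhere; non-ACC individuals draw uniformly from a fixed alternative
  set {GCC, ACT, GCT} (the real alternative haplotypes are not enumerated;
  any distinct set exercises classification).

Noise is i.i.d.: miscalls are uniform substitutions to another base
(default rate 1e-3) and genotypes go missing independently (default 0.02).
Real ancient DNA violates both — deamination concentrates C→T/G→A changes
at fragment ends and coverage (hence missingness) is structured — so
passing tests show the pipeline's statistical machinery is correct under
its stated model, not that it is robust to damage-driven error; damage
profiling and correction are upstream concerns, out of scope here. Read
simulation, coalescent genealogies and population dynamics are likewise
not modelled.

## Numerical choices and degenerate inputs

- All simulation randomness flows through one numpy Generator per call;
  the pipeline derives one seed per stage from the master seed and stage
  name (SHA-256, reduced below 2^31).
- Test-scale problem sizes: simulations in the suite use 2–3 kb genomes
  and 8–19 specimens, which exercise every code path at interactive
  runtimes; the defaults above are used for full-scale runs.
- Mixture grid: step 0.001 (finer than any printed precision of the
  quantities involved); posterior normalization asserted to 1e-9.
- PCA: a component-1 eigenvalue at zero raises a no-structure error rather
  than assigning arbitrary clades; all-missing sites are rejected (the SNP
  caller cannot produce them).
- Distances: specimen pairs with no jointly called site get the maximal
  distance (the site count) rather than NaN.
- Fisher: enumeration over the feasible hypergeometric support with exact
  integer binomials; only the final ratio is floating point.

## Known limitations

- TMRCA point estimates ignore rate and topology uncertainty entirely.
- The 0.48 eastern-clade fraction of the western source is an external
  input; mis-specifying it shifts the MAP curve (the affine link makes the
  effect easy to reason about: the MLE in p-space is fixed at k/n).
- The mixture model treats specimens as independent draws; shared
  provenance of finds from one site would overdisperse the counts.
- Clade assignment feeds the admixture model as hard labels; assignment
  uncertainty is not propagated.
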