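# Methods

## Scientific setting

Allopolyploid genomes carry two or more closely related (homoeologous)
chromosome sets.  Ordered-clone sequencing needs BAC contigs assembled from
restriction fingerprints, and the worry for polyploids is that clones from
orthologous regions of homoeologous chromosomes share enough restriction
fragments to be clustered into common contigs.  The package implements the
whole chain needed to interrogate that question in silico: genome and
library simulation, SNaPshot HICF fingerprint simulation, fingerprint
editing, Sulston-score contig assembly, and misincorporation accounting in
a merged multi-library assembly.

## Genome and library model

The generator builds an ancestral chromosome arm of uniform random sequence
with non-overlapping gene intervals (count = `gene_density` per Mbp, lengths
gamma-distributed with shape 4 around `gene_length_mean`, placed by
distributing the leftover intergenic space uniformly).  Homoeologs derive
from the ancestor under two mechanisms:

* **genes** are point-substituted, each homoeolog at half the pairwise
  `gene_divergence`, so any two homoeologs differ at ~`gene_divergence`
  substitutions per site (default 0.03, the divergence scale of wheat's A,
  B and D genomes);
* **intergenic blocks** are independently *replaced* by fresh random
  sequence with probability `intergenic_turnover` (default 1.0).  Block
  replacement rather than gradual substitution encodes the observed
  wholesale turnover of transposon-dominated intergenic space: sequenced
  homoeologous BAC clones share essentially nothing outside the genes.

Flow-sorted single-arm libraries draw `n_clones` inserts with truncated-
normal lengths ([0.2, 3]×`insert_mean`) and uniform starts.  Each clone is a
contaminant with probability `contamination_rate` (defaults 11.0/11.4/10.0%
for the three libraries, insert means 80/103/110 kb), its source drawn
uniformly over all other simulated arms — the two homoeologs plus
`n_decoy_arms` unrelated decoy arms (default 37, making a 40-arm karyotype
context in which each non-target arm is an equally likely contaminant, so
the designed homoeolog share of a library is `rate × 2/39`).  Decoy arms
are generated without genes; their internal structure is irrelevant because
they only donate contaminant inserts.

## Fingerprint model

Inserts are digested simultaneously with BamHI, EcoRI, XbaI, XhoI
(labeled; cut after base 1 of their 6-bp sites) and HaeIII (blunt, cut
after base 2 of GGCC, unlabeled).  Every *labeled* fragment end yields one
band in that enzyme's dye channel with size equal to the fragment length; a
fragment with two labeled ends yields two bands in two channels (SNaPshot
labels each cut end independently; a one-band mode exists for sensitivity
checks).  Fragments bounded by HaeIII and/or the clone terminus contribute
nothing.  Observed sizes add Gaussian sizing noise (`noise_sd` 0.08 bp,
clipped at ±0.4 bp) — the ABI-class capillary error scale is not published,
so the default is chosen to make the 0.5 bp matching tolerance
discriminating without dominating it, and it is configurable.  Only bands
in the collected 100–1000 bp window survive editing.

Simulated clones are assigned to 96-well plates in order, providing the
plate metadata cross-contamination screening operates on.

## Fingerprint editing

Editing strikes bands within 0.5 bp of listed vector bands (per channel),
applies the inclusive 100–1000 bp window, removes clones with fewer than 25
or more than 250 bands ("unsuitable length" is not defined in the
fingerprint-editing literature as a band count; these bounds are our
config-exposed interpretation), and flags same-plate clone pairs sharing
≥95% of the smaller clone's bands as cross-contaminated, removing both
members (a keep-one mode exists).  Similarity uses the same band-matching
routine as assembly.  The edit pass is idempotent and order-independent,
and its report counts partition the input exactly.

The feasibility experiment runs with the cross-contamination screen *off*:
the simulator does not model well-to-well DNA carry-over, and at desk-scale
arm lengths (2 Mb instead of hundreds of Mb) genuinely nested clone
placements are common enough that the screen's false-positive rate would
dominate.  At genomic scale the coincidence probability is negligible and
the screen is safe to enable (the default for standalone editing).

## Sulston score and band matching

Bands are matched per dye channel by a greedy two-pointer sweep over the
sorted size lists with tolerance 0.5 bp; each band is used at most once.
For threshold matching of sorted points on a line this greedy attains the
maximum matching (verified in tests against a maximum bipartite matching
oracle on all instances up to 12 bands).  Internally bands are packed into
one sorted array per clone with a 2000-unit channel stride, so one sweep
handles all four channels.

The score is the classical Sulston coincidence probability (binomial tail,
see README) with `x = 1 − (1 − 2t/G)^{n_H}`.  `G` defaults to 900 bp, the
per-channel collected range, because matching is per channel.  The tail is
summed in log space with `gammaln`; scores as deep as 10⁻⁴⁰⁰ remain exact
where a direct survival-function evaluation underflows.  All cutoff
comparisons happen in log₁₀ space with absolute slack 10⁻⁹ to avoid
floating-point threshold flapping.

The score's binomial derivation treats each band of the smaller fingerprint
as independently finding a partner, partners reusable.  The Monte-Carlo
oracle used in the acceptance tests simulates exactly this chance model
(uniform band throws on the collected range, a band counts as matched when
any partner lies within tolerance).  A no-reuse maximum-matching count
would differ from the binomial form by up to ~2× in the corner where every
band must match (e.g. 2-vs-2, m=2); this mismatch is a known approximation
inside the classical score, not an implementation artifact, and the
observed `m` in assembly does use the no-reuse matching, as fingerprint
assemblers do.

## Assembly cascade

All unordered pairs are scored; pairs at or below the loosest cascade
cutoff (10⁻¹²) are kept.  A conservative prescreen hashes bands into bins
of one tolerance width and counts co-binned band pairs (one side dilated by
±1 bin), which upper-bounds the true matched count; only pairs whose bound
reaches the minimum matched count that could pass the loosest cutoff are
scored exactly, so the prescreen can never drop a qualifying pair (tested
against exhaustive scoring).

* **Initial clustering** — single linkage at 10⁻⁵⁰: contigs are connected
  components; components of one clone are singletons.
* **Q flags and deQing** — the contig consensus is the union of band
  clusters (merged within tolerance, per channel) supported by ≥2 distinct
  members; a member is Q when >50% of its bands lack consensus support
  (contigs of two members carry no flags).  Any contig with >15% Q members
  is dissolved and its members re-clustered at a 10× more stringent cutoff;
  rounds repeat, tightening each time, until the bound holds everywhere.
  The Q definition and the 10×-per-round schedule are stand-ins for FPC's
  internal (unpublished) mechanics and are config-exposed.
* **Singleton joining** — at 10⁻³⁰ then 10⁻²², each singleton whose best
  score against any contig member passes joins that contig (ties to the
  lexicographically smallest contig id).
* **Ordering** — contig seriation is the diameter path of the maximum-
  significance spanning tree (edge weight −log₁₀ score), with off-path
  members inserted next to their best-scoring ordered neighbor.  This
  replaces FPC's consensus-band map, which is out of scope; on simulated
  tilings the seriation correlates with true clone coordinates at
  |Spearman ρ| ≥ 0.9.
* **End merging** — a contig "end" is the `end_depth` (default 2) clones at
  each extreme of the seriation.  Remaining singletons join at 10⁻¹⁵ only
  via end members; contigs merge at 10⁻³⁰/10⁻²⁰/10⁻¹⁵/10⁻¹², each stage
  iterated to a fixed point, requiring one passing end-clone pair.

After every stage the partition invariant (contig members ∪ singletons =
input clones, disjoint) is asserted.  All tie-breaks are lexicographic on
clone/contig ids, making results independent of input order.

The assembler is exposed as a scikit-learn-style clusterer
(`SulstonAssembler`: `fit` → `labels_`, `contigs_`, `singletons_`), and
editing as a transformer (`FingerprintEditor`); the module-level functions
are thin wrappers, so the cascade composes with sklearn model-selection
tooling.

## Misincorporation analysis

Libraries are merged in silico (clone ids carry their library prefix), the
merged set is assembled, and each contig with at least `min_clones` members
(default 4; 2 reproduces the two-library re-fingerprinting analysis) is
classified by its prevalent library — a strict majority; exact ties are
"ambiguous", excluded from the tables and counted separately.  Raw row
percentages divide each source-library count by the row total; the
size-adjusted mode first rescales each count by (prevalent library size /
source library size).  The adjustment formula used for the original
three-library analysis is not recoverable from its description, so raw
percentages are always emitted alongside our documented rescaling and the
adjusted numbers are not claimed to reproduce the original adjusted table.

The designed misincorporation baseline of row R is the expected number of
clones in the *other* libraries whose true source is R's arm —
`Σ_{L≠R} n_L × rate_L / 39` under the 40-arm sampling design — divided by
the observed number of clones in R's classified contigs; the comparison
uses a Clopper–Pearson 95% interval on the observed proportion because the
counts are small.  The karyotype arithmetic `rate × n_homoeo / total_arms`
is reported separately as the expected contamination of a single library.
The singleton cross-check reports, per row, the fraction of misincorporated
clones that were singletons in their own or the prevalent library's
individual assembly — contaminating clones overlap nothing in their own
library, so a high fraction indicates contamination rather than assembly
error.

## Problem sizes and what the experiment does and does not show

The default feasibility experiment uses three 2 Mb arms, libraries of
600/400/500 clones (≈22–27× arm coverage) and 37 decoy arms; one run takes
~15 s on one CPU, and the acceptance suite replicates it over five seeds.
These sizes preserve the *rates* that matter (contamination fraction,
homoeolog share, band counts of 80–110 kb inserts, coverage) while shrinking
the arm length ~100×.  Consequences: absolute contig/singleton counts are
in the tens rather than thousands; whole arms assemble into a handful of
contigs; and nested clone placements are far more frequent than at genomic
scale (the reason the cross-contamination screen is disabled here).  The
simulation also idealizes real data: digestion is complete, sizing noise is
i.i.d. Gaussian with no instrument drift, there are no partial or failed
lanes, no vector bands (they are injected only in editing tests), no
repeat-driven band-sharing between unrelated regions, and gene density is
uniform.  Passing tests therefore demonstrate the *logic* of the cascade
and the contamination accounting, not the noise robustness of real
capillary data.

## Numerical and degenerate-input choices

Probabilities are handled as log₁₀ throughout; `sulston_score` may
underflow to 0.0 for extreme inputs while `sulston_log10` stays exact.
`m = 0` scores exactly 1.  Empty fingerprints match nothing and never form
pairs.  Band clusters for consensus building start a new cluster when a
size exceeds the cluster's first member by more than the tolerance.  deQing
is capped at 200 rounds (a convergence failure raises rather than loops).
The `.sizes` channel-offset dialect stores `channel × 20000 +
round(size × 10)`; plain single-channel files are auto-detected by maximum
value, which is ambiguous only for files whose every band is in the first
channel — pass the dialect explicitly in that case.

## Known limitations

* FPC's actual Q-clone definition, CB-map ordering and gel parameters are
  unpublished; our stand-ins are documented above and config-exposed, so
  absolute contig counts should not be expected to match an FPC run.
* The library-size adjustment of the original three-library table is
  unrecoverable; only raw percentages are reproduced exactly.
* Whether real HICF pipelines match bands across channels is instrument-
  dependent; matching here is per channel by default.
* The generator's uniform-random intergenic sequence underestimates chance
  band sharing between unrelated clones in repeat-rich genomes; chance
  scores here are close to the Sulston model's own assumptions, which is
  the point of the validation but an idealization of real data.
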