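# Methods

This note documents the models, rules and defaults implemented in
`karyorec`, the choices made where the design was genuinely open, and what
the synthetic data does and does not establish about real sequencing data.

## Data model and coordinates

Variant evidence is carried as `SiteObservation` records — one scaffold,
1-based position, ref/alt allele, and FreeBayes-style read support (RO =
reference-supporting reads, AO = alternate-supporting reads, DP = total
depth). RO + AO may be less than DP (reads supporting third alleles), never
more. Positions are 1-based inclusive everywhere inside the package,
matching VCF; BED output alone uses 0-based half-open coordinates, with the
conversion confined to the I/O layer. Scaffolds are always ordered by
decreasing length with lexicographic tie-breaks, so "the N largest
scaffolds" is deterministic. Multi-allelic VCF records are decomposed into
one observation per alternate allele (sharing RO), because every downstream
rule is stated per alternate allele. Records lacking RO/AO but carrying AD
are accepted (AD[0] → RO, AD[i] → AO) for caller-dialect tolerance.

## Filter cascade

**Basic tier** (per nucleus): keep an alternate allele iff

* AO ≥ `min_alt_reads` (default 2), and
* AO ≥ `support_ratio` × RO (default 10:1, inclusive).

Non-SNV records (variant length > 1) are excluded from all SNP analyses.

**Stringent tier** adds, for sites that passed basic:

* the scaffold is among the `top_n_scaffolds` (default 100) largest;
* bulk depth at the position lies in [0.69, 1.31] × the genome-wide mean
  bulk depth, inclusive;
* bulk alternate allele frequency AO/(RO+AO) lies in [0.26, 0.74],
  inclusive;
* the flank-uniqueness (single-copy) test passes.

All windows are inclusive at both ends: the defining phrases are of the
form "between X and Y" with no strictness stated, and inclusivity makes
boundary behaviour testable. The bulk criteria deliberately use the
*assembly* reads, not the nucleus reads: they ask whether the position
looks like a clean, single-copy, bi-allelic site in the pooled data. A
position absent from the bulk records fails the depth criterion with a
distinguishable "no bulk data" note. "Genome-wide mean depth" is the mean
over all reference positions (one number, not per-scaffold), supplied as a
`CoverageProfile`.

The expensive single-copy test is evaluated only when the cheaper criteria
all pass; the pass/fail outcome is unaffected, but a failing verdict's
reason list then contains only the cheap failures.

### Single-copy (flank-uniqueness) test

The 100 bp upstream flank and the 100 bp downstream flank of a candidate
SNP are queried *separately* against the whole reference, both strands. A
unique locus therefore self-hits once per flank — 2 hits total — which makes
the "more than 2 good hits ⇒ multi-copy" threshold coherent; a single
201 bp query would let one self-hit plus one paralog pass, defeating the
filter's intent. Flanks are truncated at scaffold ends; if either flank
falls below 30 bp the site fails safe as multi-copy.

The default backend is a self-contained BLAST-like aligner: exact 13-mer
seeds locate candidate diagonals; each diagonal is scored by its best
ungapped segment (match +1, mismatch −2); a *good hit* is a seeded diagonal
whose Karlin–Altschul e-value

    E = K · m · n_eff · exp(−λ·S)

is ≤ 0.001, with λ the positive root of
0.25·e^λ + 0.75·e^{−2λ} = 1 (≈ 1.33 for uniform base composition) and
K fixed at 0.35 — an order-of-magnitude approximation; at this threshold
and flank length the hit decision is insensitive to K. Indels are not
modelled in the extension, which is adequate for the exact and near-exact
repeats the filter is designed to catch. An external BLAST+ backend
(`blastn`) is available behind the same interface and agrees with the
internal aligner on the test fixtures.

## Genotyping and the rescue clause

At each retained site a nucleus is called:

* **STRONG ALT** iff AO ≥ max(`min_alt_reads`, `support_ratio` × RO);
* **STRONG REF** iff RO ≥ max(`min_alt_reads`, `support_ratio` × AO).

The symmetric strong-REF rule is this package's explicit choice: the
filtering prose states the ratio only for alternate alleles, but scoring a
nucleus as "reference-like" in similarity and tract analyses requires the
same confidence for REF, and an asymmetric rule would bias similarity
toward the reference nucleotype.

A nucleus failing both strong rules keeps its majority allele as a
**RESCUED** call iff at least one co-existing nucleus is STRONG for that
same allele at the same position (the requirement is existential, not a
majority). Zero informative reads ⇒ MISSING. An exact RO = AO tie has no
majority: it is rescued only when exactly one of the two alleles has a
strong co-nucleus, and is otherwise MISSING with a tie flag.

The genotype matrix spans the *union* of sites retained in ≥ 1 nucleus;
every nucleus is genotyped at every universe site (MISSING where
uncovered). Pairwise analyses then handle shared-position denominators
explicitly, which is why the union (rather than intersection) is safe.

MAT alleles are assigned by majority vote over non-missing designated
marker genotypes; any disagreement sets a conflict flag, and without a
strict majority the nucleus is UNASSIGNED.

## Similarity matrices and clades

Two pairwise datasets per nucleus pair:

* `matrix_variable` — matching genotypes / shared non-missing variant
  positions (RESCUED calls count like STRONG: the rescue clause exists
  precisely to include them);
* `matrix_covered` — mismatching variant genotypes / length of the
  coverage-mask intersection, i.e. divergence over shared covered sequence,
  where invariant positions count as matches. It is therefore never larger
  than the variable-position mismatch rate.

Empty denominators give NaN entries, flagged as NA in output. Clustering is
average-linkage on 1 − `matrix_variable` with a k = 2 tree cut; the method
is not dictated by the analysis being formalized, and average linkage was
chosen for determinism and standardness — the linkage tree is exported
(Newick) so any other ordering can be recomputed. NaN entries are imputed
with the mean defined similarity for clustering only (logged, never written
back). Clade numbering follows first occurrence in nucleus input order, so
results are deterministic under permutation up to the documented
equivariance.

## Recombination tracts and dispersion

A site is **diagnostic** when both clades have a within-clade consensus —
majority of STRONG calls, ≥ `min_votes` (default 2) voters, ≥ 80%
agreement — and the consensuses differ. Per nucleus and scaffold, each
diagnostic site is labelled own/opposite/missing against the two
consensuses; a **tract** is a maximal run of ≥ `min_run` (default 2)
consecutive opposite labels, with MISSING sites neither breaking nor
extending a run. `min_run`, `min_votes` and the 80% threshold formalize
what is otherwise a visual mosaic inspection; they are explicit parameters,
not claims about the original analysis. Because true breakpoints are
unresolvable between diagnostic sites, a tract reports its supporting-site
span (inner bound) plus the flanking own-clade site positions (outer
bound).

The consensus is computed over all clade members including any recombinant,
so with few strong voters per site (heavy dropout) a recombinant can
dissolve the very consensus needed to detect it; detection is reliable when
several same-clade nuclei cover each site, and the tract-recovery tests
condition on tracts with ≥ 3 diagnostic sites informatively covered in the
carrier nucleus.

The dispersion summary keeps length-1 variants only and reports each
position as 100 × pos / scaffold-length. Normalization is per-scaffold by
default ("scaffold one" being read as each analyzed scaffold normalized to
its own length); a flag restricts it to the largest scaffold only. The
conventional plotting alpha (0.2) is recorded with the table.

## The synthetic-data generator

The generator emulates the statistical regime of single-nucleus sequencing
of an AMF isolate. Defaults (one place: `SimConfig`):

| parameter | default | rationale |
|---|---|---|
| genome | 1 Mb, 20 scaffolds, ~10× length spread | desk-scale stand-in for a fragmented fungal assembly |
| `divergence` | 0.001 | two nucleotypes at ~0.1% divergence; values > 1% are rejected as out of regime |
| `mixture` | 0.5 | equal nucleotype proportions in the dikaryotic bulk (1.0 = homokaryon) |
| `n_nuclei_per_mat` | 8 | 16 nuclei per isolate, the upper end of nuclei-per-isolate counts |
| `nucleus_coverage_fraction` | 0.4 | per-nucleus reference coverage, middle of the ~11–61% range |
| `coverage_block_length` | 10 kb | WGA dropout modelled as contiguous covered blocks |
| `nucleus_mean_depth` | 15 | per-position depth of covered nucleus sites (~12–23 observed regime) |
| `bulk_mean_depth` | 50 | assembly-read depth |
| `error_rate` | 0.002 | per-read substitution error; error bases uniform over the three non-true bases |
| `dup_fraction` | 0.02 | fraction of bases inside exact duplicated segments (source + copy both counted) |
| `dup_segment_length` | 2 kb | ≥ 402 bp so a full 201 bp flank window fits inside a duplicate |
| `n_collapsed_sites` | 30 | collapsed-duplicate artifact positions per genome (see below) |

WGA dropout is modelled as contiguous covered blocks rather than i.i.d.
per-base loss because low genome coverage combined with moderate
*position* depth implies locus-level amplification bias; the true bias
structure of WGA is not known, and the block model is an assumption. Blocks
are drawn in a fixed per-nucleus stream order, so masks are *nested* as the
coverage fraction grows — a property the missingness tests rely on. A
coverage fraction of 1.0 short-circuits to whole-genome masks (random
blocks cover the last bases only coupon-collector slowly).

Truth SNPs are single-base substitutions only, drawn uniformly at the
divergence rate, excluded from duplicated segments by default (toggleable,
so the single-copy filter can be exercised by planting SNPs inside
duplicates). MAT markers are a small cluster of truth SNPs on the largest
scaffold, mapping REF → MAT-1 and ALT → MAT-5. Nuclei carry their clade's
nucleotype except inside declared recombination tracts, where they carry
the opposite one; overlapping tracts on one nucleus are rejected.

**Collapsed-duplicate artifact sites** are the one channel beyond plain
sequencing error: positions where a hidden paralog is absent from the
assembly, so the bulk shows ~50% alternate frequency while single nuclei
show amplification-skewed support (Beta(0.3, 0.3) jackpots) that sometimes
passes the 10:1 rule. This is what leaves a homokaryon with a small but
non-zero stringent SNP count, as real homokaryotic isolates retain; pure
sequencing error cannot pass the bulk allele-frequency window. Tests of the
"error-free reads support the true allele" invariant set this channel to
zero.

Bulk observations are drawn per candidate site: depth ~ Poisson(bulk mean),
alternate count ~ Binomial(depth, p) with p the mixture-weighted true
frequency perturbed by error; records are emitted when at least one
alternate read is present (a caller emits no record otherwise). The
genome-wide mean depth is drawn as one Poisson(L·μ)/L per scaffold —
exact in distribution for the mean over all positions — rather than 10⁷
per-position draws; per-site depths are drawn independently of these
totals. Per-nucleus depths and counts are drawn for *every* truth site in
scaffold order and masked afterwards, so calls at a given site do not
change when only the coverage fraction changes.

All randomness flows from the single `SimConfig.seed` through named
`SeedSequence` spawn keys (reference, nucleotypes, masks, per-nucleus
observations, bulk), making outputs byte-identical across reruns and
per-component reproducible.

### What the simulations do not show

The generator omits read-level artifacts (mapping errors, indels,
structural variants, chimeric WGA reads), more than two nucleotypes,
assembly fragmentation bias, and any correlation between error rate and
sequence context. Passing tests therefore demonstrate that the *rules* are
implemented correctly and behave as intended under the stated statistical
regime — not that the thresholds are optimal for any particular real
dataset.

## Numerical and procedural choices

* Problem sizes in the test suite and acceptance script are desk-scale by
  design: 1 Mb default genomes for property checks (20-seed clade- and
  tract-recovery sweeps) and a 10 Mb, 100-scaffold genome for the
  dikaryon/homokaryon fold-change target, averaged over five seed pairs.
* The filter-cascade equivalence check compares the implementation against
  an independently coded brute-force evaluation of all criteria, including
  an all-diagonal re-implementation of the seeded ungapped aligner.
* Tract-recovery sweeps run at a 0.6 coverage fraction (upper end of the
  emulated range) so each clade retains enough strong voters for a
  consensus that can absorb the recombinant nucleus itself; see the
  consensus caveat above.
* Degenerate inputs are explicit: empty VCFs give empty observation lists;
  an empty site universe gives a valid 0-site matrix; an all-NA similarity
  matrix or a single nucleus is an error; an empty AF spectrum is a flagged
  empty result, not an exception.

## Known limitations

* The e-value calibration of the internal aligner is approximate (constant
  K, no finite-size edge corrections); it is calibrated for the
  hit/no-hit decision at e ≤ 0.001 with ~100 bp queries, not for reporting
  accurate e-values generally.
* Tract breakpoints are bounded, not inferred; nothing distinguishes
  meiotic from parasexual exchange.
* The consensus-based tract caller loses sensitivity under heavy dropout
  (few strong voters per clade), as quantified in the tests.
* Clade structure is assumed binary (k = 2 cut); isolates with more than
  two nucleotypes are out of scope.
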