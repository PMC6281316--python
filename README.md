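# karyorec

Single-nucleus SNP filtering, genotyping, inter-nucleus similarity and
recombination-tract analysis for fungal dikaryons — with a synthetic
dikaryon/homokaryon data generator so the whole pipeline is testable
without any sequencing downloads.

## The problem

Arbuscular mycorrhizal fungi (AMF) carry hundreds of haploid nuclei in one
continuous cytoplasm. Some strains (*dikaryons*) harbour two co-existing
nucleotypes, each tagged by a divergent mating-type (MAT) locus; whether
those nuclei ever exchange genetic material is the central question this
kind of single-nucleus sequencing analysis addresses. Individual nuclei are
FACS-sorted, whole-genome amplified (WGA) and sequenced, which yields
partial, noisy genomes: each nucleus covers only ~10–60% of the reference,
at modest depth, with amplification artifacts that flood naive variant
calls with false positives.

`karyorec` implements the analysis layer of that experiment:

1. **Filter cascade.** A *basic* tier keeps per-nucleus alternate alleles
   with ≥ 2 supporting reads that outnumber reference reads ≥ 10:1
   (inclusive). A *stringent* tier adds four bulk-level constraints: the
   site lies on one of the 100 largest scaffolds; bulk depth at the
   position is within 69–131% of the genome-wide mean; bulk alternate
   allele frequency is within 0.26–0.74 (the bi-allelic band expected of a
   50:50 nucleotype mixture); and the 100 bp flanks of the SNP align to at
   most 2 places in the reference (flank-uniqueness / single-copy test,
   e-value ≤ 0.001 per hit).
2. **Genotyping with rescue.** Each nucleus is called REF/ALT/MISSING per
   retained site; the 10:1 strong-call rule is applied symmetrically, and a
   weak call is *rescued* when a co-existing nucleus is strong for the same
   allele at the same position. MAT alleles are assigned from designated
   marker positions.
3. **Similarity matrices and clades.** Two pairwise datasets: similarity
   over shared non-missing variant positions, and divergence over shared
   *covered* positions (mismatches / covered bp, so invariant sequence
   counts as identity). Average-linkage clustering splits nuclei into the
   two expected MAT clades.
4. **Recombination tracts.** Clade-diagnostic sites (distinct,
   well-supported clade consensuses) are scanned per nucleus for maximal
   runs of opposite-clade genotypes; a run of ≥ 2 such sites is called a
   tract, the formalized equivalent of reading a mosaic genotype table by
   eye. A SNP-dispersion table (positions as percent of scaffold length)
   supports the genome-wide scatter view.
5. **Simulator.** `karyorec.sim` generates references with exact duplicated
   segments, two nucleotypes at ~0.1% divergence, per-nucleus WGA dropout
   as contiguous covered blocks, sequencing error, optional planted
   recombination tracts and collapsed-duplicate artifacts — all with known
   ground truth and byte-reproducible outputs (FASTA/VCF/BED/TSV).

## Worked example

```python
import numpy as np
import karyorec as kr
from karyorec import genotyping as gt, similarity as sm, recombination as rc
from karyorec.filtering import allele_frequency_spectrum, retained_sites

cfg = kr.SimConfig(seed=42)            # 1 Mb dikaryon, 16 nuclei, defaults
res = kr.simulate(cfg)
spec = allele_frequency_spectrum(res.bulk)

verdicts = kr.run_cascade(res.nuclei_obs, res.bulk, res.coverage, res.reference)
matrix = gt.build_matrix(verdicts, res.nuclei_obs, tier="stringent",
                         coverage_masks=res.truth.masks)
result = sm.cluster_nuclei(sm.pairwise_similarity(matrix))
diag = rc.find_diagnostic_sites(matrix, result.clades)
tracts = rc.call_tracts(matrix, diag, result.clades)
```

This prints (via the obvious summaries):

```
truth SNPs: 1004
bulk AF modal bin center: 0.525  dikaryon-like: True
retained sites: basic=946  stringent=913
mean within-clade similarity: 0.9837
mean inter-nucleus divergence (covered positions): 0.053%
clades: 8 vs 8 nuclei
diagnostic sites: 727  recombination tracts: 0
```

Reading: the bulk allele-frequency spectrum peaks at ~0.5, the hallmark of
a dikaryotic 50:50 nucleotype mixture; the stringent cascade keeps ~91% of
the planted 1,004 nucleotype-differentiating SNPs while a matched
homokaryon run retains a few dozen artifact sites at most; nuclei split
cleanly 8 vs 8 into their MAT clades; and with no recombination simulated,
no tracts are called. Planting tracts via `SimConfig.recomb_tracts` makes
the caller report them with their supporting-site spans.

The same stages are scriptable from a shell:

```sh
karyorec simulate --out data/            # writes FASTA, VCFs, BEDs, truth tables
karyorec filter --dataset data --out out/
karyorec similarity --dataset data --out out/   # matrices, newick tree, heatmap
karyorec recombine --dataset data --out out/    # diagnostic sites, tract BED/TSV
```

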