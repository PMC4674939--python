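# Methods

`polymethyl` analyses targeted bisulfite sequencing of allohexaploid bread
wheat (*Triticum aestivum*, genomes AABBDD), in which reads from the three
homoeologous sub-genomes co-align on a single capture reference and must be
separated *in silico* before methylation can be compared between
sub-genomes. This note records the model, the thresholds, the synthetic
study design and the numerical choices the implementation makes.

## Read partitioning by homoeologous SNPs

A homoeologous SNP is a fixed difference between the A, B and D sub-genomes
(one unambiguous allele per sub-genome, at least one divergent). A read
with mapping quality above 20 that covers a catalogued SNP is compared to
the three alleles:

* a unique allele match assigns the read to one sub-genome (e.g. A);
* when two sub-genomes share the allele the read is narrowed to that
  genome pair (BD, AD or AB) — the typical case, since most homoeologous
  SNPs are biallelic;
* reads spanning several SNPs take the intersection of the per-SNP labels
  (A ∩ AB = A; contradictory evidence discards the read).

Bisulfite conversion turns unmethylated C into T (read as A on the
opposite-strand products), so allele matching is conversion-aware: on a
C→T-converted product a read T also matches a C allele, and on a
G→A-converted product a read A also matches a G allele. This is safe only
because the catalogue first removes every SNP whose distinct alleles
include a {C,T} or {G,A} pair — those are indistinguishable from
conversion. A corollary worth stating: *no tri-allelic SNP survives this
filter* (any three distinct bases contain {C,T} or {G,A}), so resolving all
three sub-genomes at a site always requires reads spanning biallelic SNPs
with complementary partitions, never a single tri-allelic marker.

Coverage gates follow the study design: a single-genome label needs ≥5
reads, a pair label ≥10. Pair counts are never split arithmetically
between their genomes.

## Methylation states and site patterns

Per cytosine and genome group, the methylated-read percentage is
thresholded by sequence context (H = A, C or T):

| context | Methylated | Unmethylated | Intermediate |
|---------|------------|--------------|--------------|
| CpG     | ≥ 75%      | ≤ 25%        | 25–75%       |
| CHG/CHH | > 10%      | ≤ 10%        | —            |

The CpG intermediate band exists because a pair label averages two genomes:
a pair at 50% cannot be called "both methylated" or "both unmethylated".
For CHG/CHH the call is binary. The source thresholds can be read either
way ("0% methylation denoting two un-methylated genomes" versus the binary
framing "highly methylated … or low level methylation, i.e. both genomes
likely to be un-methylated"); this package implements the binary reading
deliberately: at realistic conversion rates (≈98.9–99%) the probability
that an unmethylated site shows *strictly zero* methylated reads decays as
conv^n, so a strictly-zero rule would misclassify most unmethylated
non-CpG sites at ≥30× — an artefact of incomplete conversion, not biology.

Site patterns are then assigned from the three genome states:

* each genome's state comes from its own single-label call when one passes
  the coverage gate — a direct measurement always beats an average;
* a genome without a single-label call inherits the state of a gated pair
  containing it, but only when that pair is called Methylated or
  Unmethylated (which pins both members). An Intermediate pair may be
  *split* (one methylated, one unmethylated genome) and pins neither; it
  is, however, positive evidence of intermediate-level-or-split
  methylation, so a site left unpinned by an Intermediate pair is
  classified `intermediate`;
* all three Methylated → `tri`; all Unmethylated → `none`; one or two
  Methylated → `uni_X`/`bi_XY` *candidates*, confirmed only by a two-sided
  Fisher's exact test of the methylated group against the rest (pooled
  opposing singles plus the complementary pair) with difference ≥ 50% and
  q < 0.01;
* a candidate failing its defining test, or a site where some genome state
  cannot be pinned at all, is `unresolved` and excluded from pattern
  denominators. This is deliberate: which partition a site's local SNPs
  offer is independent of its methylation, so excluding unresolvable sites
  keeps the uni/bi/tri proportions unbiased, whereas relabelling them
  would fold conversion noise (a single unconverted C in a thin label
  clears the 10% threshold) and partition availability into the
  "intermediate" class.

q-values are Benjamini–Hochberg, computed per comparison family (all sites
entering one pairwise comparison, e.g. all A-vs-BD tests, form one
family). BH is the standard, reproducible step-up procedure; other
q-value estimators in circulation (SLIM, Storey's method) can shift counts
slightly near the q = 0.01 boundary.

Replicate handling: replicates are pooled after a noise screen — any site
significantly different (≥50%, q < 0.01) between two within-condition
replicates is excluded outright. Between-sample comparisons are
within-genome (A–A, B–B, D–D) at difference ≥ 25%; diploid-progenitor
versus sub-genome comparisons use ≥ 50% (lower diploid coverage) and label
each significant site a methylation gain or loss in the sub-genome.

## Regions, DMRs and expression

The analysis unit is the extended-bait region supplied by the annotation
(no sliding windows). Region methylation pools reads, not sites: % =
100·Σmeth/Σtotal per genome, over single-genome labels only, so deeply
covered sites weigh more. A genome-specific DMR requires one genome ≥ 25
percentage points above **both** others with q < 0.01 on both pairwise
Fisher tests of the pooled counts; between-sample DMRs use the same rule
per genome. At most one genome can qualify per region.

Allelic expression per gene is normalized to shares summing to 100% (the
grand mean over genomes of expressed regions is therefore exactly 33.33%,
an identity the tests assert). Co-expression categories use a 5-point
window (conserved / uni-dominant / bi-dominant / all-differ). For
methylation–expression integration, every methylated genome of each
tri/uni/bi site contributes the normalized share of its region's gene —
promoters are linked by gene id, non-transcribed regions inherit the
nearest gene on the contig (ties broken downstream) — summarized per
(pattern group × annotation class) as a 20-bin histogram on [0, 100]
(right-open bins, last bin closed), mean, 75th percentile and excess
kurtosis (bias-corrected, normal = 0; the reporting convention is a
choice, the upstream numbers do not depend on it). Group means are
compared with a pooled-variance two-sample t test (integer df = n₁+n₂−2)
and distributions are
screened against a fitted normal with a Kolmogorov–Smirnov test. PPLR
values (posterior probability of positive log-ratio, 0.5 = no change) flag
differential expression at ≤0.4 / ≥0.6 and high-confidence differential
expression at <0.10 / >0.90.

## The synthetic study

The generator emulates the wheat capture design end to end and is the
ground truth every stage is tested against.

* **References.** Contigs (default 20 × 2000 bp) drawn uniformly over
  ACGT; three sub-genome copies differ only at SNP positions drawn at
  `snp_rate` = 0.05/bp. Genic homoeologous divergence in wheat is of order
  2–5%, and the capture baits were explicitly selected for the presence of
  homoeologous SNPs, so the default sits at the SNP-dense end. Each SNP is
  biallelic with the divergent genome chosen uniformly;
  `tri_allelic_fraction` = 0.05 of positions have three distinct alleles
  (which the bisulfite-safety filter later removes, as it must). The
  analysis reference is sub-genome A; a separate 6-kb contig with no SNPs
  and no methylation serves as the unmethylated conversion control — only
  its unmethylated property matters, so it stands in for the chloroplast
  genome.
* **Methylation truth.** Every cytosine (both strands) whose context
  window is SNP-free draws a pattern i.i.d. from `pattern_mix`. The
  default mix puts 11.9% of sites methylated in one or more sub-genomes;
  among those 45% tri-genome, 20% differential (uni:bi 2:1, split evenly
  over genomes/pairs) and 35% intermediate. Methylated genomes draw a
  level near the context mean (CpG 0.90, CHG 0.80, CHH 0.70, sd 0.04,
  clipped to [0.55, 0.99]) — the binary-extreme model the thresholds
  assume, consistent with a methylated residue being highly methylated;
  unmethylated genomes are exactly 0. The intermediate pattern draws each
  genome uniformly on [0.35, 0.65] and is placed only at CpG sites (the
  thresholds admit an intermediate state only there); intermediate labels
  drawn at non-CpG sites are swapped with CpG sites' labels so the overall
  mix is preserved exactly. Cytosines whose context window touches a SNP
  carry no truth and no methylation calls: their context differs between
  sub-genomes, so a single shared context does not exist.
* **Reads.** The emulated libraries are 2 × 100 bp paired-end; both mates
  of a fragment come from one molecule, so SNP linkage and per-site label
  depth are those of the ~200 bp fragment span. Fragments are therefore
  simulated as single contiguous 200 bp reads (abutting mates — the
  minimum span consistent with the protocol; the insert size is not
  reported). Placement is uniform; `depth` (default 50×) is per
  sub-genome. Non-directional libraries draw all four strand products
  (OT/OB/CTOT/CTOB; analytically only the implied conversion state, XG
  CT/GA, matters). Per read and cytosine, methylation is Bernoulli in the
  site's truth level; an unmethylated cytosine converts with probability
  `conversion_rate` (default 0.9892) — unconverted remainders read as
  methylated, exactly the background a conversion control quantifies.
  Sequencing errors (default 10⁻³/bp) are applied after conversion and the
  methylation string reflects the final base, as a reference-based caller
  would see it. MAPQ is 40 with a 2% fraction at 10 to exercise the MAPQ
  gate.
* **Regions and expression.** Four of five contigs carry one gene
  (promoter–exon–intron–exon and a gene-adjacent non-transcribed tail);
  every fifth contig is entirely non-transcribed. Baseline per-genome
  expression is i.i.d. Gamma(20, 5); a genome with at least one
  uni-methylated site in its promoter is multiplied by
  `promoter_suppression` = 0.89, sized so that a single suppressed genome
  drops from the balanced 33.3% share to ≈30.9% — the magnitude of the
  promoter-methylation effect in wheat seedlings (100·s/(s+2) = 30.9 ⇒
  s ≈ 0.89). Only uni-genome promoter methylation suppresses; bi-genome
  promoter methylation shows no comparable effect.
  PPLR values sit near 0.5 with a `de_fraction` = 0.1 of genes shifted
  into the differential range.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: alignment and mapping error (reads are
emitted at their true positions; MAPQ is synthetic), PCR duplicates and
capture bias, CHH/CHG methylation at genuinely intermediate levels outside
the CpG intermediate class, methylation–sequence correlation (truth is
i.i.d. across sites), within-population polymorphism overlapping
homoeologous SNPs, and repeat/transposon content. Results on real data
additionally depend on catalogue quality, which here is derived from truth
rather than called from mappings.

## Numerical and procedural choices

* Coordinates are 0-based half-open internally; 1-based only at the
  SAM/TSV boundary, converted exactly once.
* Threshold ties follow the printed inequalities exactly: CpG ≥75 / ≤25
  inclusive; non-CpG "exceeding 10%" strict; PPLR ≤0.4 / ≥0.6 inclusive,
  <0.10 / >0.90 strict.
* Fisher tests use the exact two-sided null; the test suite checks them
  against integer-exact hypergeometric enumeration for all tables with row
  margins ≤ 30, and BH against an independent step-up implementation.
* Writers are deterministic (stable order, 4-significant-digit floats,
  `.` for missing); a rerun with the same config and seed is
  byte-identical, which the CLI tests assert by checksum. One root seed is
  split into independent child generators per stage.
* Merge of two SNP catalogues prefers the progenitor-derived (primary)
  alleles at conflicting shared positions and reports the conserved
  fraction; with no shared positions the conservation statistic is
  reported as not applicable. Consensus for read-derived SNP alleles is
  ≥90% of bases per genome at ≥5× — a strict reading of "unambiguous".
* Degenerate inputs: depth 0 simulates nothing (with a warning); a
  zero-total group is never tested (no call); zero-variance t tests return
  ±∞ with p = 0; an empty control yields an explicit undefined conversion
  rate.
* Problem sizes: the validation simulations use ~100 contigs × 2 kb
  (≈10⁵ cytosine sites, ≈10⁴ methylation-assigned) at 100× per sub-genome
  for pattern-mix recovery, 40 × 2 kb at 50× for end-to-end recovery, and
  ≥10⁵ control observations for conversion recovery — sizes at which the
  3-standard-error acceptance bands are decisive for the quantities under
  test.

## Known limitations

* Tri-genome resolution depends on local SNP density and partition
  diversity; in SNP-poor stretches sites fall back to a single biallelic
  partition and uni/bi patterns orthogonal to it come out `unresolved`.
  The `unresolved` fraction is reported and should be watched on real
  data.
* The binary non-CpG rule cannot represent genuinely intermediate CHG/CHH
  methylation (e.g. tissue-mixture effects); such sites will oscillate
  between Methylated and Unmethylated with coverage.
* With ~1% unconverted cytosines, thin single-genome labels (5–19 reads)
  clear the 10% threshold with a single unconverted read; the differential
  test catches these (they become `unresolved`), but tri calls have no
  such guard, so a small inflation of tri at very low coverage is
  possible.
* The q-value procedure (BH) is one of several in circulation; analyses
  using SLIM-style estimators will not match boundary counts exactly.
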