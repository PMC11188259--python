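# Methods

This note documents the models, conventions and design choices behind
`iblood`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The inference problem

The chicken I blood system is a red-cell alloantigen polymorphism typed
by hemagglutination. The package operationalises the chain of evidence
that assigns the system to the *RHCE* gene on microchromosome 23 and
replaces serology with DNA typing: two independent association scans
locate a ~200-kb region; annotation plus frequency-contrast filtering
reduces it to a candidate gene; a 15-SNP allele-specific-PCR panel
defines gene haplotypes; concordance between serological genotypes and
panel diplotypes validates the assignment; and read-depth analysis
characterises a 6243-bp structural deletion segregating in some lines.

## Pooled intensity regression

Each DNA pool contributes one intensity measurement per SNP. We model
pool intensity as the B-allele signal fraction

θ(pool, SNP) = mean over members of (B-allele dosage / 2) + ε,
ε ~ N(0, σ²) truncated to [0, 1].

The published procedure defines no numeric intensity; θ is the standard
Axiom contrast proxy and is what makes a 0/1/2 regression meaningful.
For every SNP, the expected pool allele count implied by serology
(I⁸I⁸ → 0, I²I⁸ → 1, I²I² → 2) is regressed on θ by ordinary least
squares — response and explanatory deliberately in that order, matching
the source procedure. For simple linear regression the squared Pearson
correlation and the slope *t*-test (n − 2 df) are invariant under
exchanging the two variables (asserted to 1e-12 in the tests), so the
unusual orientation is harmless. Degenerate inputs (zero variance in
either variable) return slope 0, R² 0, p 1 by contract; a perfect fit
clamps p to the smallest positive float so that p ∈ (0, 1] always
holds. SNP ranking is by p ascending with ties broken by (chrom, pos);
we rank rather than threshold because no explicit R² cut-off is
published.

Pool-level QC estimates the allele frequency of a SNP as its mean θ
across pools folded to ≤ 0.5 (individual genotypes do not exist for
pools) and retains SNPs with folded frequency ≥ 0.1 and missing
fraction ≤ 0.1, both bounds inclusive.

## Case/control association

Individual-genotype QC: MAF ≥ 0.05 and per-SNP call rate ≥ 0.99 over
the samples used. The test is the 1-df allelic χ² on the 2×2
(case/control) × (allele) count table without continuity correction;
the source names no test and this is the standard choice for allelic
GWAS. When any expected cell is below 5 the p-value falls back to
Fisher's exact test. Zero-margin tables carry no information and return
χ² = 0, p = 1. Genome-wide significance is −log₁₀(α/m). How the
published analysis counted "independently segregating markers" for its
threshold is not stated, so *m* is an explicit parameter defaulting to
the post-QC SNP count. Caveat recorded in the tests: the asymptotic χ²
and scipy's two-sided conditional Fisher p can differ by far more than
0.01 outside the small-p regime even with all cells ≥ 20; their
agreement is asserted only for strongly associated tables.

## Candidate-gene filtering

A variant qualifies if (i) it lies in the peak interval, (ii) its
predicted impact class is HIGH or MODERATE (impact labels are consumed
as input; annotation is upstream of this package), and (iii) its
alternate-allele frequency is ≥ 0.9 in one serologically defined
homozygote group and **exactly zero** observed alternate alleles in the
opposing group — the hard zero matches the published rule and is
attainable with small groups. Frequencies use 2 × (non-missing
samples) as denominator; variants with no called sample are skipped
with a log entry. Genes overlap the peak by any base (1-based
inclusive) and rank membrane-annotated (GO:0005886) first, then by
passing-variant count. The frequency rule is applied per variant, not
per gene aggregate.

## Panel haplotypes and diplotype calling

The packaged table transcribes the published 15-SNP panel (positions on
build GRCg7b) and 16 haplotype profiles, H01–H08 and H10–H17 (the
source's own tally says 17; its table lists 16 with no H09 — the
discrepancy is carried, not resolved). Four "short" haplotypes (H07,
H12, H13, H16) have the trailing SNP block 8–15 deleted, following the
table's no-amplification dashes rather than the narrative's "last nine
SNPs".

Expected panel genotype of a diplotype: REF/REF → RR, ALT/ALT → AA,
REF/ALT → RA; a site deleted on one haplotype amplifies hemizygously
and appears homozygous for the retained allele; deleted on both → FAIL.
Diplotype calling enumerates all unordered haplotype pairs (with
repetition) and keeps exactly-matching pairs — panel assays are
discrete calls, so no error tolerance. Consequences faithfully
represented: a full/short heterozygote is indistinguishable from the
full homozygote (flagged `short_ambiguous`), and short haplotypes are
uniquely callable only in the homozygous state (all-FAIL block). A
`candidates` argument restricts enumeration to the haplotypes known to
segregate in a line, which is how homozygous-looking profiles become
unique calls in practice. Profiles with no compatible pair and no
heterozygous site are reported as candidate novel haplotypes with their
inferred allele string — mirroring how novel full-length and short
haplotypes are discovered.

In the transcribed table H07 and H16 (discovered in different lines)
carry *identical* panel profiles: all-reference over SNPs 1–7 and
deleted over 8–15. The table therefore declares them panel-equivalent;
validation accepts declared equivalences and rejects any undeclared
duplicate profile, and the caller reports the equivalence-class
representative (H07). The six-SNP epitope cluster (L43F…Y147H, panel
order 4–9, exons 2–3) classifies haplotypes as I2-like (all ALT),
I8-like (all REF), indeterminate (deletion inside the span) or other.

## Concordance

A serological genotype matches a diplotype when the two haplotypes can
be assigned one-to-one to the two serological alleles under the line's
allele → haplotype map (a haplotype may serve several alleles, e.g.
H03 for both I⁴ and I⁸). Percentages are rounded half away from zero
to whole percent — the convention that reproduces every published
figure. Samples with ambiguous diplotype calls are reported separately
and excluded from denominators by default. The aggregate report pools
raw counts across lines, each line scored under its own map.

The packaged cross-tabulations transcribe the published per-line
counts. Cells the source reports only at the margin (the diplotype of
single discordant birds, the NIU heterozygote breakdowns) are filled
with the minimal het/hom-confusion pattern consistent with the
published per-line consistency rates and flagged `printed=False`; the
aggregate I⁸I⁸ (76/99) and heterozygote (124/142) figures require the
unpublished supplementary table and are deliberately not reproduced or
tested — the main-text-supported aggregate I²I² accuracy (88/89 = 99%)
is.

## Deletion calling from depth

The source located the deletion visually in a genome browser; the
thresholded caller here is this package's operationalisation. Depth is
normalised by the median over a flanking diploid interval. Homozygous
deletions are maximal runs of ratio ≤ τ_hom = 0.15, merged across gaps
≤ 50 bp; merged runs are trimmed of stray boundary components shorter
than the merge gap (a component shorter than the gap it bridges is no
evidence for a breakpoint), and the longest span ≥ 500 bp is reported
with its first and last depressed base. Heterozygous deletions are
detected on a 200-bp moving-average track (base-level noise at half
depth breaks raw runs constantly), edge-refined on the raw track, and
accepted when the raw mean ratio lies in [0.3, 0.7]. Defaults were
chosen to be robust at the study's 4× combined low-pass coverage. The
published breakpoints are treated as the first and last deleted bases,
which yields the printed 6243-bp length.

Coordinates are 1-based inclusive internally; bedGraph (0-based
half-open) is converted exactly once at the file boundary; BED output
is 0-based half-open. Intervals carry a genome-build tag (panel:
GRCg7b; deletion: GRCg6a) and cross-build comparison raises — builds
are never converted. Breakpoint consensus across samples uses the low
median (stays on an observed breakpoint) and reports the maximum
deviation of any call from the consensus.

Exon geometry: the real exon coordinates of the gene are not published.
`rhce_exon_model()` is a synthetic 10-exon model, placed so the
deletion starts 43 codons (129 bp) before the end of exon 3 and runs
past the end of the gene — reproducing the published geometry (exon 3
partially removed, exons 4–10 fully) without claiming real coordinates.

## Synthetic data: what it emulates, and what it does not

Generators are deterministic given (config, seed).

* **Diplotypes**: Hardy–Weinberg draws from per-line haplotype
  frequencies. Real study lines are selected and partly pedigreed; HW
  is sufficient for testing the inference chain, so pedigree structure
  and selection trajectories (e.g. the rise of the short haplotype in
  one brown-egg line) are not simulated.
* **Serology error**: only het↔hom confusion toward a dominant allele
  (P(het recorded as dominant homozygote) = q, and the reverse
  hom-as-het channel), because every reported discrepancy class is of
  this kind. Cross-reactivity between unrelated alleles is not
  modelled.
* **Array genotypes**: causal-region SNPs copy the causal gamete
  indicator with probability exp(−d/ld_decay_bp) (default 50 kb) and
  otherwise draw from the causal-allele frequency; background SNPs are
  independent HW draws with frequencies uniform on [0.1, 0.9]. Real LD
  is block-structured, not exponential; this matters only for the
  shape, not the existence, of the association peak.
* **Pools**: default 5 sets × 3 serology classes, sizes uniform on
  4–15, members drawn without replacement per pool; θ noise
  σ = 0.03 truncated to [0, 1], chosen so the causal SNP separates
  cleanly with 15 pools. No array-normalisation artefacts or batch
  effects; per-pool replicate counts are not published, so θ is a
  single draw per pool.
* **Depth**: per-base Poisson with λ = 4 (the study's combined
  low-pass coverage), λ·copies/2 inside the deletion span; a noiseless
  mode returns exact expectations. Mappability, GC bias and read-level
  structure are not simulated, so passing tests show correctness of
  the calling logic at Poisson noise, not robustness to alignment
  artefacts.

Because the real per-sample intensities, 54K genotypes and the
supplementary concordance table are unavailable ("data available on
request"), the published peak p-value (3.355E−10), post-QC SNP counts
(580,961; 49,760) and the marker count behind the 6.000512 threshold
cannot be recomputed. The suite substitutes recovery properties at
study-scale designs: causal-SNP recovery by the pooled scan in ≥ 95/100
seeds at σ = 0.03 (150 birds, 15 causal + 60 background SNPs);
familywise type-I control of the case/control scan under label
permutation (100 seeds × 300 SNPs); exact agreement of the diplotype
caller with an independent exhaustive-enumeration oracle (136 pairs +
1000 random profiles); recovery of the serology error rate
(heterozygote-class accuracy ≈ 1 − q within 3 s.e. at n = 2000); and
deletion-breakpoint recovery within ±100 bp at 4× Poisson depth in
≥ 95/100 seeds. Problem sizes were chosen to make each property a
sharp statistical test while keeping the whole suite fast.

## Numerical and interface conventions

* p-values clamped to (0, 1]; R² clipped to [0, 1].
* Ranking ties broken by (chrom, pos) ascending, stable sorts
  throughout, so outputs are byte-identical across reruns.
* `top_region` centres a window on the best SNP and clips at
  chromosome bounds.
* Whole-percent rounding is half away from zero.
* Config files (JSON/YAML) are schema-validated; unknown keys are
  errors; every stochastic stage has an explicit seed recorded in the
  run manifest.

## Known limitations

* The panel cannot distinguish declared panel-equivalent haplotypes
  (H07/H16) or a full/short heterozygote from the full homozygote;
  resolving these requires the junction assay or sequencing, which are
  out of scope.
* Statistical phasing (EM) for populations with unknown haplotypes is
  not implemented; novel haplotypes are inferred only from
  homozygous-appearing profiles.
* The case/control Fisher fallback uses the conditional two-sided
  convention of scipy; mid-p variants are not offered.
* Allele maps are inputs, as in the original reasoning; the package
  does not infer serological allele identities de novo.
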