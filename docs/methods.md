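# Methods

This note documents the models and estimators implemented in `popsweep`,
the choices made where several conventions exist, and what the synthetic
data generator does and does not emulate.

## Synthetic data model

The generator (`popsweep.sim`) emulates the product of a small
whole-genome resequencing study of structured populations: a target
population (default 6 samples), a domestic reference panel (default 20)
and a wild outgroup (default 4), genotyped at biallelic SNPs placed at a
configurable density (default one per 300 bp) along user-defined contigs.

**Differentiation.** Ancestral allele frequencies are drawn
Uniform(0.05, 0.95) (the floor keeps most sites above the MAF filter by
design). For a population with drift coefficient F, the population
frequency at a site with ancestral frequency p is drawn from the
Balding–Nichols distribution Beta(p(1−F)/F, (1−p)(1−F)/F), which has
mean p and variance F·p(1−p). For two populations sharing F, the
expected Hudson FST — sample-size-corrected numerator over denominator,
in expectation over sites — equals F (more generally (F₁+F₂)/2). This
analytic target is the calibration oracle used throughout the test
suite; defaults are F = 0.10 (target), 0.08 (reference panel, a mixture
of breeds treated as one unit), 0.15 (outgroup).

**Sweeps.** A planted sweep is an interval in which the target
population's draw uses a larger coefficient F_sweep and an ancestral
frequency rescaled toward fixation, p′ = 1 − s·(1−p) with
s = `diversity_scale` ∈ (0,1]. Both changes reduce target heterozygosity
and inflate allele-frequency divergence — the θπ-ratio and FST signature
the scan looks for.

**Linkage disequilibrium.** Each haplotype carries a latent uniform
variate along the chromosome; at each site it is retained from the
previous site with probability exp(−d/`ld_block_scale`) (d = separation
in bp, default scale 10 kb) and redrawn otherwise, and the allele is the
indicator {u < population frequency}. Copying the latent variate rather
than the realized allele is deliberate: it preserves the per-site
marginal distribution exactly — so the Balding–Nichols FST calibration
is untouched — while giving nearby sites positive, geometrically
decaying r². The model is first-order (no recombination graph, no
haplotype blocks with sharp edges); it is sufficient to make decay
curves and their ordering across scales testable, not to reproduce
realistic haplotype structure.

**Other fields.** REF/ALT pairs are labelled transition with probability
R/(1+R), R = `tstv_ratio` (default 2.57, a typical mammalian
whole-genome value). Genotypes are masked missing at `missing_rate`
(default 2%). Per-site depth is Poisson with mean 20× per sample; RMS
mapping quality and base quality are constants (60, 35) chosen to pass
the default filters, so filter tests construct their violations
explicitly. The per-contig SNP count is deterministic
(round(length × density)), which lets tests target exact problem sizes.

**What passing tests do not show.** The generator has no demography
through time, no selection other than the planted drift/diversity
rescaling, no reference-sequence context for the SNPs beyond a random
background (so annotation consistency between the FASTA and the VCF REF
is enforced only at the variant site itself), site-independent
missingness, and constant quality fields. Recovery and calibration
results on this model therefore validate the estimators and the
pipeline plumbing, not performance on real data with batch effects,
call-rate structure or reference bias.

## Filters

A site survives iff depth ∈ [`min_depth`, `max_total_depth`],
RMS MQ ≥ 20, base quality ≥ 20, missingness ≤ 0.2, MAF ≥ 0.05 (computed
from called alleles only) and the record is a biallelic single-nucleotide
variant. All comparisons are inclusive. The removal report attributes
each dropped record to the first violated criterion in a fixed order
(biallelic, low depth, high depth, MQ, BQ, missingness, MAF); the
surviving set is order-independent because every mask is evaluated on
the input. The high-depth cap (default 31,000 summed over samples) is a
guard against collapsed repeats and is configurable.

## Annotation

Precedence when a SNP touches several transcripts is most-severe-wins:
coding (stop-gain > stop-loss > nonsynonymous > synonymous) > splicing >
intronic > upstream > downstream > intergenic. Splicing means the first
two intron bases on either side of a junction. Flanks are 1 kb from the
transcript start (upstream) and end (downstream), strand-aware. Coding
effects substitute REF and ALT into the spliced CDS (reverse-complemented
on minus-strand genes; the VCF REF is trusted over the FASTA base at the
variant position) and translate the affected codon with the standard
genetic code. A CDS whose length is not a multiple of three yields
`exonic_unresolved` with a logged warning rather than an abort.
Coordinates are 1-based inclusive at the I/O boundary (VCF, GFF3) and
0-based half-open internally (windows, BED output).

## Sweep scan

θπ per window is the sum of per-site unbiased heterozygosities
2p̂(1−p̂)n/(n−1) divided by the full window length in bp (no
accessible-site masking; invariant sites contribute zero). Window FST is
Hudson's estimator combined as a ratio of sums, which is bounded above
by 1 and robust to low-diversity windows; sites with fewer than two
called alleles in either population are skipped. Windows are 40 kb
sliding by 20 kb by default; terminal windows that would be truncated
are dropped so per-bp normalization stays comparable (fully
configurable, e.g. 500 kb/10 kb).

Outlier calling Z-standardizes log₂(θπ_ref/θπ_target) and the
log-transformed FST. Because window FST can be ≤ 0, it is shifted by
1 − min(FST) before the log (a `log_transform_fst=False` switch
standardizes raw FST instead; published descriptions of this transform
are rarely precise enough to pin down one convention, so both are
provided). A window is an outlier when both Z-scores lie at or above
their empirical 95% quantile (linear-interpolation quantile, ties
included); union and single-statistic modes are available. Overlapping
or bookended outlier windows merge into regions; genes are assigned by
transcript-span intersection and deduplicated for the global list. Note
that the selected-gene count depends on the FST estimator, the transform
and the merging rule; comparisons across tools should fix all three.

With very small target panels (e.g. 6 samples) the two Z-scores are
substantially positively correlated under the null — window FST and
target θπ share the same few samples' sampling noise (measured
ρ ≈ 0.45 at 6 vs 20 samples; ≈ 0.07 at 20 vs 20) — so the joint
top-5% rule yields more than top_frac² outliers (≈1.7% rather than
0.25% at the default design) while remaining far stricter than either
marginal 5% rule. Null-calibration checks against the top_frac² level
are therefore run at the 20-vs-20 design where the independence
approximation holds; replicate genomes, not windows, are the unit used
for the standard error, because overlapping windows share half their
SNPs and outliers arrive in adjacent pairs.

## Distances, tree, PCA

p-distance between two individuals is Σ|g_i − g_j| / (2·n) over
pairwise-complete sites (allele-sharing distance on unphased dosages —
genotypes here are unphased, so a haplotype-level p-distance is not
identifiable). Pairs sharing no called site are an error; triangle
violations, which pairwise-complete deletion can produce, are logged.
Neighbor joining is the standard Saitou–Nei Q-criterion agglomeration;
ties break on the lowest active index pair, and negative branch lengths
are clamped to zero with the excess moved to the sibling edge (raw
values logged at DEBUG). On additive inputs the reconstruction is exact,
which the suite verifies on randomly generated additive trees. Bootstrap
supports resample sites with replacement (default 1000 replicates; the
pipeline default is 100 to keep desk-scale runs fast) and report the
percentage of replicates containing each internal bipartition of the
point tree. PCA mean-imputes missing dosages, drops monomorphic sites,
scales each site by √(p̂(1−p̂)), and eigendecomposes the sample
covariance normalized by the number of sites; component signs follow a
largest-coordinate-positive convention.

## LD

The default r² is the squared Pearson correlation of dosage vectors over
pairwise-complete samples (composite/Rogers–Huff), appropriate for
unphased data; under HWE-style random pairing it coincides with the
gametic r², and for unlinked sites it inflates to ≈ 1/(n−1), which the
suite documents rather than corrects. The EM mode estimates the four
two-locus haplotype frequencies by the classic gametic-phase EM
(iterating the cis/trans split of double heterozygotes) and returns
D²/(p_A q_A p_B q_B); it serves as a cross-check and matches phased
counts exactly when no double heterozygotes are present. Decay curves
bin all intra-contig pairs closer than `max_distance` (default 500 kb,
the averaging window conventional in livestock LD comparisons) by
separation; bins can be subsampled to `max_pairs_per_bin` pairs with a
seeded draw after enumeration, so capped and uncapped runs agree in
expectation. The half-decay distance is the first bin midpoint at which
the mean falls to half the first bin's mean; near the 1/(n−1) floor this
summary loses resolution, so cross-scale comparisons should use bins
within the range where exp(−2d/scale) is non-negligible.

## Enrichment

The test is the exact binomial tail P(X ≥ k), X ~ Binomial(n, m/M) — the
"sampling with replacement" approximation of the hypergeometric, which
is also provided for comparison and is slightly more conservative for
large terms. The background universe defaults to all genes in the term
map and is configurable; adding unannotated genes to the universe can
only increase p-values. FDR is Benjamini–Hochberg (statsmodels). Real
GO/KEGG content is out of scope: the interface takes any two-column
gene→term file.

## Determinism and problem sizes

All randomness descends from a single root seed split per stage
(recorded in the run manifest); identical config + inputs give
byte-identical outputs, which the suite asserts end to end. Test and
acceptance problem sizes — 0.1–3 Mb contigs, hundreds to ~10,000 SNPs,
10–20 replicate genomes — are chosen so that every statistic is either
checked against an exact oracle or estimated with a standard error small
relative to its tolerance; headline quantities from published
whole-genome studies (millions of SNPs, hundreds of selected genes)
scale with data volume and external databases and are not reproduced at
these sizes.
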