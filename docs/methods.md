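# Methods

## Data model

Genotypes are diploid biallelic SNP-array calls, coded 0 (hom A), 1 (het),
2 (hom B), −1 (missing), in an individuals × markers matrix with a marker
map sorted by (chromosome, position). Coordinates are 1-based inclusive
internally and converted to 0-based half-open only when writing BED.
Chromosome labels are strings and the autosome set is configurable (the
default labelling 1..38 matches the dog genome); nothing downstream depends
on the species. Allele-code orientation is immaterial to every statistic in
the package (all are symmetric in allele labels); the PED reader fixes
orientation deterministically to the first allele observed per marker in
file order, which makes write→read a projection that is the identity on its
own image — round-trip tests are phrased accordingly.

## Quality control

"Call rate 0.10" is implemented as *maximum missingness* 0.10 per marker
and then per sample (the PLINK `--geno`/`--mind` idiom, marker filter
first); a literal call-rate ≥ 0.10 filter would remove essentially nothing
and cannot be what a QC step intends. The MAF ≥ 0.01 filter is applied only
on the tier feeding Tajima's D and F_ST; run and island detection must see
monomorphic and rare sites, since removing them would fabricate gaps and
distort sharing profiles.

Sample selection to 20 per breed ranks individuals by mean within-breed
relatedness using a standardized-genotype (GRM-style) estimator,
(1/M′) Σ_m (g_im − 2p_m)(g_jm − 2p_m)/(2p_m(1−p_m)), and greedily removes
the most related individual (ties broken lexically) until the target size
is reached. Only the within-breed ranking matters for this use, so the
estimator substitutes for PLINK's method-of-moments PI_HAT without
consequence. With very few samples the in-sample allele frequencies bias
off-diagonal entries by about −1/(n−1); an optional `freqs` argument
accepts external reference frequencies where that matters.

## Run detection

An interval of consecutive markers is *feasible* for an individual when its
endpoints are non-missing target-state markers (heterozygous for HRR,
homozygous for ROH), internal opposite-state and missing counts are within
budget (3 and 1 for HRR; 1 and 2 for the consecutive-ROH utility), all
adjacent gaps are ≤ 50 kb, and it spans ≥ 20 SNPs and ≥ 50 kb (length
convention: last bp − first bp). The scanner returns **all
inclusion-maximal feasible intervals**: for a fixed start the
budget-feasible ends form a prefix and the maximal end is monotone in the
start, so a two-pointer sweep over gap-free segments finds the exact set in
O(m) per individual per chromosome. This output is clean to verify — unit
and acceptance tests check exact set equality against an O(m²) brute-force
enumerator — at the cost that maximal intervals may overlap. Per-SNP
coverage, which is what island calling consumes, is invariant to that
choice; for run-level recovery scoring the overlapping intervals are first
union-merged per individual (`merged_run_intervals`).

## HBD hidden Markov model

States: K HBD classes with fixed rates R = (2, 4, 8, 16, 32, 64) — the
rate sets the expected segment-length scale, higher meaning shorter, older
segments — plus one non-HBD class at R = 128. Between adjacent markers at
genetic distance d (physical distance × 1 cM/Mb, the usual default without
a genetic map) the chain persists with probability e^(−R_k d) and otherwise
redraws a state from the mixing distribution π. HBD classes emit a
homozygote for an allele drawn at the breed frequency, contaminated toward
Hardy–Weinberg with probability ε = 0.001; the non-HBD class emits plain
Hardy–Weinberg genotypes; missing genotypes are uninformative (emission 1
in every state). π is fitted per individual by EM from a uniform start,
with the M-step proportional to total state occupancy — an approximation to
segment-count weighting that is simpler and adequate for segment calling.
Rates are never estimated. Segments are maximal marker stretches with
summed HBD posterior ≥ 0.5.

Numerics: the forward–backward pass is scaled (no log-space needed), runs
batched across a breed's individuals with per-individual π, and is verified
against exhaustive path summation on ≤ 6-marker instances to 1e−8 in log
likelihood. Monomorphic sites are retained (QC1 applies no MAF filter) with
frequencies clamped to [1e−3, 1 − 1e−3]; at the clamp a fixed site is
nearly uninformative, which is the intended behaviour. The demo
configuration caps EM at 25 iterations — convergence on data of that size
happens well before — while the library default is 200 with a 1e−6
log-likelihood tolerance.

## Islands

For each breed and run type, f_m is the fraction of individuals with at
least one run covering marker m (by base-pair interval, so duplicated or
overlapping runs count once). The island threshold is the 99.9th percentile
("top 0.1%") of f over **all** markers genome-wide in that breed, zeros
included, with linear interpolation between order statistics; whether the
original analysis excluded zero-sharing SNPs from the percentile is not
reconstructible, so the inclusive choice is fixed and recorded in the
output provenance. Islands are maximal stretches of ≥ 2 consecutive markers
(no gap tolerance, never spanning chromosomes) with f_m ≥ threshold and
f_m > 0; the positivity guard prevents an all-zero profile from producing
genome-wide "islands", and a constant profile is flagged as degenerate.

## Tajima's D

Windows are 250 kb, non-overlapping, anchored at position 0 per
chromosome. Per site, n_s = 2 × called individuals; sites with n_s < 4 are
ignored; a site segregates when 0 < x < n_s for alt count x; per-site
π = 2x(n_s − x)/(n_s(n_s − 1)), the exact mean pairwise difference among
the sampled chromosomes. Window π sums site π, S counts segregating sites,
and D = (π − S/a₁)/√(e₁S + e₂S(S−1)) with the classical constants
evaluated at the window median of n_s over segregating sites — a documented
approximation for sites with unequal call rates (exact when data are
complete, the case the oracle tests cover to 1e−10). Windows with S = 0
have undefined D. Signals are, per breed, windows with D at or above the
genome-wide (1 − 0.001) quantile of defined D values *and* D > 0; the
positivity guard keeps degenerate breeds from flagging negative-D windows,
and threshold ties are all kept.

## Cross-breed statistics

The genome is decomposed by a sweep line into maximal regions of constant
breed coverage (≥ 1); each region's breed count k is standardized over all
regions (sample standard deviation) and regions with z ≥ 1.645 (one-sided
p < 0.05) are hot spots, adjacent significant regions merged with their
supporting sets unioned (the merged record carries the maximum component
z). Island × signal overlaps are counted per same-breed pair with ≥ 1 bp
intersection; a cross-breed mode exists behind a flag. The ANOVA treats
each (breed, region) incidence as an observation with response = the
region's sharing count and group = the breed's factor level — the original
numeric coding ("based on chromosomal location and the number of breeds")
is not operational, so this reading is an interpretive choice recorded in
provenance, not asserted as equivalent. F_ST is the Weir–Cockerham (1984)
two-population estimator with ratio-of-sums aggregation over loci
polymorphic in the pooled pair; negative estimates are reported unclipped.

## Synthetic data

The generator emulates the shape of the study data — multiple breeds of 20
diploids on autosomes with ~15 kb SNP spacing — at desk scale (default two
25 Mb chromosomes). Ancestral frequencies are Uniform(0.05, 0.95); breed
frequencies follow the Balding–Nichols model at divergence F = 0.10;
background genotypes are Hardy–Weinberg with independent sites (no linkage
disequilibrium — sufficient for every statistic in scope, since none uses
haplotype structure; a documented limitation for any LD-based extension).
Planted features: heterozygous tracts (carriers het with probability 0.95),
autozygous tracts (carriers homozygous for an allele drawn at the breed
frequency, 1% contamination), and balancing windows (frequencies redrawn
Uniform(0.4, 0.6) in every breed, heterozygote probability inflated ×1.3
and renormalized — one knob controlling both excess heterozygosity and D
inflation). Missingness is uniform at 2%. Everything is drawn from one
seeded generator; equal configs produce byte-identical outputs.

What passing tests show: the scanner, island caller, HMM and window
statistics are exact relative to their independent oracles, and planted
features of realistic effect size are recovered under no-LD,
no-genotyping-artefact conditions. What they do not show: behaviour under
array ascertainment bias, LD structure, or genotyping error beyond uniform
missingness — real-data thresholds (the top-0.1% percentiles in
particular) should be read as relative, not absolute, levels.

## Problem sizes

The bundled demo uses 5 breeds × 20 individuals × ~4,000 SNPs; recovery
experiments use 3 breeds on two 25 Mb chromosomes (HRR tracts), one breed
on one 25 Mb chromosome (HBD tract), and 2,000 windows per breed on two
250 Mb chromosomes (balancing windows). These sizes give stable recovery
statistics while keeping a full run on one CPU in well under a minute per
experiment.

## Known limitations

- The exact percentile conventions of the original tooling (quantile
  interpolation, zero inclusion) are unknown; ours are fixed and recorded.
- The HBD M-step's occupancy weighting slightly favours long segments over
  many short ones relative to segment-count weighting.
- ANOVA response coding is interpretive (see above).
- No VCF/PLINK-2 input, no sex chromosomes, no phased data.
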