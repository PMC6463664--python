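# Methods

## The problem

Meiotic recombination in hexaploid wheat redistributes parental alleles in
two ways: crossovers (COs) exchange large chromosome arms reciprocally, and
gene conversions (GCs) copy short tracts non-reciprocally between homologs
during double-strand-break (DSB) repair. In recombinant inbred line (RIL)
populations built by single-seed descent (SSD), both leave characteristic
footprints in genotype data: COs as changes of the predominant parental
allele along the chromosome, GCs as short donor islands embedded in the
other parent's background. This package implements the calling machinery
for both signals at two resolutions — a genotyping-array mode (thousands of
markers, 20-Mbp windows) and a skim-sequencing mode (millions of
discrimination SNPs, ~1 per 540 bp) — plus cross-platform validation,
landscape statistics, and a DSB-based expectation calculator, all driven
and tested by an SSD simulator that provides planted ground truth.

## Array mode

**Window CO calling.** Marker calls are binned into fixed windows of
W = 20 Mbp. The window size derives from genome size over genetic map
length times a shared-haplotype factor: 16x10^9 bp / 3894 cM x 5 = 20.5
Mbp, rounded to the nearest 10 Mbp. Window k (0-based) covers
[kW+1, (k+1)W]; a marker at position p belongs to window floor((p-1)/W).
Each window takes the strict majority of its parent-specific calls; a tie
between parents, or a window whose HET calls outnumber the parental calls,
is heterozygous; a window without informative calls is missing. A CO is
recorded at each change of predominant parent between consecutive
non-missing windows, positioned at the start coordinate of the later
window. Missing windows are transparent, and in parental mode so are HET
windows: A -> HET -> B yields exactly one CO (at the first B window),
A -> HET -> A none. This avoids double-counting around residual
heterozygous blocks; the tie -> HET rule is the conservative choice for F8
lines, which are ~99% homozygous.

**GC estimation.** No windows: after dropping HET and missing calls, every
change of parent between adjacent markers is a shift (never across a
chromosome boundary). Since each CO also produces one shift, the per-line
GC estimate is shifts - COs, clamped at zero with a warning (a CO falling
in a marker desert can make the raw difference negative). By construction
COs + GCs = shifts whenever no clamp fires.

**TILLING mode.** EMS-mutagenized lines use induced mutations as markers:
records are kept only if the substitution is EMS-type (G>A or C>T as
recorded on the reference strand — the pair covers both strands, so no
strand flipping is applied), mapping quality >= 50, alternate depth >= 4,
and the chromosome is named. Zygosity is homozygous-mutant when the
alternate fraction strictly exceeds 0.85, else heterozygous; window calling
then records homozygous/heterozygous shifts (zygosity mode). Because
marker counts vary strongly between lines, GC counts are normalized to a
target of 5000 SNPs (linear scaling).

## Skim-sequencing mode

**Discrimination SNP set.** Variant calls of one parent against the other
parent's reference are filtered to homozygous sites (alternate fraction
> 0.80, strict), quality >= 30, depth >= 3; then any SNP lying in an
inclusive 10-bp sliding span containing 3 or more retained SNPs is removed
(clustered calls indicate misalignment). The sliding reading is the
conservative interpretation of a phase-free "10-bp window".

**Per-line classification.** Line variants below quality 20 are discarded.
At each discrimination site exactly one label is assigned: parent A when a
SNP with a matching alternate allele exceeds 80% of reads; undetermined
when a SNP exists but fails the fraction or allele test; undetermined when
no SNP is called and coverage is below the reference-confirmation minimum;
parent B when no SNP is called and coverage suffices (absence of a variant
call at a covered site is the reference observation). The
reference-confirmation minimum defaults to 3 reads. A single read is an
unreliable confirmation at ~6x Poisson coverage, and 3 matches the depth
standard applied when the discrimination set itself is built; the knob is
configurable down to 1 for the most permissive reading.

**Segmentation.** Undetermined sites are removed; the remaining label
string is cut into maximal single-parent runs. A change of parent is only
believed when 3 or more consecutive markers support it: shorter runs are
discarded (their markers dropped) and the flanking same-parent runs merge,
iterating until stable. Each surviving internal run — bounded by the other
parent on both sides — is emitted as a GC event spanning its first to last
marker, with the run length as marker support. Terminal runs at chromosome
ends are emitted as SHIFT boundaries, not GC tracts (a conversion requires
flanking donor on both sides). Event span is measured marker-to-marker:
resolution is bounded by the ~540-bp marker spacing, and extrapolating
beyond the observed markers would fabricate precision.

**Length classes.** Left-closed right-open bins [20 bp, 2 kbp), [2, 10
kbp), [10, 500 kbp), [500 kbp, inf); spans below 20 bp are SUB_MINIMUM and
excluded from GC tallies. Runs spanning >= 20 Mbp / >= 40 Mbp carry
crossover-proxy flags for comparison with the window-based analysis —
at that scale a "tract" is better read as a CO-bounded block.

**Conservation and read-pair checks.** Two events in different lines are
shared when their intervals overlap by >= 1 bp with the same donor; events
unique to one line are high-confidence meiotic candidates, events conserved
in a strict majority of lines are flagged as likely structural variation
between the parents rather than recombination. Donor-change sites can be
validated directly where the flanking SNPs are close enough for single read
pairs to span both: a site with >= 3 such pairs is assessable, and
supported when the majority report the expected discordant parental
alleles; accuracy = supported / assessable. GC frequencies are compared
across lines after scaling by informative-site counts
(gc x reference_sites / informative_sites).

## Cross-platform validation

An array CO is resolved only to the intersection of two 20-Mbp windows, so
it validates when the interval +-20 Mbp around its window-start position
overlaps a skim donor-change boundary (the inter-marker gap between two
adjacent runs — the boundary is a region, not a point, because skim
resolution is the local marker gap). An array GC validates when a 3-Mbp
total-width interval (+-1.5 Mbp) centred on the defining array SNP
intersects a skim GC of the same line; the total-width reading matches the
stated rationale (16 Gbp / 5000 markers ~ 3.2 Mbp of genome per marker),
and +-3 Mbp is available as an option. The call is high-confidence when the
matched tract's donor agrees with the array allele at the defining SNP.

## Landscape statistics

Per-site sharing censuses count the lines carrying each distinct CO site.
Genic bias compares gene counts in 40-Mbp windows centred on CO sites
against windows centred on every array SNP (controlling for the array's
genic design bias) with a two-tailed Welch t test; gene counting uses
any-overlap of the gene interval with the window. Two identical degenerate
samples return t = 0, p = 1 instead of NaN. Genome profiles rescale every
chromosome to 500 Mbp, accumulate events in 20-Mbp bins of the normalized
axis, and report a trailing simple moving average (period 15; the first 14
bins are undefined). Profile rows are clustered by average linkage on
1 - Pearson r dissimilarity; clade support is the plain bootstrap
proportion over column resamples (the approximately-unbiased multiscale
variant is a distinct method and deliberately not reimplemented);
zero-variance rows cannot be placed by a correlation metric and are
dropped with a warning.

**DSB expectations.** From a mean of 2133 +- 157 immunostained DSB foci
per male meiosis: doubling for female meioses gives 3952-4580 per meiosis;
eight generations give 31,616-36,640; and discounting detectability by 50%
per generation (an allelic conversion is only visible while the region is
still heterozygous) gives bound x sum_{g=1..8} 0.5^(g-1), rounded up:
7874 and 9125. The exact geometric sum followed by ceiling reproduces both
bounds (7873.125 -> 7874; 9124.219 -> 9125).

## The simulator

**Genetics.** A line is an F1 heterozygote selfed for generations-1 rounds
(F8 default: 7 rounds), keeping one offspring per round; each offspring is
formed from two independent meioses of the same parent plant. Haplotypes
are piecewise-constant mosaics over the two founders. Per chromosome and
meiosis the CO count is Poisson conditioned >= 1 (obligate CO); positions
are drawn from a mixture of a uniform component and a telomere-proximal
Beta(1.5, 4) component reflected to both ends (mixture weight 0.6).
Interference is not modelled — the callers are interference-agnostic — and
is noted as an extension point. GC tracts (mean 1 per chromosome per
meiosis) are stamped as non-reciprocal copies from the homolog; a tract
falling where the homologs agree changes nothing and is not recorded.

**Calibration.** The per-gamete conditioned mean CO per chromosome is 1.1.
The target is ~2.2 surviving breakpoints per chromosome in the final line —
the per-chromosome rate implied by 40.8-51.9 COs per line over 21 wheat
chromosomes — and selfed RILs approach twice the meiotic junction density
at fixation (Haldane-Waddington), giving 2.2 / 2 = 1.1. The tract-length
mixture (weights 0.15/0.20/0.25/0.40 over the four classes, class-4
lengths log-uniform on 3-15 Mbp) is a free calibration knob: no
per-meiosis GC rate is known for wheat, and the mixture deliberately
carries a heavy megabase tail so that both detection regimes are exercised
— the dense skim markers see all classes while the sparse array panel sees
only the tail, mirroring the two assays' real resolutions.

**Observation layers.** The array panel holds 618 markers (206 per
chromosome — the per-chromosome density of 4335 markers over 21 wheat
chromosomes), placed uniformly once per population and read directly off
each line's final mosaic. Skim discrimination sites are spaced
exponentially (mean 540 bp) with random distinct ref/alt alleles; parent
reads at 20x error-free coverage feed the discrimination-set build, and
per line each site draws depth ~ Poisson(6.42) and alternate-read counts ~
Binomial(depth, p) with p = 1 - 0.001 at parent-A sites, 0.001 at parent-B
sites and 0.5 in residual heterozygous regions. Sites with any alternate
read become variant records whose quality grows with alternate depth; the
coverage track reports every site.

**Truth ledger and evaluation.** A shadow lineage without GC tracts
replays the identical crossover draws, so surviving post-SSD CO
breakpoints (transitions of the HET-removed shadow state string) are
recorded free of tract edges. A planted tract is detectable when the final
line is homozygous for the donor inside it and for the other parent on
both flanks, and recoverable when it additionally contains >= 3 classified
skim markers — sparser tracts are undetectable by the break rule by
construction and are excluded from the recall denominator. Recall is the
fraction of recoverable tracts overlapped by a called GC with the correct
donor. Precision scores each call against the true mosaic: correct when
its interval lies within a single same-donor segment (tract islands and
CO-bounded donor blocks both qualify; runs created by noise or straddling
a true junction do not). Calls whose midpoint falls in residual
heterozygous truth are excluded from the primary precision denominator and
reported separately: at ~6x coverage a heterozygous region yields
coin-flip labels at the minority of sites that escape the 80% fraction
test, producing spurious >= 3-marker runs that no parameterization of the
homozygous-only calling logic can avoid — the same hazard that motivates
restricting skim genotyping to homozygous calls in the first place.
Overall precision including those calls is also reported.

## Problem sizes and numerical choices

Desk scale is 3 chromosomes x 600 Mbp. The parameter-recovery experiment
uses 100 lines (~3.3 M discrimination sites per line); heterozygosity
decay uses 200 lines; oracle-equivalence checks use 500 random fixtures
per primitive. All randomness flows from a single integer seed through
`numpy.random.default_rng`; a fixed seed fixes every downstream artifact.
Threshold comparisons follow the stated inequalities exactly (alternate
fraction strictly > 0.80 and > 0.85; quality >= 30, >= 20, >= 50; depth
>= 3; alternate depth >= 4). Multiallelic VCF records are dropped rather
than decomposed, because parent discrimination is strictly biallelic.

## What passing tests do and do not show

The generator emulates marker geometry, Poisson coverage, allele-fraction
noise and SSD genetics, but not read alignment (mapping bias, repeats,
homoeologous cross-mapping in a polyploid), structural variation between
parents, array genotyping error, crossover interference, or mismatch-repair
dynamics (subsumed into the detectability halving). Recovery results on
simulated data therefore demonstrate the internal consistency and
correctness of the calling logic at the stated densities and coverages —
not the error rates to expect on real sequencing data, where the
misalignment modes the density and conservation filters exist for are the
dominant hazard.
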