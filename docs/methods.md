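# Methods

`paranome` analyses high-identity, recently duplicated gene families —
the regime where a ~20 kbp "core duplicon" is dispersed as tens of
paralogous copies whose sequence identity approaches allelic variation,
so that mapping alone cannot tell paralogs from alleles. Every stage is
exercised against synthetic gene families with planted truth; this note
records the models, the parameters that matter, and the choices made
where the design was genuinely open.

## Synthetic gene families (`paranome.simulate`)

`simulate_family` evolves an ancestral duplicon into N paralogs by
independent substitution processes and gives each haplotype one allele
of each paralog. Divergence parameters are *pairwise* targets: each
lineage mutates at half the requested rate, so two paralogs differ at
`inter_div` (default 0.03, the few-percent identity scale of young
segmental duplications) and two alleles at `intra_div` (default 0.001,
human allelic diversity). Sequence evolution is substitution-only
outside planted VNTRs, which keeps coordinate truth exact for
breakpoint-recovery tests; real SD families also carry indels and
mosaic structure that this generator deliberately omits, so passing
tests show correctness of the algorithms under clean coordinates, not
robustness to alignment error.

Copies are embedded in unique background sequence (default 30 kbp
flanks/spacers). The background is generated once and carried as an
allele by every haplotype — it is one genomic locus, and therefore a
true copy-number-2 region usable for read-depth calibration.

`plant_events` adds copy-number gains/losses (new alleles of an existing
paralog), inversions (reverse-complement of the spanned copies plus
interior sequence; truth records the original symbol order), and
interlocus gene conversion (IGC: the acceptor interval is overwritten
with the donor paralog's sequence at the same coordinates). Overlapping
planted events are rejected so the truth stays unambiguous.

`simulate_transcripts` builds per-paralog cDNAs: a 5' UTR taken from the
paralog sequence, a coding body deterministically derived from
paralog DNA (so paralog-level substitutions propagate into transcript
differences), an optional in-frame VNTR, a stop, and a 3' UTR. Two
isoforms per paralog differ by a skipped body segment. The VNTR
alternates a 19- and a 23-residue SADD-frame unit, switches to a
25-residue MIISR-frame unit, and switches back (n1, n2, n3 unit counts),
each unit back-translated with one fixed codon per amino acid so the
genomic repeat is an exact tandem array.

`simulate_reads` emits genomic short reads (uniform starts, both
strands), short RNA-seq fragments, or full-length cDNA molecules, with
uniform substitution errors only; every read appears exactly once in the
truth table.

### Forward Wright–Fisher simulator

`simulate_sweep` is a discrete, haploid Wright–Fisher population of N
recombining haplotypes with infinite-sites mutation. Defaults N = 200,
mu = rho = 1e-6 per bp per generation are human-like rates (~1e-8)
rescaled by the same factor as the population size, so N·mu and N·rho
stay realistic; burn-in is 10N generations. With s > 0 a favored allele
enters one haplotype after burn-in, fitness is multiplicative (1 + s per
carrier), runs that lose the allele restart from the burn-in state, and
haplotypes are sampled when the allele first reaches
`sample_at_freq` (default 0.80) — an ongoing sweep, since
haplotype-length statistics need both allele pools present. Neutral
calibration: per-bp diversity matches the 2N·mu coalescent expectation
within Monte Carlo error, and per-replicate whole-region Tajima's D is
within 3 SE of 0 over 50 replicates. Windowed (30 kbp) Tajima's D runs
mildly negative (≈ −0.09) under these conditions; a matched msprime
coalescent gives the same sign (≈ −0.05). This is the expected
small-sample behavior of discrete Wright–Fisher genealogies when
n²/N ≈ 8, not a defect, and both statistics are reported.

## Locus discovery (`paranome.loci`)

The internal mapper indexes 48-mers of the query locus, collects exact
matches in the assembly on both strands, chains them collinearly with
gaps up to 5 kbp, and seeds a copy from any chain covering ≥ 60% of the
query, extended to query-projected bounds. At a few percent divergence
roughly a quarter of 48-mers survive intact, which anchors planted
copies to within ±50 bp. Externally supplied PAF hits and internal hits
are pooled and union-merged (≥ 1 bp overlap), with strand from the
majority of merged block length — mirroring the union of two independent
aligners. Validation requires 30 kbp of flanking sequence inside the
contig and no overlap of copy ± flank with unreliable-assembly mask
intervals; failures are recorded states, not errors.

## Paralog assignment (`paranome.classify`)

Copies are named by supported monophyletic clades around anchor leaves
(reference copies with known paralog names). The tree is consumed as
Newick with branch supports; the hermetic fallback is neighbor joining
on p-distances (columns with > 50% gaps dropped — a stand-in for the
manual alignment trimming the problem usually receives). Rooting uses a
designated outgroup, kept in the tree so the ingroup clade's support
survives rerooting. Missing supports are trusted.

Naming walks the rooted tree: the smallest supported clade containing a
copy and at least one anchor gives the name; several anchor names with
no supported split separating them give the merged "X/Y" name
(conservative grouping: with equal-support nestings the more inclusive
clade wins). A supported anchor-free clade of ≥ 2 copies whose patristic
distance to every anchor exceeds a paralog-level threshold becomes a
novel paralog, named after its nearest anchor with an "L" ordinal. The
threshold defaults to max(4 × the 25th percentile of copy-to-nearest-
anchor distances, 0.25 × the smallest inter-anchor distance): allele
noise sits well below it, paralog-level divergence well above, for
inter/intra ratios ≥ 5. Copies hanging directly at an unsupported root
are "unassigned".

Copy-number heterozygosity of a paralog is the fraction of samples whose
two haplotypes carry discordant integer copy numbers, over samples with
both haplotypes validated.

## Read-depth copy number (`paranome.depth`)

Reads are split into non-overlapping 36 bp segments; a segment counts at
every reference position matching with ≤ 2 substitutions (12-mer seed
index, pigeonhole-complete for 2 mismatches, Hamming verification, both
strands). Window depth is counted over positions that can host a full
segment start (the last 35 bp of a contig cannot — ignoring this
deflates terminal windows by ~3.5%). `cn = 2 × depth / calibration`
against known CN=2 regions; the calibration region should be large
(tens of kbp at least): at 30× coverage a 16 kbp region's ±1% depth
noise alone moves a CN≈48 estimate by ±0.5 copies. Windows overlapping
the coding VNTR are excluded from estimation. No GC correction is
applied (extension point). Group comparisons use the two-sided
Mann–Whitney rank-sum test.

## Structural configurations and DCJ-indel distance (`paranome.rearrange`)

A locus configuration is the coordinate-ordered, oriented list of family
paralogs and named marker genes. The distance between two linear
configurations is the minimum number of DCJ operations (circular
intermediates allowed) plus insertions/deletions of contiguous blocks
transforming one into the other. It is computed on the adjacency graph
over shared markers: d_DCJ = n − c − |AB-paths|/2, plus run-based indel
accounting — each component's alternating runs of genome-unique content
cost ceil((Λ+1)/2) indels — plus an exact correction for the single
possible AA/BB path recombination (two linear chromosomes have exactly
two paths), minimized over every split of the two run words.

Duplicate marker names (multiplicity ≤ 2) are resolved by minimizing
over *all* partial injective matchings, not just maximal bijections:
the scenario minimum may delete a shared marker and reinsert it, and
restricting to maximal matchings breaks the triangle inequality. The
resulting distance is a true metric and agrees exactly with an
exhaustive breadth-first-search oracle on hundreds of random ≤ 6-marker
instances. Configurations seen in fewer than two haplotypes are dropped
before tree building (detectability rule); trees are neighbor joining on
the pairwise distance matrix, midpoint-rooted. Inversion calls are
maximal runs of shared markers in reversed order with flipped
orientation; a configuration's inversion allele frequency counts
haplotypes whose configuration yields at least one call against the
reference.

## IGC scanning (`paranome.igc`)

A nearest-consensus scan: 1 kbp windows sliding by 100 bp along a copy,
flagged with donor P when the Hamming distance to P's consensus beats
the distance to the copy's own consensus by ≥ 3 diagnostic sites
(windows > 20% gaps skipped). Adjacent same-donor windows merge into
tracts (union bounds), summarized as a donor × acceptor matrix and an
acceptor hotspot ranking. At 3% inter-paralog divergence a planted
≥ 2 kbp tract carries ~60 diagnostic sites while allelic noise
contributes ~1 per window, so planted tracts are recovered with
precision and recall ≥ 0.9 and breakpoints within one window; IGC-free
copies produce no flags across seeds. This scan is a detection stand-in:
its parameters are operational choices, and it assumes the copy shares
the consensus coordinate frame (substitution-only alignment).

## Selection statistics (`paranome.selection`)

Tajima's D follows the 1989 constants exactly (verified against an
independent exact-rational implementation to 1e-12). nSL measures, for
each site and each haplotype pair agreeing there, the run of consecutive
sites over which the pair is identical (SNP units, truncated at region
edges, focal site included); raw = ln(SL_ancestral / SL_derived) with
the ancestral allele taken as REF (polarity assumption — the scans this
mirrors run without ancestral annotation). Sites with an allele pool
< 2 are skipped. Standardization subtracts the mean and divides the SD
within 100 equal-width derived-allele-frequency bins; bin statistics can
be fitted on a reference cohort (e.g. pooled neutral simulations, or a
genome-scale callset) and applied to a target — without this, a local
sweep's hitchhikers dominate their frequency bins and normalize
themselves away.

Windows (default non-overlapping 30 kbp; the step is a first-class
parameter because published window counts imply much denser tilings)
report S, pi, D, max |standardized nSL| and the fraction of scores
beyond ±2 (the scan tool's exact window statistic is not published, so
both are kept). Windows under `min_snps` = 10 SNPs are dropped;
percentile ranks use the midrank convention, so an x% tail flags ~x% of
uniform windows; a second ranking excludes mask-overlapping windows
(IGC-exclusion reanalysis); target overlap requires ≥ 5 kbp.

### Power at desk scale

`paranome.experiments.sweep_power` runs matched sweep/neutral replicate
sets (defaults: 50 + 50, N = 200, L = 300 kbp, n = 40 haplotypes — the
size of a 20-sample phased panel), normalizes nSL against the pooled
neutral background, and asks whether the sweep-site window's max |nSL|
reaches the top 1% of the pooled neutral window distribution. The
matched-neutral flag rate calibrates at ~1% as it must. Detection power
at s = 0.05 is low (~10–25%): with the forward simulator's population
sizes (N ≤ 500), s = 0.05 means 2Ns ≤ 50, below the regime where
extended-haplotype statistics have power. The pipeline itself is not the
limit: at s = 1.0 (2Ns = 1000, the per-generation intensity a
human-scale sweep of s = 0.05 implies) the same procedure detects 8/8
sweep windows far above the neutral 99th percentile. Power claims from
these synthetic runs therefore transfer to real data only through the
scaled strength 2Ns, not through s alone.

## Iso-seq models and VNTR profiling (`paranome.isoforms`)

Reads are assigned by the mismatch-delta rule: unique iff the best copy
beats the second best by ≥ 1 mismatch (mismatch counts from global
edit-distance alignment against each paralog's transcript set — a
stand-in for spliced alignment on synthetic data). Mono-exonic reads
never contribute to models. ORFs are the longest ATG-initiated,
stop-terminated forward-strand frames, ≥ 50 codons (the shortest real
isoform reported for this family is 155 aa; the floor suppresses
spurious short frames), ties to the 5'-most; the start class is the
first four residues against {MFCC, MVKL, MRVR, MRLR}. Isoform models
need ≥ 5 supporting molecules, are ranked per paralog by abundance
(`_1.._k`), and the longest retained model is flagged alongside the most
abundant.

VNTR profiling counts SADD-frame units (occurrences of "SADD") and
MIISR-frame units (occurrences of "ISR" outside SADD units), segmented
into the n1 → n2 → n3 alternation (extra alternation segments set an
overflow flag). Unit lengths fall out of anchor spacings (19 and 23
residues for the two printed SADD forms). The genomic repeat length is
a motif-seeded tandem scan: consecutive occurrences of a 20-mer spaced
40–300 bp apart cover repeat intervals, merged across seeds and frames;
on planted arrays the recovered length matches the planted length
exactly, and is guaranteed within one alternation period.

## Unique k-mer expression (`paranome.kmers`)

The catalog holds canonical (strand-folded) 31-mers of the gene models
absent from the rest of the genome (model loci are not background).
"Uniquely identifying k-mer positions" are counted as model positions
where a group-private k-mer starts. Paralogs merge iteratively until
every group has ≥ 5 such positions, each deficient group joining the
group it shares most catalog k-mers with (ties lexicographic; the
partition is input-order invariant, group uniqueness is monotone under
merging, and ≤ #paralogs − 1 merges can occur). Reads are classified by
exclusivity: assigned to a group only when they contain that group's
private k-mers and no other group's (the strictest rule — zero false
assignment on clean reads); otherwise ambiguous, unresolved (family
k-mers only), or non-family. Counts are conserved across the four
classes. Tissue enrichment is Z = (group proportion in tissue − mean
across tissues) / SD across tissues, with one-sided permutation
p-values from shuffling tissue labels over samples (single-sample
tissues flagged unreliable).

## Known limitations

* Substitution-only sequence evolution; no indels, no SV breakpoint
  microhomology, no sequencing-error profiles beyond uniform mismatch.
* The IGC scan and the p-distance trimming rule are operational
  stand-ins, not reconstructions of any published caller.
* The DCJ-indel matching model is exact only for name multiplicity ≤ 2.
* Forward-time simulation caps the achievable 2Ns at desk scale;
  haplotype-statistic power at small nominal s is correspondingly low.
* Read-depth CN has no GC correction and assumes calibration regions
  large enough that their depth noise is negligible.
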