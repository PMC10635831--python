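# Methods

`metasgb` re-implements, at desk scale, a marker-gene approach to
metagenomic taxonomic and strain-level profiling built on species-level
genome bins (SGBs).  This note documents the models, the parameters that
matter, the synthetic data the package is validated on, and the numerical
choices made where the design was genuinely open.

## Genome bins

Genomes (isolate references and metagenome-assembled genomes, MAGs) are
organised purely by whole-genome genetic distance: average-linkage
hierarchical clustering of all-versus-all MinHash distances, with the
dendrogram cut at 5% (SGB), 15% (genus-level, GGB) and 30% (family-level,
FGB).  A bin containing at least one isolate reference is *known* (kSGB);
MAG-only bins are *unknown* (uSGB) and are retained for profiling only when
they contain at least five MAGs.  Quality control consumes externally
supplied completeness/contamination values (genomes below 50% completeness
or above 5% contamination are removed; the boundary values are kept) and
near-identical genomes (distance ≤ 10⁻⁴, i.e. 99.99% identity) are
dereplicated to the highest-quality member, with quality scored as
`completeness − 5 × contamination` (the CheckM-community convention; ties
break on genome id).

The MinHash distance is `d = min(1, −ln(2J/(1+J))/k)` with `J` the Jaccard
estimate from the `s` smallest hashes of the merged bottom-`s` sketches of
canonical `k`-mers; `J = 0` maps to the cap at 1.  Defaults are `k = 21`,
`s = 1000`.  The benchmark pipeline passes `s = 2000`: desk-scale genomes
(~150–200 kb) share only on the order of a hundred 21-mers at family-level
divergence, and at `s = 1000` the Jaccard estimate near the 30% cutoff would
be dominated by sampling noise.  With `s = 2000` the realised distance bands
(~0.03 within SGBs, ~0.11–0.14 between SGBs of a genus, ~0.19–0.26 between
genera of a family) sit well clear of all three cutoffs.

Taxonomy is assigned per SGB by a majority rule over the member reference
genomes (ties resolve to the alphabetically first label); uSGBs inherit a
genus-level majority label from their GGB, failing that a family-level label
from their FGB, failing that the majority phylum among the closest reference
plus up to 100 references within 5% of that closest distance.  Unlabeled
ranks carry bin-derived placeholders (`f__FGBn`, `g__GGBn`, `s__SGBn`, …) so
every clade keeps a full lineage.

## Marker database

Per SGB, member genes are clustered greedily into families at the amino-acid
level: genes (longest first) join the first centroid they match at >90%
identity over >80% of the centroid length (edlib semi-global alignment);
otherwise they found a new family whose nucleotide sequence becomes the
representative.  *Coreness* is the family's prevalence among the
quality-ranked genomes of the SGB (up to 2,000).  The core set uses the
largest integer-percent coreness threshold yielding ≥800 core genes of
length 450–4,500 nt, bounded below at 60% (SGBs under 100 genomes) or 50%;
when no threshold reaches 800 the bound is used, and SGBs whose core set
stays under 200 genes are discarded.

Core genes are split into non-overlapping 150-nt fragments (a final window
shorter than 150 nt is kept when ≥75 nt) and screened against up to the 100
highest-quality genomes of every other SGB.  A fragment maps when an exact
31-mer seed extends ungapped to ≥90% identity over the fragment — a
declared, configurable stand-in for a sensitive short-read aligner — and a
mapped fragment marks its gene as hitting that genome.  Genes hitting no
external genome are unique markers; genes hitting under 1% of every external
SGB's screened subset are quasi-markers (with the sharing SGBs recorded).
Since 1% of a ≤100-genome subset is less than one genome and the fraction
comparison is strict, quasi-markers can only arise against SGBs screened
with more than 100 genomes.  A gene must also hit at least its SGB's
coreness-threshold fraction of its own genomes.

SGBs producing fewer than 100 markers enter a rescue: (1) external SGBs
conflicting on more than 200 core genes and holding under 10% of the
target's genome count are iteratively discarded (rolled back if 100 markers
are not reached); (2) the same loop restricted to externals whose species
label matches the low-quality-name patterns (Candidatus, `_sp`, `bacterium`,
… — placeholder labels of uncharacterised SGBs are treated as low-quality
too), goal ten markers; (3) SGBs still short are merged along the heaviest
edges of the >200-conflicting-genes graph until their group reaches ten
markers.  Finally at most 200 markers are kept per SGB — unique before
quasi, longer first — and SGBs still under ten markers are dropped.  The
database serialises to a JSON metadata file (per marker: owner, external
SGBs, length, taxonomy; per SGB: average genome length, reference/MAG
counts) plus a FASTA of marker sequences, and the build is deterministic:
identical inputs give byte-identical files.

## Profiling

Reads are aligned to markers by the same seed-and-extend contract (dense
31-mer seed offsets every 6 positions, both strands, best hit per read,
≥90% identity over the read).  MAPQ is a surrogate: 60 for a single best
marker, 0 for a tie, otherwise ten times the score gap, capped at 60.  SAM
from an external aligner and a two-column read→marker mapping are accepted
as alternative inputs.  Alignments from reads shorter than 70 nt or with
MAPQ < 5 are discarded.

Marker depth is summed aligned length over marker length.  The clade
coverage of an SGB is the robust average of its *full* marker-depth vector
(undetected markers contribute zeros): the vector is sorted and
`floor(stat_q·n)` entries are removed from each end (`stat_q = 0.2`;
vectors shorter than 3 take the plain mean).  Quasi-markers are excluded
from the vector when any of their external SGBs has ≥33% of its own markers
present (`perc_nonzero`).  An SGB is reported when at least 20% of its
markers attract reads (inclusive) and its coverage is positive; relative
abundance is its coverage over the summed coverage of detected SGBs, and
internal ranks (genus … kingdom, with GGB/FGB placeholders) receive the sum
of their descendants.  Including zero-depth markers in the truncated vector
is an explicit choice (the original tool's behaviour is not documented);
it is consistent with detection by marker fraction and is isolated behind
the function boundary.

The unclassified fraction is estimated as

    unclassified = (N − Σ_sp cov_sp · L_sp / ℓ) / N

over reported SGBs, where `cov_sp` is the mean depth of the SGB's detected
(non-zero) markers, `L_sp` its average genome length (reference genomes
only for kSGBs; the stored MAG average inflated by 7% for uSGBs, reflecting
the typical MAG size deficit), `ℓ` the average read length and `N` the
total input reads; the value is clamped to [0, 1] and clade abundances are
rescaled to sum to its complement.

Because the internal aligner requires the full read inside the marker,
depth underestimates true genome coverage by roughly `(L_m − ℓ)/L_m` per
marker.  The factor is nearly constant across SGBs (marker length
distributions are similar), so it cancels in the within-sample
normalisation; it does bias the unclassified estimate slightly upward.

## Strain genotyping

Per sample and marker, the dominant-strain consensus takes each position's
majority base; positions with no reads, mean base quality under 30
(aggregated per position — the alternative per-read reading of the quality
rule is not used) or major-allele dominance under 80% become gaps.  Markers
covered by fewer than eight reads or with breadth under 80% are rejected.
Samples holding under 80% of the available markers are dropped first, then
markers present in under 80% of the remaining samples; retained consensuses
lose 50 nt from each end.  The polymorphic rate — covered positions whose
major allele holds <80% of reads, over covered positions — is a
within-sample strain-heterogeneity signal.

Consensuses are concatenated in fixed marker order into a
coordinate-anchored alignment: columns are homologous by construction
because every consensus is called against the same marker reference, so no
de novo multiple alignment is needed; insertions relative to the marker are
ignored (the price of forgoing an aligner's indel handling).  Columns with
more than 67% gaps are trimmed.  Pairwise distance is mismatches over
shared non-gap columns, and a neighbour-joining tree (negative branch
lengths clamped to zero) replaces likelihood inference; an externally
computed Newick tree is accepted to reproduce a full MSA+ML pipeline when
desired.  Sample distances are tree path lengths normalised by the total
branch length, and a pair of related samples shares a strain when its
normalised distance is at or below a caller-supplied, species-specific
cutoff (the cutoffs are data products of longitudinal surveys, consumed as
parameters).

## Synthetic data

The generator emulates a genome catalog with known structure.  Each FGB
ancestor carries a pool of "universal" genes; each GGB and SGB gains
private genes; genomes descend from their SGB ancestor by per-base
substitution, with nonsense mutations reverted (a CDS-preserving stand-in
for purifying selection).  Defaults: 5 FGBs × 2 GGBs × 3 SGBs (30 SGBs), 5
genomes per SGB (150 genomes), half the SGBs MAG-only with 5 MAGs each;
170 universal + 20 GGB-private + 60 SGB-private core genes and 8 accessory
genes per genome; gene lengths log-normal clipped to 450–1,800 nt (genomes
≈ 170–200 kb); substitution rates 1.5% (strain), 4% (SGB), 5% (GGB),
placing pairwise divergences inside the required bands (<5% within SGBs,
5–15% within GGBs, 15–30% within FGBs).  Communities draw one genome per
SGB with log-normal abundances (μ = 0, σ = 1 — the shape is standard for
microbial communities; the scale is not critical as abundances are
normalised), and 200,000 150-nt single-end reads per sample proportional
to abundance × genome length, with uniform substitution errors at 0.5%.
The error model is substitution-only and quality values are constant — no
quality-profile realism, indels, or host contamination — so passing
benchmarks demonstrate the correctness and calibration of the pipeline's
logic on in-model data, not robustness to platform-specific artefacts.

SGB-private genes are what make unique markers possible at this scale:
universal genes are screened out through their cross-SGB homologs, and the
survivors (~60 markers per SGB) are the private complement plus the
occasional homolog whose fragments all fall below 90% identity everywhere
else.  Because the screen shares the aligner's contract, such borderline
markers attract essentially no foreign reads at profiling time.

## Benchmark protocol and problem sizes

The evaluation harness scores detection with set-based TP/FP/FN at the SGB
level (a predicted SGB containing — or overlapping, via an explicit map — a
community genome is a true positive) and quantification with Bray-Curtis
dissimilarity (Σ|p−g| / Σ(p+g)) and RMSE over the union of SGBs, both
profiles normalised to 1.  The packaged protocol builds a ~30-SGB catalog,
constructs its database and profiles five communities per condition (all
SGBs; MAG-only bins; reference-containing bins; holdout strains generated
at 1% substitution from each SGB centroid and excluded from the build), plus
a single-isolate coverage sweep from 0.01× to 100×.  These sizes keep a
full end-to-end run in minutes on one CPU while leaving every algorithmic
path exercised; they are the package's chosen study conditions, scaled down
from catalog sizes that would require cluster hardware.

## Known limitations

- The internal seed-and-extend aligner is ungapped; indel-bearing reads and
  genes are outside its contract (real data would use the SAM input path).
- Gene-family clustering assumes frame-1 CDS input (the generator
  guarantees this); genes with internal stops or excess ambiguity are
  skipped with a warning rather than frame-corrected.
- Quasi-marker behaviour only manifests with external SGBs screened at
  >100 genomes; the synthetic benchmark therefore exercises it through
  constructed unit fixtures, not end-to-end.
- NJ on p-distances underestimates long branches relative to
  likelihood methods; distances are used comparatively (normalised within a
  tree), where rank order is what matters.
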