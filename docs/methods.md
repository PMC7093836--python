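# Methods

## Quantification model

Reads are assigned to satDNA families by Smith–Waterman local alignment
against each family's dimer reference (two concatenated copies of the
consensus monomer), scored +2 per match, −3 per mismatch and −5 per gap
base (linear gaps). The dimer guarantees that a fragment spanning the
monomer junction aligns as one contiguous block. Each read is scored
against every family on both strands and contributes one fragment to the
single best family (ties break to the alphabetically first family id,
then the forward strand), so every masked nucleotide is counted exactly
once. Fragments scoring below 40 (about 20 matched bases) or shorter than
20 nt are "no hit". `N` bases score 0 in the aligner and are excluded
from all site counts, matching the pairwise-deletion convention used for
distances.

Abundance is the masked fraction of library nucleotides, in percent.
Copy number is `abundance × genome_size / monomer_size`, rounded; genome
size is a required user input because shotgun data alone cannot supply
it. Intraspecific divergence is the alignment-length-weighted mean of the
fragments' K2P distances — weighting by nucleotides rather than fragments
keeps the summary consistent with the landscape, which apportions
nucleotides. The repeat landscape bins each fragment's aligned length by
its K2P percent into `[0,w), [w,2w), …` bins (default width 1%), so the
bin sum equals the abundance by construction. Fragments whose observed
divergence saturates the K2P correction (`1−2P−Q ≤ 0` or `1−2Q ≤ 0`) are
discarded and counted in a log message rather than capped: capping would
silently pile unalignable noise into the highest bin.

K2P is used instead of the raw p-distance because transitions outnumber
transversions in satDNA and multiple hits accumulate quickly at the
divergences involved (10–30%); the correction is always at least the
observed difference proportion. No CpG or composition adjustment is
applied.

## Tandem repeat detection

Candidate monomer periods come from spacings between repeated 7-mers in
the sequence; each candidate period `d` defines regions where
`s[i] == s[i+d]` holds densely (runs bridged across up to `d` mismatched
positions). A provisional consensus is the per-column majority base
(position mod `d`, ties alphabetical); region bounds are trimmed to the
maximum-scoring subarray of the per-position +2/−3 scan, and the region
is validated by wraparound dynamic programming against the cyclic
consensus under the 2/3/5 weights with a minimum reported score of 50.
Overlapping reports are merged keeping the higher score, and among
overlapping candidates within 95% of the best score the smallest period
wins, preferring the primitive monomer over its multiples. The
probabilistic detection phase of classic tandem-repeat finders is
deliberately replaced by this deterministic k-mer + DP procedure; only
the weights and the score threshold carry over, so a perfect array of
length L scores exactly 2L and each substitution costs exactly 5. The
self-dotplot utility reports all window pairs above an identity cutoff by
diagonal offset; the dominant off-diagonal offset estimates monomer size
independently of the detector.

## Consensus derivation

Species-level consensuses are built center-star: the longest monomer is
the center, every other monomer is locally aligned to it with the same
scoring, bases are projected onto center columns (insertions relative to
the center are dropped), and each column takes its majority base (ties
alphabetical; columns gapped in more than half the monomers are
removed). Because independently derived consensuses may differ at their
ends, consensus-to-consensus distances are computed after a local
alignment of each pair rather than by naive truncation.

## Cross-species statistics

All summary statistics use the sample (n−1) standard deviation — the
population form does not reproduce the reference survey's printed SD/CV
values. Z-scores standardize each species against the included species'
mean and SD; excluded species (normally the outgroup) still receive
scores against that baseline, which is what flags an outgroup
amplification relative to the ingroup average, under the assumption that
the ingroup mean approximates the ancestral library state. Reported
tables round half-up at the printed precision (abundance and K2P to two
decimals).

The clade consistency test pools all unordered ingroup species pairs into
within- and between-clade distance sets and applies a pooled-variance
Student t with `df = pairs − 2` (nine species in clades of 2/2/2/3 give
6 + 30 pairs, df = 34). The statistic is `(mean_between − mean_within)/SE`
so that positive t means phylogenetically consistent change. The pairs
are not independent (m species yield m(m−1)/2 pairs); the test reproduces
the conventional procedure for this design and should be read as
descriptive, not strictly calibrated. Spearman correlation assigns
mid-ranks to ties and tests `t = ρ√(n−2)/√(1−ρ²)` against a t
distribution. Substitution rates divide the consensus p-distance to the
outgroup by twice the time since the radiation (both lineages evolve for
T Myr). No multiple-testing correction is applied anywhere.

Neighbor joining is implemented directly so that negative branch lengths
can be clamped to zero with the deficit transferred to the sibling branch
(preserving the joined pair's summed length); maximum-likelihood tree
inference and bootstrap are out of scope, and clade claims are tested as
monophyly properties on the NJ tree rooted on the outgroup.

## The simulator

`simulate_library_evolution` evolves per-family monomer arrays down a
dated tree. Per copy, point mutations are Poisson with rate
`mu × monomer_length × Δt` (default mu = 0.015 substitutions/site/Myr,
chosen so that fragment divergences and per-lineage rates land in the
1–2 %/Myr range reported for satDNA); mutated sites change to a uniformly
chosen different base. Amplification events replicate a randomly chosen
contiguous window of copies (inserted adjacently, approximating unequal
crossing over) until the copy count has grown by the given factor; the
new copies are exact duplicates at event time, which is the entire model
of homogenization — there is no continuous gene-conversion process.
Single-copy windows make the duplicated variant the array majority, so
the species consensus jumps to it and intraspecific divergence drops:
recent amplifications therefore produce the zs-abun > 0 / zs-div < 0
signature and a landscape mode in the lowest bin, while old arrays drift
to a mode near `mu × tree depth`. Contraction removes a uniformly chosen
fraction of copies. Indels are not simulated (monomer length is fixed);
real monomer-size variation in the reference survey is under a few
percent, so substitution-only is a stated simplification. Events address
branches by the label of the branch's child node, with event times given
as ages (Ma) inside the branch's span.

`emit_genome_and_reads` concatenates each family's copies into one
tandem block, inserts the blocks at random positions of a seeded random
background, and draws `round(coverage × genome/read_length)` fixed-length
reads uniformly from either strand. What this does **not** emulate:
sequencing error, quality variation, paired ends, GC bias, multiple loci
per family, and satellite fractions are far larger than in real genomes
because the background is scaled to tens–hundreds of kilobases so the
full loop runs in about a minute per design. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to platform artifacts.

The default ten-species design mirrors the study system the statistics
are calibrated on: an outgroup splitting 7.9 Ma, four ingroup clades
(sizes 2/2/2/3, node ages 5.0/4.0/2.5/2.0/1.5 Ma), three families of
170/350/170 bp at ~57% A+T, recent outgroup amplifications of two
families, a shared clade-1 amplification, clade-stem amplifications of
the third family in all four clades, and contractions in clades 3–4.

## Numerical choices and degenerate inputs

* Round-half-up at printed precision for all reported tables.
* Ties: alphabetical base in consensus columns; alphabetically first
  family id and forward strand in masking; smallest period within 95% of
  the best score in tandem detection.
* Pooled t with zero pooled variance returns t = 0 (equal means) or ±inf
  (complete separation) rather than an indeterminate float ratio.
* Spearman with |ρ| = 1 reports p = 0 with an infinite t.
* Zero comparable sites (all gaps/N) raises instead of returning 0.
* Subsampling uses a seeded generator and returns records in file order.
* Seeds derived internally stay below 2³¹.

## Known limitations

Single best-family assignment per read slightly biases abundance when
families are similar (not the case for the bundled or simulated
references). Local alignment trims divergent fragment ends, giving a
small (~1–3%) systematic underestimate of abundance at high divergence.
The simulator's homogenization-by-duplication cannot produce gradual
concerted evolution between events, so intraspecific divergence is
bimodal right after a burst rather than unimodal as continuous gene
conversion would make it. Consensus distances assume colinear monomers
(no rotation handling); rotated assemblies should be normalized upstream.
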