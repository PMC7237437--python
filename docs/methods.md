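# Methods

`smithrna` implements a discovery-and-validation workflow for smithRNAs —
small mitochondrially encoded RNAs proposed to regulate nuclear transcripts —
together with the population-genetic conservation analysis of their encoding
loci and the nonparametric statistics used for downstream assay tables.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic data do and do not establish.

## Candidate discovery

Small-RNA reads are mapped to the circular mitogenome by an exhaustive
full-length, ungapped scan of both strands, tolerating at most
`max_mismatch` mismatches (default 1). The scan is wrap-aware: a read may
span the origin, in which case its alignment is recorded with `end < start`.
Unlike a seeded heuristic aligner, the exhaustive scan is exact — it reports
every locus attaining the minimum mismatch count — and is entirely feasible
at mitogenome scale (~16 kb). Reads with an equally good hit to an optional
nuclear decoy set are discarded before clustering, emulating the standard
screen against nuclear copies of mitochondrial sequence (NUMTs).

Retained reads are clustered greedily per strand in order of decreasing
abundance at identity 0.99; for sequences shorter than 100 nt this means
exact sequence identity, so a cluster is effectively a read pileup with a
well-defined centroid (its most abundant sequence). Two requirements gate a
cluster:

1. **size** — strictly more than `min_cluster_size` reads (default 200;
   the relaxed reanalysis threshold of 50 is a config change away);
2. **end sharpness** — the fraction of member reads sharing the modal 5′
   end and the fraction sharing the modal 3′ end must both reach
   `min_frac5`/`min_frac3`. The published procedure required "sharp"
   coverage without quantifying it; we operationalize sharpness as these
   modal-end fractions with defaults 0.75/0.75, and always report the raw
   fractions so users can re-threshold.

## Target prediction

A surviving centroid is evaluated against every 3′ UTR through four gates:

3. **seed** — the reverse complement of centroid nucleotides 4–10 (the
   shifted seed reported for mitochondrial small RNAs, rather than the
   canonical miRNA 2–7 seed) must occur verbatim in the UTR. Seed matching
   is Watson–Crick only; wobble pairs are not accepted in the seed.
4. **total complementarity** — the best gapless local alignment between the
   centroid and the reverse complement of the UTR window around the site
   (window: centroid length + 30 nt each side), scored +1/−3 as in
   short-query BLAST searches, must cover at least `min_matches` (11)
   matched positions. Only alignments whose matched segment contains the
   seed site are considered, so the match count and the seed refer to the
   same interaction.
5. **accessibility** — ΔΔG = ΔG_duplex + ΔG_open must be below −9, where
   ΔG_open is the cost of opening the target site (site plus 3 nt of 5′
   flank and 15 nt of 3′ flank) out of the local secondary structure of a
   140-nt window centered on the site.
6. **duplex stability** — the nearest-neighbor duplex energy with centroid
   positions 3–10 forced to pair must be below −20.

Thresholds 11 / −9 / −20 are strict inequalities, applied on the energy
model's native kcal/mol scale; the unit label is configurable metadata.
The "matching" of requirement 3–4 is base-pairing complementarity (target
logic), not sequence identity.

### Energy model

Duplex energies are nearest-neighbor sums: one helix-initiation term
(+4.09) plus stack terms over adjacent paired columns of a gapless,
bulge-free antiparallel duplex. Watson–Crick stacks carry standard
Turner-style 37 °C parameters (−0.93 … −3.42 kcal/mol). G:U wobble pairs
are allowed outside the seed, with deliberately conservative stack values
(−0.60 for a stack containing one wobble, −0.25 for tandem wobbles), chosen
weaker than any Watson–Crick stack so that the model is strictly monotone:
disrupting any pair of a perfect-complement duplex always raises the
energy. The recorded folding temperature (25 °C) is metadata; the
simplified table is temperature-fixed.

Single-sequence folding (for ΔG_open and the illustrative pre-region
structures) is a dynamic program over nested structures scored by the same
stack table plus one initiation penalty per helix and a minimum hairpin
loop of 3 nt — a single-structure minimum-free-energy approximation, not an
ensemble partition function. The helix penalty stands in for the
destabilizing loop terms of a full loop-based model; without it every
random sequence folds into a dense tangle of one-stack helices, and the
opening cost ΔG_open is overestimated badly enough to reject genuine
perfect-complement target sites. ΔG_open is computed as (MFE with the site
constrained unpaired) − (unconstrained MFE) and is non-negative by
construction. Parity with PITA/RNAhybrid output is not claimed; the gates
reproduce their roles, not their numbers.

## Naming and pre-regions

Candidates are named `<species>_<sex>_smithRNA<number><category>`: the
number is `floor(five-prime coordinate / 100)` (this reproduces the three
published names checked in the tests), and the category is decided by the
feature type at the locus midpoint — `r` (rRNA), `t` (tRNA), `nc`
(unassigned region, UR). Midpoints of origin-wrapping intervals are taken
on the unrolled arc. A candidate inside a protein-coding gene receives an
internal `cds` label; the published scheme has no printed suffix for that
case. Name collisions within a 100-bp bin get letter suffixes.

The pre-smithRNA region defaults to the 70-bp window centered on the mature
candidate (left flank `ceil((70 − len)/2)`, right flank the floor; the
window may extend into a neighboring gene, e.g. the 3′ end of an upstream
tRNA when the candidate sits at the very start of a gene). For
tRNA-category candidates the pre-region is the whole containing tRNA
extended through flanking unassigned nucleotides up to the neighboring
genes.

URs are re-annotated as the exact complement of the PCG/rRNA/tRNA features,
so after re-annotation every genomic position belongs to exactly one base
feature (smithRNA/pre_smithRNA features are overlays and never mask URs).

## Conservation analysis

Nucleotide diversity per window is

    pi_hat = N/(N−1) · Σ_i Σ_{j>i} p_i p_j π_ij

with N sequences, haplotype frequencies p_i and uncorrected p-distances
π_ij. The sum runs over unordered haplotype pairs, exactly as the estimator
is printed in the source analysis; the conventional (Nei) estimator is
twice this, available via `ordered_pairs=True`. Rank-based tests are
invariant to the constant factor, so the choice does not affect any test
conclusion. Gap handling is pairwise deletion (complete deletion by flag).
Windows are 10 bp with 5-bp steps by default; zero-diversity windows are
kept. Each window is labeled by the region type at its midpoint with
precedence smithRNA > pre_smithRNA > tRNA > rRNA > PCG > UR.

Group differences are tested with a tie-corrected Kruskal–Wallis test
(χ² reference, k−1 df), followed by two-tailed Dunn's post hoc tests on the
joint ranks with Bonferroni correction over all k(k−1)/2 pairs. One-tailed
Mann–Whitney tests (exact enumeration for n_x·n_y ≤ 400 and tie-free data,
otherwise a tie- and continuity-corrected normal approximation; W is the U
of the first sample, the R convention) serve the two-group assay
comparisons. All three are implemented from their rank formulas; scipy
provides only the χ²/normal distributions, and the installed scipy
implementations act as independent oracles in the test suite.

## Synthetic data

The generators produce every input the pipeline consumes, plus ground
truth:

* **Genome**: ~16-kb circular genome, 13 PCG + 2 rRNA + 22 tRNA features on
  both strands; inter-gene slack is split by a Dirichlet-multinomial
  (concentration 0.5), giving a few large and many tiny URs, the pattern
  typical of bivalve mtDNAs.
* **Reads**: per planted locus, `depth` reads with ends jittered ±1 nt with
  probability `end_noise` (0 by default: perfectly sharp pileups, the
  idealized transcription pattern the sharpness filter looks for), plus
  uniform background reads (15–40 nt, both strands). Default library sizes
  follow the study conditions the filters encode: depth 250 clears the
  size > 200 gate, depth 150 does not.
* **UTRome**: random UTRs (~500 nt) with planted sites — `perfect` (full
  reverse complement of the centroid), `seed_only` (reverse complement of
  centroid nt 4–10 in random context), or `none`.
* **Population alignments**: per-site, per-sequence substitutions at rate
  μ · multiplier(region), Jukes–Cantor-like, no indels (the real amplicon
  alignments are essentially indel-free). The study-like contrast uses
  μ = 0.005, 40 sequences, multiplier 5 for URs and 1 elsewhere.
* **Assay tables**: baseline + group shift + sex effect + Gaussian noise.

What the synthetic data do **not** model: sequencing errors and quality
variation, expression heterogeneity among loci, RNA modification or
degradation products, NUMT-derived reads with realistic divergence,
recombination or selection in the population model, and any correlation
structure between neighboring sites. Passing the recovery tests therefore
shows the pipeline's logic is correct under its own assumptions, not that
those assumptions hold for any particular real library.

## Simulation scales and inference choices

The packaged conservation simulations use a 6-kb six-region genome with six
planted smithRNA loci — large enough that each of the six region classes
contributes a usable number of windows (the mature-smithRNA class is
intrinsically small: a handful of ~22-nt loci). Descriptive window scans
use the default 10/5 sliding windows; the replicated hypothesis-testing
simulations (contrast recovery and null calibration) use non-overlapping
windows (step = size), because half-overlapping windows share 5 of 10
sites, and that within-group dependence inflates the type-I error of
rank tests that assume independent observations — a property of the
windowing, not of the tests. With non-overlapping windows the
Kruskal–Wallis null rejection rate is ~5% at α = 0.05 (recomputed by the
test suite and the acceptance script), and the UR-vs-coding contrast is
recovered in essentially every replicate.

## Numerical notes and edge cases

* Kruskal–Wallis H is defined as 0 (p = 1) when all pooled values are equal
  (the tie correction would otherwise divide by zero).
* The exact Mann–Whitney tail is computed by the standard counting
  recurrence; exact p-values with ties are refused rather than approximated
  silently.
* Sequences are normalized U→T internally; candidate outputs are re-emitted
  as RNA. `N` never matches anything during mapping.
* Fold tracebacks only add a helix when it strictly improves the energy, so
  energetically neutral lone pairs are not reported.
* `circular_subseq` and all coordinates are 1-based inclusive (GFF3
  convention); BED exports convert to 0-based half-open, splitting
  origin-wrapping features into two rows.
* Multi-mapping reads are assigned to all best-scoring loci and flagged;
  each locus cluster counts the read once.

## Known limitations

* The folding model has no multiloop/dangling-end terms and no ensemble
  averaging; ΔΔG values are comparable within this package but not to PITA
  output numerically.
* The clustering identity definition for unequal-length sequences
  (matches / longer length over the best gapless offset) only matters below
  identity 0.99; at the default it reduces to string equality.
* The nuclear screen requires decoy contigs to be provided; with none, all
  mito-mapped reads are retained (with a warning).
* Reproducing the published Kruskal–Wallis statistic for the deposited
  population amplicons requires downloading those accessions; the test that
  checks the published value runs only when the alignment has been placed
  under `data/amplicons/`.
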