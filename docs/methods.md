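# Methods

## The generative model

The simulator emulates a plant-like genome at desk scale: by default two
chromosomes of 10 Mb binned at 50 kb (200 bins each). The central 40% of
each chromosome's bins form a contiguous, centered TE-rich core in the
constitutive-heterochromatin state (`const_het`); the arms carry one gene
per bin and are active (`active`) or facultative heterochromatin
(`fac_het`, Polycomb/H3K27me3) with per-bin probability `p_fac = 0.3`.
TAD-like domains tile the core into `n_tads_per_chrom = 10` equal
intervals. The compartment truth is A for active bins and B for both
repressed flavors.

Cis contacts between bins i < j are independent Poisson counts with rate

    λ_ij = L · (j − i)^(−α) · A(s_i, s_j) · T_ij

where α = 1 is the distance-decay exponent, A is a symmetric state-affinity
lookup, and T_ij multiplies in an intra-TAD boost τ (when i and j share a
planted domain) and a 3× boost on planted anchor pairs. L is calibrated per
chromosome so the expected cis total equals `depth`. The matrix is
symmetrized with a zero diagonal. The wild-type affinities are

    homotypic a_AA = a_FF = a_CC = 1.6,
    facultative↔constitutive a_cross_rep = 0.8,
    active↔repressed a_AB = 0.5,

i.e. each chromatin flavor prefers itself, the two repressed flavors
associate more with each other than with active chromatin (so PC1 sees a
two-compartment genome) yet remain partially segregated from each other
(the facultative/constitutive separation that the mutant dissolves).

**ddm1 mode** changes the system in two mechanistic ways:

1. *State relocation.* Exactly round(`rho_relocate` × n_core) core bins
   gain H3K27me3 and lose the constitutive marks (becoming `fac_het`), and
   round(`rho_loss` × n_fac) arm facultative bins lose H3K27me3 and become
   active-like. Relocated bins are redistribution class II or III (50/50 by
   default), eroded arm bins class I. Both fractions default to 0.5; the
   genome-wide proportions are not constrained by prior knowledge and are
   stated here as model choices.
2. *Affinity mixing.* The facultative↔constitutive affinity rises to
   `a_cross_rep_mut = 1.4` (the two repressed flavors no longer exclude
   each other) and the active↔repressed affinity rises to `a_AB_mut = 0.8`,
   modelling the mutant's novel contacts between genic and TE regions.
   Raising only the cross-repressive affinity would *increase* the measured
   A/B strength (it feeds the BB saddle corner and leaves AB untouched), so
   the genic–TE mixing term is what produces the weakened
   compartmentalization; the cross-repressive term is what erases the
   H3K27me3-sorted segregation. The intra-TAD boost drops from τ = 2.0 to
   τ_mut = 1.4, weakening domain interiors and borders.

Mark and methylation tracks are per-bin base levels (by state) times
log-normal noise exp(N(0, σ)), σ = 0.3 by default. Base levels are chosen
so every log2 contrast the classifier relies on is either exactly 0 or well
beyond the ±0.5 thresholds, and so that wild-type H3K27me3 orders as
core (0.1) < genic baseline (0.3) < Polycomb (2.0) — TE cores devoid of
H3K27me3 is what makes the K27me3-sorted correlation map segregate
facultative from constitutive territory in the WT. Class III regions carry
a low H3K9me2 base in *both* genotypes ("stable but low"), which is their
defining feature relative to class II. The DE table draws class-I genes
(de-repressed Polycomb targets) from log2FC ~ N(2.5, 0.5) with small
adjusted p; all other genes from a null.

What the generator does **not** emulate: polymer/loop-extrusion physics,
trans contacts, replicate-level count noise in ChIP tracks, peak-level
structure within bins, restriction-fragment resolution, and any sequence
content. Passing tests therefore demonstrate the *analysis logic* —
normalization identities, estimator correctness against brute-force
oracles, recovery of planted structure, directions of effect under the
stated mechanism — not performance on real sequencing data.

## Analysis choices

- **Coordinates** are 0-based half-open everywhere except GFF3 on disk.
- **Balancing** is plain iterative correction to unit-mean marginals
  (tol 1e-5, ≤200 sweeps); non-convergence flags rather than fails.
- **O/E** is cis and per chromosome; by construction each diagonal of O/E
  has unmasked mean exactly 1, which the suite asserts at 1e-9.
- **PC1** comes from the Pearson map of O/E (SVD of the column-centered
  map), per chromosome, sign-fixed by correlation with H3K9ac. A
  degenerate (constant) map or an exactly zero orientation correlation is
  an error, not a silent guess.
- **Saddle**: Q = 5 PC1 quantiles, corner fraction 0.2, pairs at
  separation ≥ 2 bins, pooled over pair counts. Pentad block means use the
  same d_min = 2.
- **Insulation**: diamond of `window = 10` bins by default; the pipeline
  and experiments here use window 4 because the planted TADs are 8 bins —
  the window should be about half the expected domain size. Boundary
  prominence threshold delta = 0.2 (log2 units), minima found per
  contiguous valid run so masked gaps cannot bridge peaks.
- **Aggregate TADs** rescale by exact area-weighted block averaging (no
  interpolation), so small divisible cases are hand-checkable; WT-called
  boundaries are applied to both genotypes so the aggregates are
  position-matched.
- **Differential z-scores**: ε = 0.01 pseudocount, 8 log-spaced distance
  bands to d_max = 100 bins; within-band mean 0 / sd 1 holds by
  construction; no FDR layer — ranking by |z| is the intended readout.
- **Track scaling** defaults to genome-mean = 1. For differential calls the
  pipeline additionally median-centers the per-region deltas (the
  log-space equivalent of median-of-ratios normalization): mean scaling
  assumes total signal is conserved, which a genome-wide H3K27me3
  redistribution violates, and the median re-anchors "no change" on the
  unchanged majority. Thresholds ±0.5 log2, low-signal flag below the 25th
  percentile of pooled per-bin signal.
- **Superfamily composition** uses the standard two-proportion (pooled) z
  test per superfamily; categories absent from both sets report p = 1.

## Experiment designs used in the evaluation suite

- *Default study*: paired WT/ddm1 simulations at the defaults above,
  ten seeds; all comparative claims (strength, pentad AB, sorted-map
  segregation, insulation dip, aggregate-TAD differential) are asserted as
  directions in ≥9/10 paired seeds.
- *Sequencing depth*: 1e6 cis contacts per 10-Mb chromosome by default.
  The saddle's response to the homotypic affinity is measured in a regime
  where the PC1 ranking still mixes positions within compartments; at much
  deeper coverage the ranking locks onto a geometry-dominated order on
  this single-core layout (extreme-PC1 bins are geometry-extreme, their
  same-state pairs sit at composition-saturated separations, and ICE
  absorbs a one-core compartment signal into per-bin biases), flattening
  the corner ratio. One pericentromeric core per chromosome is the
  realistic plant layout, so the depth defines the operating regime
  rather than the layout being changed.
- *Boundary recovery* is scored on a TAD-only simulation (all affinities 1,
  τ = 2.0): in the compartmentalized genome, arm state transitions are
  genuine insulating boundaries that are not planted TAD edges, so scoring
  against the TAD truth there would conflate two real structures.
- *Differential-interaction calibration and recovery* run at 4e6 contacts
  per chromosome, with genotypes identical except for 30 planted boosted
  pairs: the log2(3) boost must exceed a few Poisson standard deviations
  of the per-pair ratio to be rankable among ~30k pairs, and under the full
  ddm1 reorganization the genome-wide differences dominate the per-band
  variance (any real redistribution *is* the signal there).
- *Classifier recovery* is scored over changed bins (planted classes
  I/II/III) at σ = 0 (exact) and σ = 0.2.

## Known limitations

- With a single centered core, ICE and O/E partially absorb compartment
  structure, so absolute strength values are compressed relative to
  multi-domain genomes; comparisons between genotypes remain valid.
- The ddm1-mode compartment labels are compared against WT-defined truth;
  mutant-side label agreement is intentionally lower because the mutant
  genuinely blurs the planted partition.
- The classifier operates on fixed bins (or user intervals), not called
  peaks; region boundaries inherit bin quantization.
- The cache key of the pipeline covers parameters and seed, not code
  version; clear the cache directory after upgrading.
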