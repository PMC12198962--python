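# Methods

This note documents the models and procedures implemented in `orthotrace`,
the choices made where the design was genuinely open, and what the synthetic
test scenarios do and do not demonstrate.

## Overview

`orthotrace` performs a profile-based targeted ortholog search that starts
from a single seed protein instead of a pre-compiled ortholog group.  The
workflow has three phases:

1. **Training** — iteratively compile a small, taxonomically diverse *core
   ortholog group* C across *primer taxa* P and train a profile HMM on its
   alignment.
2. **Search** — run the final profile against every proteome of a taxon
   collection, validate candidates with a reciprocity criterion, and select
   per-taxon representatives and co-orthologs.
3. **Profiling** — attach a bidirectional feature-architecture similarity
   (FAS) score to every ortholog and post-process the resulting phylogenetic
   profiles (filtering, binarization, 2-D embedding, contamination/HGT
   screening).

## Taxonomy model

Taxonomic distance between two species is the index, on the fixed ladder
species(0) < genus(1) < family(2) < order(3) < class(4) < phylum(5) <
kingdom(6) < superkingdom(7), of the rank of their lowest *ranked* common
ancestor.  Unranked nodes are skipped upward; ranks below species count as
species level; an unranked root with no ranked ancestor maps to the ladder
top.  The `minDist`/`maxDist` options are rank names on this ladder: the
lower bound removes every candidate whose common ancestor with the seed
species sits *at or below* that rank (the default "genus" therefore excludes
the seed's congeners), the upper bound removes candidates more distant than
its index.  After each training iteration the selected primer taxon and all
species within `minDist` of it or of the seed species leave the candidate
pool, so primer taxa are pairwise separated by more than the `minDist` rank
and the taxonomic diversity of the core group never decreases.

Pruned trees retain a reference to their source taxonomy so that distances
to already-pruned species (the seed species, earlier primer taxa) remain
defined.

## Alignment scores and distances

Pairwise global alignments use BLOSUM62 with affine gap penalties (open 10,
extend 1) — conventional defaults; the tool the package models does not
publish its scoring parameters.  The candidate score of the training phase
is

    score(c_i) = AS(c0, c_i) / AS(c0, c0) + (FAS_F + FAS_B) / 2,

where AS is the global alignment score, AS(c0, c0) the seed's self-score
(its maximal achievable score), and FAS_F/FAS_B the directional architecture
similarities (below).  The maximum is 2.

Evolutionary distances are Kimura-corrected p-distances,
d = −ln(1 − p − 0.2 p²), with p the fraction of mismatched aligned positions
(gap columns excluded).  The correction saturates at p ≈ 0.8541; saturated
distances are reported as +∞ so they lose every minimum-distance comparison.

Core groups are aligned with an internal progressive aligner: a
neighbor-joining guide tree on pairwise p-distances, then profile-profile
Needleman–Wunsch merges whose column score is the mean substitution score
over residue pairs (linear gap cost 4 per column).  The aligner is
deterministic for a fixed input order and is not intended to reproduce any
external aligner column-for-column; a hook allows substituting one.

## Profile HMM

The profile has one match/insert/delete state triplet per match column of
the training alignment, where match columns are those with at most 50% gap
characters.  Emissions are Laplace-smoothed relative frequencies (weight 1
by default; a column observing A/A/C yields P(A) = 3/23).  Transitions
receive one pseudo-observation spread according to a match-favouring prior
(M→M 0.9, M→I = M→D 0.05, and analogous insert/delete rows); a flat
transition pseudocount would tax every column of a single-sequence profile
with ~1 bit of gap-open probability and make even the training sequence
score near zero.

Scoring is local with the uniform-fragment convention: a homologous fragment
may enter at any match state and exit at any later one, each of the
L(L+1)/2 fragments carrying prior weight 2/(L(L+1)); flanking sequence and
insert states emit from the background (uniform 1/20) and cancel in the
log-odds.  Scores are reported in bits.  Both forward (sum over paths; used
for hit ranking) and Viterbi (best path) recursions are implemented as
row-vectorized dynamic programs; the in-row delete recursion is computed as
a single log-sum-exp (or max) prefix scan.  The default hit threshold is
10 bits; on 60-residue fixtures, self-hits score ~40 bits, 60%-identity
orthologs ~20 bits, and shuffled decoys ≤ ~6 bits.

## Architecture similarity (FAS)

The published FAS algorithm is specified elsewhere; `orthotrace` implements
a **documented surrogate** that preserves the published contract — the score
is asymmetric, lies in [0, 1], equals 1 for identical architectures and 0
when no reference feature type occurs in the query.  For each feature type
t of the *reference* architecture,

    s(t) = min(n_ref, n_qry) / n_ref × mean best-pair positional overlap,

where positional overlap is the Jaccard index of residue intervals after
normalizing coordinates by protein length, and the mean runs over the
min(n_ref, n_qry) best reference-instance matches.  The final score is the
weight-normalized sum over reference types (per-namespace weights, default
1).  Summing over reference types only is what makes the score directional:
FAS_F uses the seed, FAS_B the ortholog as reference.  Under length
normalization a domain that is, say, quadruplicated on a five-fold longer
ortholog yields FAS_F > FAS_B with FAS_B well below 1 — the qualitative
direction of the published examples — but FAS_F does not reach exactly 1;
consumers should treat surrogate scores as ordinal, not as reproductions of
the reference implementation's values.

## Training loop and stopping rules

Candidates are visited in order of increasing taxonomic distance to the seed
species, equidistant species in an order drawn from a seeded generator (the
seed is recorded; identical inputs and seed reproduce the run exactly).
Each candidate found by the current profile is validated by the reciprocity
criterion before scoring.  Ties in the total score are broken by smaller
taxonomic distance, then lexicographically by protein id.  Two accelerations
are faithful to the modelled tool: a candidate reaching the maximal score 2
is accepted outright (hard cut-off), and one reaching 2·(1 − distDeviation)
(default 5%) is accepted because no more distant clade could supersede it by
the configured margin (soft cut-off; an alternative reading — margin
relative to the best of the remaining clades — is noted as an open
interpretation, and the rule can be disabled).  The FAS computation is
skipped when even a perfect FAS pair could not lift a candidate above the
current best; skipped candidates are never selected.  Compilation ends when
the core size (default 6 = seed + 5 iterations) is reached, the candidate
pool is empty, or an iteration finds no ortholog.

AS ratios are always computed against the seed c0, never against a group
consensus.  Per-candidate AS ratios, reciprocity verdicts and FAS pairs are
cached across iterations (seed and reference proteome are constant within a
run); the cache is behaviourally transparent, which the oracle-equivalence
test verifies by exhaustive re-scoring.

## Full search

The reference species of the reciprocity check is the seed species by
default.  Reference proteins are ranked by global alignment score against
the candidate; the candidate is accepted if the rank-1 protein is the core
ortholog, or if the core ortholog is closer (Kimura) to the best hit than
the candidate is.  Among accepted candidates of one taxon, the one with
minimal Kimura distance to the seed becomes the representative; candidates
whose distance to the representative exceeds the representative's distance
to the seed are discarded as putative out-paralogs.  FAS pairs are computed
for every retained record.  Searches are independent per (seed, taxon);
worker counts only partition the taxa, and the canonical output ordering
makes results invariant under partitioning.  Stored profiles can be re-used
to extend a profile matrix with new taxa.

## Profiles, visualization, duplications

Binarization marks a (seed, taxon) cell present when at least one retained
ortholog has FAS ≥ 0.3; the mean of FAS_F and FAS_B is used by default
because the filter direction is configurable in all other places too.
Embedding delegates to UMAP (15 neighbours, min-dist 0.1, Jaccard metric,
fixed seed 42).  Because stock UMAP is order-sensitive in the presence of
duplicate rows, the embedding is computed on the distinct repertoire
patterns and taxa sharing a pattern receive identical coordinates; the
neighbour count is clamped with a warning when patterns are fewer.  For
paralogous seed genes, the duplication origin is approximated by the closest
relative of the seed species in which one target protein is an ortholog of
two or more seeds, and the seed with the most ortholog-bearing taxa below a
focal lineage is kept as representative.

## Contamination and HGT screening

Consumed inputs are similarity hit tables (query, subject, subject taxon,
bit score) and gene-to-contig maps.  Per query, the self-hit is discarded,
hits within 10% of the best remaining bit score vote, and the assignment is
the lowest common ancestor of the voting taxa.  A gene assigned off the path
from its species to the root is foreign; a foreign gene on a contig shorter
than the assembly's unweighted mean contig length whose existing direct
neighbours (ordinal predecessor/successor; none on a single-gene contig,
vacuously satisfied) are also foreign is a contamination, any other foreign
gene is tentatively horizontally acquired.  The longest isoform represents a
gene; strand is carried but unused.

## Synthetic scenarios

The generator emulates the study conditions at desk scale.  Defaults, chosen
once: 16 species on an eight-rank ladder taxonomy contributing exactly one
clade per taxonomic distance class 1–7 from the seed species; 20 gene
families of 60-residue proteins; i.i.d. residue substitution at rate 0.03
per site per tree edge (maximal pairwise path ≈ 14 edges → ≈ 35% expected
divergence, far from Kimura saturation); no indels by default, so identity
oracles stay exact; per-family event probabilities of 0.1 for terminal loss,
in-paralog duplication, pre-speciation duplication (paralogous seed pairs)
and horizontal transfer from the most distant kingdom; 3 single-gene
contaminant contigs per scenario; 5 random decoy proteins per proteome.
Architectures descend from per-family templates with 0.1-rate gain, loss
and duplication events.

Hit tables scale bit scores as 2·L·identity.  Vertically inherited genes
additionally hit their own species' database record under a distinct
accession — reference databases contain annotated proteomes — whereas
planted HGT and contaminant copies have no conspecific database entry and
never act as database subjects themselves; their closest records come from
the donor lineage.  This mirrors the situation the screening rules were
designed for.

What passing tests show: the pipeline recovers planted representative
orthologs with precision/recall ≥ 0.9 across independent scenario draws,
keeps paralogous seeds consistent on pre-duplication taxa, and separates
planted contamination from HGT exactly.  What they do not show: behaviour
under indels, domain-level homology without full-length conservation,
unequal proteome sizes, annotation noise, or real database redundancy —
the generator's substitution-only model and its curated hit tables are
idealizations.

## Numerical choices and degenerate inputs

Score ties in candidate selection use an absolute tolerance of 1e-12 before
falling back to distance and id tie-breaks; the hard stop tolerates 1e-9.
Saturated Kimura distances compare as +∞.  Architectures missing from the
annotation map count as featureless (FAS 0 against any annotated reference,
1 against another featureless protein).  An empty reference architecture
scores 1 against an empty query and 0 otherwise.  Single-sequence "groups"
are legal (profile of the seed alone, the state before the first training
iteration).  A candidate pool pruned to nothing terminates compilation with
the members collected so far; a pruned-to-root tree reports an empty leaf
set.

## Scale of the shipped analyses

All tests and the acceptance script run on generated fixtures: scenario
generation takes well under a second, a full compile-and-search pass over
one scenario (23 seed profiles × 16 taxa) about 20–30 s.  These sizes are
the package's chosen test scale; the algorithms themselves are linear in the
number of search taxa.

## Known limitations

- The FAS surrogate is contract-compatible, not value-compatible, with the
  published algorithm (no e-value weighting, no overlap resolution by
  maximum-weight paths).
- The internal progressive aligner is adequate for the short, indel-free
  core groups it serves; for real data an external aligner hook is the
  better choice.
- The profile HMM uses a uniform background and Laplace/fixed-prior
  smoothing, not Dirichlet mixtures, and bit thresholds are not calibrated
  to database size.
- Taxonomic distance is rank-based; branch lengths play no role.
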