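"""Iterative compilation of the core ortholog group and its profile HMM.

Starting from a single seed protein c0, the compiler grows a small,
taxonomically diverse set C of core orthologs.  Candidate species are visited
in the order of increasing taxonomic distance to the seed species p0
(equidistant species in seeded random order).  In each iteration a targeted
ortholog search with the current profile is run per species, and the
candidate maximizing

    AS(c0, ci) / AS(c0, c0)  +  (FAS(c0 -> ci) + FAS(ci -> c0)) / 2

is added to C (AS: global alignment score; FAS: directional architecture
similarity).  Ties go to the candidate from the taxonomically closer
species, then to the lexicographically smaller protein id.  After each
iteration the group is re-aligned, the profile re-trained, and the selected
primer taxon plus every species within ``min_dist`` of either it or p0 is
pruned, so primer taxa stay pairwise at least ``min_dist`` apart.

Two early-stopping rules shortcut the candidate scan: a candidate reaching
the maximal total score of 2 is accepted outright (hard cut-off), and one
whose total cannot be superseded by more than ``dist_deviation`` of the
maximum — total >= 2*(1 - dist_deviation) — is accepted as well (soft
cut-off).  The costly architecture comparison is skipped whenever even a
perfect FAS pair could not lift the candidate above the current best.

Compilation terminates when (i) the requested core size is reached, (ii) the
candidate species pool is exhausted, or (iii) an iteration finds no ortholog.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .features import Architecture, FasPair, bidirectional_fas
from .ortholog_search import SearchParams, reciprocity_check
from .phmm import ProfileHMM, search_phmm, train_phmm
from .seqmodel import (
    Alignment,
    Protein,
    Proteome,
    ScoringParams,
    align_core_group,
    pairwise_score,
    self_score,
)
from .taxonomy import (
    TaxonomyTree,
    prune_after_iteration,
    prune_rank_bounds,
    taxonomic_distance,
    traversal_order,
)

MAX_TOTAL_SCORE = 2.0
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class CompileOptions:
    core_size: int = 6  # seed + 5 iterations
    min_dist: str = "genus"
    max_dist: str = "superkingdom"
    dist_deviation: float = 0.05
    core_taxa: Optional[frozenset[int]] = None
    rng_seed: int = 42
    bit_threshold: float = 10.0
    scoring: ScoringParams = ScoringParams()
    pseudocount: float = 1.0
    fas_weights: Optional[Mapping[str, float]] = None
    enable_early_stop: bool = True
    enable_fas_skip: bool = True

    def __post_init__(self):
        if self.core_size < 1:
            raise ValueError("core_size must be >= 1")
        if not (0.0 <= self.dist_deviation < 1.0):
            raise ValueError("dist_deviation must lie in [0, 1)")


@dataclass
class CandidateScore:
    as_ratio: float
    fas_f: Optional[float]  # None when the FAS computation was skipped
    fas_b: Optional[float]
    total: Optional[float]

    @property
    def skipped(self) -> bool:
        return self.total is None


@dataclass
class CoreMember:
    protein: Protein
    taxon: int
    score: Optional[CandidateScore]  # None for the seed itself


@dataclass
class CoreGroup:
    """The compiled core ortholog group: members, alignment and profile."""

    seed: Protein
    members: list[CoreMember]
    primer_taxa: set[int]
    alignment: Alignment
    hmm: ProfileHMM

    def proteins(self) -> list[Protein]:
        return [m.protein for m in self.members]


@dataclass
class ScoreLogRow:
    iteration: int
    taxon: int
    protein: str
    as_ratio: float
    fas_f: Optional[float]
    fas_b: Optional[float]
    total: Optional[float]
    decision: str


# ------------------------------------------------------------ scoring rules


def candidate_total_score(as_ratio: float, fas_f: float, fas_b: float) -> float:
    """Combined candidate score: alignment-score ratio plus mean directional
    architecture similarity; maximal value 2."""
    return as_ratio + 0.5 * (fas_f + fas_b)


def fas_skip_allowed(as_ratio: float, best_total_so_far: float) -> bool:
    """True when even a perfect architecture match (FAS_F = FAS_B = 1) could
    not beat the current best candidate, so the FAS computation is skipped."""
    return as_ratio + 1.0 < best_total_so_far


def early_stop_decision(
    score: CandidateScore,
    remaining,
    dist_deviation: float,
    soft_enabled: bool = True,
) -> str:
    """``accept_now`` or ``keep_searching`` for a fully scored candidate.

    Hard rule: the candidate reaches the maximal total of 2.  Soft rule (may
    be disabled): its total is within ``dist_deviation`` of the maximum, so no
    more distant clade could supersede it by the configured margin.
    ``remaining`` (the unvisited distance classes) is part of the call
    contract for alternative margin interpretations but unused by the default
    rule.
    """
    if score.total is None:
        return "keep_searching"
    if score.total >= MAX_TOTAL_SCORE - 1e-9:
        return "accept_now"
    if soft_enabled and score.total >= MAX_TOTAL_SCORE * (1.0 - dist_deviation):
        return "accept_now"
    return "keep_searching"


# ------------------------------------------------------------------ compiler


@dataclass
class _CompileCaches:
    as_ratio: dict[str, float] = field(default_factory=dict)
    reciprocal: dict[str, bool] = field(default_factory=dict)
    fas: dict[str, FasPair] = field(default_factory=dict)


def compile_core_group(
    seed: Protein,
    proteomes: Mapping[int, Proteome],
    tree: TaxonomyTree,
    architectures: Mapping[str, Architecture],
    opts: CompileOptions = CompileOptions(),
) -> tuple[CoreGroup, list[ScoreLogRow]]:
    """Compile the core ortholog group for one seed protein.

    ``proteomes`` maps taxon id to gene set; ``tree`` must cover all proteome
    taxa; ``architectures`` maps protein id to feature architecture (missing
    proteins count as featureless).  Returns the final group together with a
    per-candidate score log.
    """
    p0 = seed.taxon
    if p0 not in proteomes or seed.id not in proteomes[p0]:
        raise ValueError(f"seed protein {seed.id} not found in proteome of taxon {p0}")

    candidate_taxa = [t for t in proteomes if t != p0 and tree.is_leaf(t)]
    if opts.core_taxa is not None:
        candidate_taxa = [t for t in candidate_taxa if t in opts.core_taxa]
    active = tree.restrict(candidate_taxa)
    active = prune_rank_bounds(active, p0, opts.min_dist, opts.max_dist)

    search_params = SearchParams(
        bit_threshold=opts.bit_threshold,
        scoring=opts.scoring,
        fas_weights=opts.fas_weights,
    )
    seed_self = self_score(seed, opts.scoring)
    seed_arch = architectures.get(seed.id) or Architecture(seed.id, len(seed), [])
    caches = _CompileCaches()

    members = [CoreMember(seed, p0, None)]
    primer_taxa = {p0}
    alignment = align_core_group([seed], opts.scoring)
    hmm = train_phmm(alignment, opts.pseudocount)
    log: list[ScoreLogRow] = []
    iter_seeds = np.random.SeedSequence(opts.rng_seed).generate_state(
        max(opts.core_size, 1) + 1
    ) % (2**31)

    iteration = 0
    while len(members) < opts.core_size and active.leaves():
        iteration += 1
        order = traversal_order(active, p0, int(iter_seeds[iteration - 1]))
        best: Optional[tuple[CandidateScore, int, Protein]] = None
        best_dist = -1
        stop_scan = False
        for taxon in order:
            taxon_dist = taxonomic_distance(tree, p0, taxon)
            proteome = proteomes[taxon]
            hits = search_phmm(hmm, proteome, opts.bit_threshold)
            for hit in sorted(hits, key=lambda h: h.protein):
                cand = proteome.get(hit.protein)
                ok = caches.reciprocal.get(cand.id)
                if ok is None:
                    ok = reciprocity_check(cand, proteomes[p0], seed, search_params)
                    caches.reciprocal[cand.id] = ok
                if not ok:
                    log.append(
                        ScoreLogRow(iteration, taxon, cand.id, float("nan"), None, None, None, "rejected-reciprocity")
                    )
                    continue
                as_ratio = caches.as_ratio.get(cand.id)
                if as_ratio is None:
                    as_ratio = pairwise_score(seed, cand, opts.scoring) / seed_self
                    caches.as_ratio[cand.id] = as_ratio
                best_total = best[0].total if best else 0.0
                if opts.enable_fas_skip and fas_skip_allowed(as_ratio, best_total):
                    log.append(
                        ScoreLogRow(iteration, taxon, cand.id, as_ratio, None, None, None, "fas-skipped")
                    )
                    continue
                fas = caches.fas.get(cand.id)
                if fas is None:
                    cand_arch = architectures.get(cand.id) or Architecture(cand.id, len(cand), [])
                    fas = bidirectional_fas(seed_arch, cand_arch, opts.fas_weights)
                    caches.fas[cand.id] = fas
                score = CandidateScore(
                    as_ratio,
                    fas.fas_f,
                    fas.fas_b,
                    candidate_total_score(as_ratio, fas.fas_f, fas.fas_b),
                )
                decision = "scored"
                if _beats(score, taxon_dist, cand.id, best, best_dist):
                    best = (score, taxon, cand)
                    best_dist = taxon_dist
                    decision = "new-best"
                if (
                    opts.enable_early_stop
                    and best is not None
                    and best[2].id == cand.id
                    and early_stop_decision(score, None, opts.dist_deviation) == "accept_now"
                ):
                    decision = "early-accept"
                    stop_scan = True
                log.append(
                    ScoreLogRow(
                        iteration, taxon, cand.id, as_ratio, fas.fas_f, fas.fas_b, score.total, decision
                    )
                )
                if stop_scan:
                    break
            if stop_scan:
                break
        if best is None:
            break  # termination (iii): no ortholog found in this iteration
        score, pi, protein = best
        members.append(CoreMember(protein, pi, score))
        primer_taxa.add(pi)
        alignment = align_core_group([m.protein for m in members], opts.scoring)
        hmm = train_phmm(alignment, opts.pseudocount)
        active = prune_after_iteration(active, p0, pi, opts.min_dist)

    return CoreGroup(seed, members, primer_taxa, alignment, hmm), log


def _beats(
    score: CandidateScore,
    dist: int,
    pid: str,
    best: Optional[tuple[CandidateScore, int, Protein]],
    best_dist: int,
) -> bool:
    if best is None:
        return True
    cur = best[0].total
    if score.total > cur + _TIE_EPS:
        return True
    if score.total < cur - _TIE_EPS:
        return False
    if dist != best_dist:
        return dist < best_dist
    return pid < best[2].id
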