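"""Full ortholog search: per-taxon profile search, reciprocity validation,
representative selection and co-ortholog filtering.

A candidate hit from the profile search is promoted to an ortholog only if a
reciprocal similarity search against a reference proteome (by default the
seed species) either returns the core ortholog as the best hit, or — when the
core ortholog ranks lower — the evolutionary distance between the core
ortholog and the best hit is smaller than between the candidate and the best
hit.  Evolutionary distances are Kimura-corrected p-distances on pairwise
global alignments.

When several candidates of one taxon pass, the one minimizing the Kimura
distance to the seed protein becomes the representative, and only candidates
whose distance to the representative does not exceed the representative's
distance to the seed are retained (co-orthologs); this guards against
out-paralogs.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Optional, Sequence

from .features import Architecture, FasPair, bidirectional_fas
from .phmm import HmmHit, search_phmm
from .seqmodel import (
    Protein,
    Proteome,
    ScoringParams,
    kimura_between,
    pairwise_score,
)

if TYPE_CHECKING:  # pragma: no cover
    from .core_compile import CoreGroup


@dataclass(frozen=True)
class SearchParams:
    bit_threshold: float = 10.0
    scoring: ScoringParams = ScoringParams()
    fas_weights: Optional[Mapping[str, float]] = None


@dataclass
class OrthologRecord:
    """One accepted ortholog of a seed protein in one taxon."""

    seed: str
    taxon: int
    protein: str
    hmm_bits: float
    kimura_to_seed: float
    fas: Optional[FasPair]
    is_representative: bool
    co_ortholog_rank: int


@dataclass(frozen=True)
class ReciprocityResult:
    accepted: bool
    best_hit: str
    kimura_core_to_best: float
    kimura_candidate_to_best: float


def reciprocity_check_detailed(
    candidate: Protein,
    reference_proteome: Proteome,
    core_protein: Protein,
    params: SearchParams = SearchParams(),
) -> ReciprocityResult:
    """Reciprocity criterion with the values the decision was based on."""
    ranked = sorted(
        reference_proteome,
        key=lambda p: (-pairwise_score(candidate, p, params.scoring), p.id),
    )
    best = ranked[0]
    if best.id == core_protein.id:
        return ReciprocityResult(True, best.id, 0.0, 0.0)
    d_core = kimura_between(core_protein, best, params.scoring)
    d_cand = kimura_between(candidate, best, params.scoring)
    return ReciprocityResult(d_core < d_cand, best.id, d_core, d_cand)


def reciprocity_check(
    candidate: Protein,
    reference_proteome: Proteome,
    core_protein: Protein,
    params: SearchParams = SearchParams(),
) -> bool:
    return reciprocity_check_detailed(candidate, reference_proteome, core_protein, params).accepted


def select_representative(
    accepted: Sequence[Protein],
    seed: Protein,
    params: SearchParams = SearchParams(),
) -> Protein:
    """The accepted candidate with minimal Kimura distance to the seed
    (ties broken by protein id)."""
    if not accepted:
        raise ValueError("no accepted candidates to select a representative from")
    return min(
        accepted, key=lambda c: (kimura_between(c, seed, params.scoring), c.id)
    )


def filter_coorthologs(
    accepted: Sequence[Protein],
    representative: Protein,
    seed: Protein,
    params: SearchParams = SearchParams(),
) -> list[Protein]:
    """Retain candidates at most as far from the representative as the
    representative is from the seed; the representative itself always stays."""
    d_rep_seed = kimura_between(representative, seed, params.scoring)
    return [
        c
        for c in accepted
        if c.id == representative.id
        or kimura_between(c, representative, params.scoring) <= d_rep_seed
    ]


def search_taxon(
    group: "CoreGroup",
    proteome: Proteome,
    reference_proteome: Proteome,
    architectures: Mapping[str, Architecture],
    params: SearchParams = SearchParams(),
) -> list[OrthologRecord]:
    """Run the trained profile against one taxon and emit ortholog records.

    Pipeline: profile search -> reciprocity validation against the reference
    species -> representative selection -> co-ortholog filter -> bidirectional
    feature-architecture scoring of every retained record.
    """
    seed = group.seed
    hits: list[HmmHit] = search_phmm(group.hmm, proteome, params.bit_threshold)
    bits = {h.protein: h.log_odds for h in hits}
    accepted = [
        proteome.get(h.protein)
        for h in hits
        if reciprocity_check(proteome.get(h.protein), reference_proteome, seed, params)
    ]
    if not accepted:
        return []
    rep = select_representative(accepted, seed, params)
    retained = filter_coorthologs(accepted, rep, seed, params)
    retained.sort(key=lambda c: (kimura_between(c, seed, params.scoring), c.id))
    seed_arch = _arch_of(seed, architectures)
    records = []
    for rank, cand in enumerate(retained, start=1):
        fas = bidirectional_fas(seed_arch, _arch_of(cand, architectures), params.fas_weights)
        records.append(
            OrthologRecord(
                seed=seed.id,
                taxon=proteome.taxon,
                protein=cand.id,
                hmm_bits=bits[cand.id],
                kimura_to_seed=kimura_between(cand, seed, params.scoring),
                fas=fas,
                is_representative=cand.id == rep.id,
                co_ortholog_rank=rank,
            )
        )
    return records


def _arch_of(protein: Protein, architectures: Mapping[str, Architecture]) -> Architecture:
    arch = architectures.get(protein.id)
    if arch is None:  # unannotated proteins count as featureless
        arch = Architecture(protein.id, len(protein), [])
    return arch


@dataclass
class SearchFailure:
    seed: str
    taxon: int
    error: str


@dataclass
class FullSearchResult:
    records: list[OrthologRecord]
    failures: list[SearchFailure] = field(default_factory=list)


def run_full_search(
    groups: Sequence["CoreGroup"],
    proteomes: Mapping[int, Proteome],
    architectures: Mapping[str, Architecture],
    params: SearchParams = SearchParams(),
    n_workers: int = 1,
    taxa_subset: Optional[Iterable[int]] = None,
    skip: Optional[set[tuple[str, int]]] = None,
) -> FullSearchResult:
    """Search every seed's profile across a taxon collection.

    Each (seed, taxon) search is independent; ``n_workers`` only partitions
    the taxa into non-overlapping subsets, and the canonical output ordering
    (seed id, taxon, co-ortholog rank) makes the result invariant under the
    worker count.  ``taxa_subset`` confines the search to a taxonomic
    subgroup; ``skip`` holds (seed, taxon) pairs already searched (incremental
    extension with stored profiles).  A failing taxon is logged and does not
    abort the run.
    """
    taxa = sorted(taxa_subset) if taxa_subset is not None else sorted(proteomes)
    taxa = [t for t in taxa if t in proteomes]
    jobs = [
        (g, t)
        for g in groups
        for t in taxa
        if t != g.seed.taxon and (skip is None or (g.seed.id, t) not in skip)
    ]

    def run_job(job) -> tuple:
        group, taxon = job
        try:
            recs = search_taxon(
                group,
                proteomes[taxon],
                proteomes[group.seed.taxon],
                architectures,
                params,
            )
            return recs, None
        except Exception as exc:  # surfaced per taxon, run continues
            return [], SearchFailure(group.seed.id, taxon, repr(exc))

    records: list[OrthologRecord] = []
    failures: list[SearchFailure] = []
    if n_workers <= 1:
        outcomes = map(run_job, jobs)
    else:
        chunks = [jobs[i::n_workers] for i in range(n_workers)]
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            chunk_results = pool.map(lambda chunk: [run_job(j) for j in chunk], chunks)
        outcomes = (o for chunk in chunk_results for o in chunk)
    for recs, failure in outcomes:
        records.extend(recs)
        if failure is not None:
            failures.append(failure)
    records.sort(key=lambda r: (r.seed, r.taxon, r.co_ortholog_rank))
    failures.sort(key=lambda f: (f.seed, f.taxon))
    return FullSearchResult(records, failures)


def records_to_rows(records: Iterable[OrthologRecord]) -> list[dict]:
    """Tabular form of ortholog records (one dict per row)."""
    rows = []
    for r in records:
        rows.append(
            {
                "seed": r.seed,
                "taxon": r.taxon,
                "ortholog": r.protein,
                "hmm_bits": round(r.hmm_bits, 3),
                "kimura": round(r.kimura_to_seed, 6),
                "fas_f": None if r.fas is None else round(r.fas.fas_f, 6),
                "fas_b": None if r.fas is None else round(r.fas.fas_b, 6),
                "representative": int(r.is_representative),
                "co_ortholog_rank": r.co_ortholog_rank,
            }
        )
    return rows
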