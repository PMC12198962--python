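"""Reciprocity validation, representative selection, co-ortholog filtering
and the parallel full search."""

import numpy as np
import pytest

from orthotrace.core_compile import CoreGroup, CoreMember
from orthotrace.ortholog_search import (
    filter_coorthologs,
    reciprocity_check,
    reciprocity_check_detailed,
    run_full_search,
    search_taxon,
    select_representative,
)
from orthotrace.phmm import train_phmm
from orthotrace.seqmodel import (
    AMINO_ACIDS,
    Protein,
    Proteome,
    align_core_group,
    kimura_between,
)
from orthotrace.synthdata import ScenarioSpec, generate

AA = list(AMINO_ACIDS)


def mutate_at(seq: str, positions, rng) -> str:
    out = list(seq)
    for i in positions:
        out[i] = rng.choice([a for a in AA if a != out[i]])
    return "".join(out)


def seed_group(seed: Protein) -> CoreGroup:
    """A minimal core group: the seed alone with its single-sequence profile
    (the situation before the first training iteration, or a stored profile)."""
    aln = align_core_group([seed])
    return CoreGroup(seed, [CoreMember(seed, seed.taxon, None)], {seed.taxon}, aln, train_phmm(aln))


@pytest.fixture(scope="module")
def crafted():
    rng = np.random.default_rng(20)
    base = "".join(rng.choice(AA, 60))
    return rng, base


class TestReciprocity:
    def test_core_as_best_hit_accepts(self, crafted):
        rng, base = crafted
        core = Protein("core", 1, base)
        candidate = Protein("cand", 2, mutate_at(base, range(6), rng))
        reference = Proteome(1, [core, Protein("junk", 1, "".join(rng.choice(AA, 60)))])
        assert reciprocity_check(candidate, reference, core) is True

    def test_lower_ranking_core_accepted_when_closer_to_best_hit(self, crafted):
        rng, base = crafted
        best = Protein("best", 1, base)
        core = Protein("core", 1, mutate_at(base, range(0, 4), rng))  # near best
        candidate = Protein("cand", 2, mutate_at(base, range(10, 28), rng))  # far
        reference = Proteome(1, [best, core])
        detail = reciprocity_check_detailed(candidate, reference, core)
        assert detail.best_hit == "best"
        assert detail.kimura_core_to_best < detail.kimura_candidate_to_best
        assert detail.accepted is True

    def test_rejected_when_core_farther_from_best_hit(self, crafted):
        rng, base = crafted
        best = Protein("best", 1, base)
        core = Protein("core", 1, mutate_at(base, range(0, 26), rng))  # far from best
        candidate = Protein("cand", 2, mutate_at(base, range(30, 38), rng))  # near best
        reference = Proteome(1, [best, core])
        detail = reciprocity_check_detailed(candidate, reference, core)
        assert detail.best_hit == "best"
        assert detail.kimura_core_to_best > detail.kimura_candidate_to_best
        assert detail.accepted is False


class TestRepresentativeSelection:
    def test_single_candidate_is_representative(self, crafted):
        rng, base = crafted
        seed = Protein("seed", 1, base)
        only = Protein("only", 2, mutate_at(base, range(5), rng))
        assert select_representative([only], seed).id == "only"

    def test_minimum_kimura_wins(self, crafted):
        rng, base = crafted
        seed = Protein("seed", 1, base)
        near = Protein("near", 2, mutate_at(base, range(6), rng))
        far = Protein("far", 2, mutate_at(base, range(20), rng))
        assert select_representative([far, near], seed).id == "near"

    def test_tie_broken_by_protein_id(self, crafted):
        _, base = crafted
        seed = Protein("seed", 1, base)
        twin_a = Protein("a", 2, base)
        twin_b = Protein("b", 2, base)
        assert select_representative([twin_b, twin_a], seed).id == "a"

    def test_empty_candidate_list_rejected(self, crafted):
        _, base = crafted
        with pytest.raises(ValueError):
            select_representative([], Protein("seed", 1, base))


class TestCoorthologFilter:
    def test_retention_inequality(self, crafted):
        rng, base = crafted
        seed = Protein("seed", 1, base)
        rep = Protein("rep", 2, mutate_at(base, range(10), rng))  # moderate distance
        close = Protein("close", 2, mutate_at(rep.residues, range(55, 57), rng))
        distant = Protein("distant", 2, mutate_at(rep.residues, range(20, 50), rng))
        d_rep_seed = kimura_between(rep, seed)
        assert kimura_between(close, rep) <= d_rep_seed
        assert kimura_between(distant, rep) > d_rep_seed
        retained = filter_coorthologs([rep, close, distant], rep, seed)
        assert [p.id for p in retained] == ["rep", "close"]

    def test_representative_always_retained(self, crafted):
        _, base = crafted
        seed = Protein("seed", 1, base)
        rep = Protein("rep", 2, base)
        assert filter_coorthologs([rep], rep, seed) == [rep]


class TestSearchTaxon:
    def test_planted_one_to_one_ortholog(self, small_fixture):
        fixture = small_fixture
        seed_id = sorted(fixture.seeds)[0]
        seed = fixture.seeds[seed_id]
        family = seed_id.split("@")[0]
        taxon = next(
            t for t in (105, 106, 107)
            if f"{family}@{t}" in fixture.proteomes[t]
        )
        records = search_taxon(
            seed_group(seed), fixture.proteomes[taxon],
            fixture.proteomes[fixture.seed_taxon], fixture.architectures,
        )
        reps = [r for r in records if r.is_representative]
        assert len(reps) == 1
        assert reps[0].protein == f"{family}@{taxon}"
        assert reps[0].fas is not None

    def test_planted_inparalog_pair_both_retained(self):
        fixture = generate(ScenarioSpec(
            n_families=2, n_decoys=3, p_loss=0.0, p_dup_after=1.0,
            p_dup_before=0.0, p_hgt=0.0, n_contaminant_contigs=0, rng_seed=6,
        ))
        dup = fixture.truth[fixture.truth["relation"] == "in-paralog"].iloc[0]
        seed = fixture.seeds[dup.seed]
        records = search_taxon(
            seed_group(seed), fixture.proteomes[dup.taxon],
            fixture.proteomes[fixture.seed_taxon], fixture.architectures,
        )
        assert len(records) == 2
        assert {r.protein for r in records} == {dup.protein, dup.protein[:-2]}
        assert sum(r.is_representative for r in records) == 1
        assert [r.co_ortholog_rank for r in sorted(records, key=lambda r: r.co_ortholog_rank)] == [1, 2]

    def test_decoy_only_proteome_yields_nothing(self, small_fixture):
        fixture = small_fixture
        seed = fixture.seeds[sorted(fixture.seeds)[0]]
        decoys = Proteome(113, [p for p in fixture.proteomes[113] if p.id.startswith("DEC")])
        records = search_taxon(
            seed_group(seed), decoys,
            fixture.proteomes[fixture.seed_taxon], fixture.architectures,
        )
        assert records == []


@pytest.fixture(scope="module")
def small_groups(small_fixture):
    return {sid: seed_group(p) for sid, p in small_fixture.seeds.items()}


class TestRunFullSearch:
    def test_worker_count_does_not_change_results(self, small_fixture, small_groups):
        fixture = small_fixture
        serial = run_full_search(
            list(small_groups.values()), fixture.proteomes, fixture.architectures,
            n_workers=1,
        )
        parallel = run_full_search(
            list(small_groups.values()), fixture.proteomes, fixture.architectures,
            n_workers=4,
        )
        assert serial.records == parallel.records
        assert serial.failures == parallel.failures == []

    def test_subgroup_restriction(self, small_fixture, small_groups):
        fixture = small_fixture
        subset = [103, 104]
        result = run_full_search(
            list(small_groups.values()), fixture.proteomes, fixture.architectures,
            taxa_subset=subset,
        )
        assert {r.taxon for r in result.records} <= set(subset)

    def test_incremental_extension_adds_only_new_taxa(self, small_fixture, small_groups):
        fixture = small_fixture
        first = run_full_search(
            list(small_groups.values()), fixture.proteomes, fixture.architectures,
            taxa_subset=[103, 104, 105],
        )
        done = {(r.seed, r.taxon) for r in first.records}
        second = run_full_search(
            list(small_groups.values()), fixture.proteomes, fixture.architectures,
            taxa_subset=[103, 104, 105, 107, 108], skip=done,
        )
        assert {r.taxon for r in second.records} <= {107, 108}
        # merged output covers all five taxa
        merged = {(r.seed, r.taxon) for r in first.records + second.records}
        assert {t for _, t in merged} == {103, 104, 105, 107, 108}

    def test_paralogous_seeds_agree_in_outgroup_taxa(self):
        # seeds duplicated before the outgroup speciations receive the same
        # ortholog there
        fixture = generate(ScenarioSpec(
            n_families=2, n_decoys=3, p_loss=0.0, p_dup_after=0.0,
            p_dup_before=1.0, p_hgt=0.0, n_contaminant_contigs=0, rng_seed=8,
        ))
        groups = {sid: seed_group(p) for sid, p in fixture.seeds.items()}
        result = run_full_search(
            list(groups.values()), fixture.proteomes, fixture.architectures,
        )
        reps = {
            (r.seed, r.taxon): r.protein for r in result.records if r.is_representative
        }
        outgroup = [t for t in fixture.proteomes if t >= 109]
        agreements = 0
        for family in ("F00", "F01"):
            a, b = f"{family}A@101", f"{family}B@101"
            for taxon in outgroup:
                ra, rb = reps.get((a, taxon)), reps.get((b, taxon))
                if ra is not None and rb is not None:
                    assert ra == rb
                    agreements += 1
        assert agreements > 0
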