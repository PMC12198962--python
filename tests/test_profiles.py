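"""Profile-matrix filtering, binarization, embedding and repertoire ranking."""

import numpy as np
import pandas as pd
import pytest

from orthotrace.features import FasPair
from orthotrace.ortholog_search import OrthologRecord
from orthotrace.profiles import (
    ProfileMatrix,
    binarize,
    embed,
    filter_by_fas,
    rank_taxa_by_repertoire,
    select_paralog_representative,
    write_binary_tsv,
    write_phyloprofile,
    write_profile_tsv,
)
from orthotrace.synthdata import ladder_taxonomy


def rec(seed, taxon, protein, fas_f, fas_b, rep=True, rank=1):
    return OrthologRecord(
        seed, taxon, protein, hmm_bits=50.0, kimura_to_seed=0.1,
        fas=FasPair(fas_f, fas_b), is_representative=rep, co_ortholog_rank=rank,
    )


@pytest.fixture()
def toy_matrix():
    records = [
        rec("S1", 201, "a", 0.8, 0.6),
        rec("S1", 202, "b", 0.9, 0.9),
        rec("S2", 201, "c", 0.2, 0.2),
        rec("S2", 202, "d", 0.3, 0.3),
    ]
    return ProfileMatrix.from_records(records, seeds=["S1", "S2"], taxa=[201, 202])


class TestFilterByFas:
    def test_zero_threshold_is_identity(self, toy_matrix):
        filtered = filter_by_fas(toy_matrix, 0.0, "mean")
        assert filtered.cells.keys() == toy_matrix.cells.keys()
        assert all(
            filtered.records(s, t) == toy_matrix.records(s, t)
            for s in toy_matrix.seeds for t in toy_matrix.taxa
        )

    def test_direction_modes_differ(self, toy_matrix):
        # FAS_F 0.8 / FAS_B 0.6: kept in forward mode at 0.75, dropped in mean
        forward = filter_by_fas(toy_matrix, 0.75, "forward")
        mean = filter_by_fas(toy_matrix, 0.75, "mean")
        assert [r.protein for r in forward.records("S1", 201)] == ["a"]
        assert mean.records("S1", 201) == []

    def test_threshold_one_keeps_only_perfect_scores(self):
        matrix = ProfileMatrix.from_records(
            [rec("S1", 201, "a", 1.0, 1.0), rec("S1", 202, "b", 0.999, 1.0)]
        )
        kept = filter_by_fas(matrix, 1.0, "mean")
        assert [r.protein for r in kept.all_records()] == ["a"]

    def test_idempotent_and_monotone(self, toy_matrix):
        once = filter_by_fas(toy_matrix, 0.5, "mean")
        twice = filter_by_fas(once, 0.5, "mean")
        assert once.cells == twice.cells
        stricter = filter_by_fas(toy_matrix, 0.8, "mean")
        loose_ids = {r.protein for r in filter_by_fas(toy_matrix, 0.5, "mean").all_records()}
        strict_ids = {r.protein for r in stricter.all_records()}
        assert strict_ids <= loose_ids

    def test_invalid_mode_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match="unknown FAS mode"):
            filter_by_fas(toy_matrix, 0.5, "sideways")


class TestBinarize:
    def test_low_scoring_records_do_not_count(self):
        matrix = ProfileMatrix.from_records([rec("S1", 201, "a", 0.2, 0.2)],
                                            seeds=["S1"], taxa=[201])
        assert binarize(matrix, fas_min=0.3).loc[201, "S1"] == 0

    def test_boundary_score_counts(self):
        # "below 0.3" filtered: a record at exactly 0.3 stays
        matrix = ProfileMatrix.from_records([rec("S1", 201, "a", 0.3, 0.3)],
                                            seeds=["S1"], taxa=[201])
        assert binarize(matrix, fas_min=0.3).loc[201, "S1"] == 1

    def test_at_least_one_rule(self):
        records = [rec("S1", 201, f"c{k}", 0.5, 0.5, rep=(k == 0), rank=k + 1)
                   for k in range(4)]
        matrix = ProfileMatrix.from_records(records, seeds=["S1"], taxa=[201, 202])
        bin_df = binarize(matrix, fas_min=0.3)
        assert bin_df.loc[201, "S1"] == 1
        assert bin_df.loc[202, "S1"] == 0

    def test_commutes_with_mean_filter(self, toy_matrix):
        direct = binarize(toy_matrix, fas_min=0.6, mode="mean")
        via_filter = binarize(filter_by_fas(toy_matrix, 0.6, "mean"), fas_min=0.0)
        assert direct.equals(via_filter)


@pytest.fixture(scope="module")
def disjoint_binary():
    # two repertoire groups concentrated on disjoint seed subsets, with a
    # little cross-presence so the neighbourhood graph stays connected
    rng = np.random.default_rng(3)

    def row(first_half_rich):
        rich = (rng.random(6) < 0.9).astype(int)
        poor = (rng.random(6) < 0.15).astype(int)
        parts = [rich, poor] if first_half_rich else [poor, rich]
        return np.concatenate(parts)

    rows = [row(True) for _ in range(5)] + [row(False) for _ in range(5)]
    rows.append(rows[0])  # duplicated taxon
    return pd.DataFrame(rows, index=list(range(101, 112)),
                        columns=[f"F{i}" for i in range(12)])


class TestEmbedding:
    def test_deterministic_and_duplicates_coincide(self, disjoint_binary):
        with pytest.warns(UserWarning, match="clamped"):
            r1 = embed(disjoint_binary, rng_seed=5)
        with pytest.warns(UserWarning, match="clamped"):
            r2 = embed(disjoint_binary, rng_seed=5)
        assert r1.coordinates == r2.coordinates
        assert r1.coordinates[101] == r1.coordinates[111]  # duplicated taxon row

    def test_disjoint_groups_separate(self, disjoint_binary):
        with pytest.warns(UserWarning, match="clamped"):
            result = embed(disjoint_binary, rng_seed=5)
        coords = np.array([result.coordinates[t] for t in range(101, 111)])
        a, b = coords[:5], coords[5:]
        intra = np.mean([np.linalg.norm(x - y) for g in (a, b) for x in g for y in g])
        inter = np.mean([np.linalg.norm(x - y) for x in a for y in b])
        assert inter > intra

    def test_single_taxon_rejected(self):
        df = pd.DataFrame([[1, 0]], index=[101], columns=["a", "b"])
        with pytest.raises(ValueError, match="at least two"):
            embed(df)


class TestParalogRepresentative:
    def _matrix(self, cells):
        records = []
        for (seed, taxon), proteins in cells.items():
            for k, pid in enumerate(proteins):
                records.append(rec(seed, taxon, pid, 0.9, 0.9, rep=(k == 0), rank=k + 1))
        seeds = sorted({s for s, _ in cells})
        taxa = sorted({t for _, t in cells})
        return ProfileMatrix.from_records(records, seeds=seeds, taxa=taxa)

    def test_shared_ortholog_in_sister_genus_dates_duplication(self):
        tree = ladder_taxonomy()
        matrix = self._matrix({
            ("A@101", 102): ["a102"], ("B@101", 102): ["b102"],
            ("A@101", 103): ["x103"], ("B@101", 103): ["x103"],  # shared
            ("A@101", 105): ["x105"], ("B@101", 105): ["x105"],
        })
        call = select_paralog_representative(
            ["A@101", "B@101"], matrix, tree, focal_lineage=2, seed_taxon=101,
        )
        assert call.origin_taxon == 103  # closest relative with a shared target

    def test_representative_has_most_focal_orthologs(self):
        tree = ladder_taxonomy()
        matrix = self._matrix({
            ("A@101", t): [f"a{t}"] for t in (103, 105, 107, 109, 111)
        } | {("B@101", t): [f"b{t}"] for t in (103, 105)})
        call = select_paralog_representative(
            ["A@101", "B@101"], matrix, tree, focal_lineage=2, seed_taxon=101,
        )
        assert call.representative == "A@101"

    def test_no_shared_target_reports_within_seed_species(self):
        tree = ladder_taxonomy()
        matrix = self._matrix({
            ("A@101", 103): ["a103"], ("B@101", 103): ["b103"],
        })
        call = select_paralog_representative(
            ["A@101", "B@101"], matrix, tree, focal_lineage=2, seed_taxon=101,
        )
        assert call.origin_taxon is None
        assert call.origin_label == "within seed species"


class TestRepertoireRanking:
    def test_counts_families_not_seeds(self):
        binary = pd.DataFrame(
            [[1, 1, 1, 0], [0, 0, 0, 0], [1, 0, 1, 1]],
            index=[201, 202, 203],
            columns=["s1", "s2", "s3", "s4"],
        )
        # s1/s2 are paralogous seeds of one family: 201 covers 2 families,
        # 203 covers 3 of the 4 seed columns but 3 distinct families
        fam = {"s1": "famA", "s2": "famA", "s3": "famB", "s4": "famC"}
        ranked = rank_taxa_by_repertoire(binary, fam)
        assert list(ranked["taxon"]) == [203, 201, 202]
        assert list(ranked["n_families"]) == [3, 2, 0]

    def test_equal_counts_rank_in_id_order(self):
        binary = pd.DataFrame([[1, 0], [0, 1]], index=[302, 301], columns=["a", "b"])
        ranked = rank_taxa_by_repertoire(binary, {})
        assert list(ranked["taxon"]) == [301, 302]


class TestExports:
    def test_tsv_outputs_written(self, toy_matrix, tmp_path):
        write_profile_tsv(toy_matrix, tmp_path / "profiles.tsv")
        write_phyloprofile(toy_matrix, tmp_path / "pp.tsv")
        binary = binarize(toy_matrix, fas_min=0.3)
        write_binary_tsv(binary, tmp_path / "bin.tsv")
        pp = pd.read_csv(tmp_path / "pp.tsv", sep="\t")
        assert list(pp.columns) == ["geneID", "ncbiID", "orthoID", "FAS_F", "FAS_B"]
        assert pp["ncbiID"].str.startswith("ncbi").all()
        assert len(pd.read_csv(tmp_path / "profiles.tsv", sep="\t")) == 4
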