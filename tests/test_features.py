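"""Feature architectures and the asymmetric architecture similarity score."""

import numpy as np
import pytest

from orthotrace.features import (
    Architecture,
    ArchitectureError,
    FasPair,
    FeatureInstance,
    architecture_diff,
    bidirectional_fas,
    fas_score,
    read_architectures,
    write_architectures,
)


def arch(pid, length, *feats):
    return Architecture(pid, length, [FeatureInstance(t, s, e) for t, s, e in feats])


class TestArchitectureModel:
    def test_single_instance_architecture(self):
        a = arch("p", 100, ("PFAM:PF00759", 10, 80))
        assert len(a.instances) == 1

    def test_out_of_range_feature_rejected(self):
        with pytest.raises(ArchitectureError, match="exceeds"):
            arch("p", 100, ("PFAM:PF1", 10, 101))

    def test_inverted_coordinates_rejected(self):
        with pytest.raises(ArchitectureError, match="invalid coordinates"):
            FeatureInstance("PFAM:PF1", 10, 5)

    def test_instances_kept_ordered_by_start(self):
        a = arch("p", 100, ("TM:helix", 50, 70), ("PFAM:PF1", 5, 40))
        assert [i.start for i in a.instances] == [5, 50]


class TestArchitectureIO:
    def test_fixture_annotations_roundtrip(self, tmp_path, small_fixture):
        path = tmp_path / "arch.json"
        write_architectures(small_fixture.architectures, path)
        again = read_architectures(path)
        assert set(again) == set(small_fixture.architectures)
        for pid, a in small_fixture.architectures.items():
            b = again[pid]
            assert (b.length, b.instances) == (a.length, a.instances)

    def test_unknown_namespace_warned_but_kept(self, tmp_path):
        path = tmp_path / "arch.json"
        write_architectures({"p": arch("p", 50, ("WEIRD:x", 1, 10))}, path)
        with pytest.warns(UserWarning, match="unknown feature namespace"):
            result = read_architectures(path)
        assert result["p"].instances[0].type == "WEIRD:x"


class TestFasScore:
    def test_identical_architectures_score_one(self):
        a = arch("p", 100, ("PFAM:PF_A", 10, 40), ("TM:helix", 50, 90))
        assert fas_score(a, a) == 1.0

    def test_disjoint_type_sets_score_zero_both_directions(self):
        a = arch("p", 100, ("PFAM:PF_A", 10, 40))
        b = arch("q", 100, ("TM:helix", 10, 40))
        assert fas_score(a, b) == 0.0
        assert fas_score(b, a) == 0.0

    def test_missing_reference_domain_halves_forward_score(self):
        # reference {A, B}, query {A perfectly overlapping}: forward 0.5,
        # backward 1.0 — the asymmetry of the score
        a = arch("p", 100, ("PFAM:PF_A", 10, 40), ("PFAM:PF_B", 50, 90))
        b = arch("q", 100, ("PFAM:PF_A", 10, 40))
        assert fas_score(a, b) == pytest.approx(0.5)
        assert fas_score(b, a) == pytest.approx(1.0)

    def test_lost_domain_pattern_direction(self):
        # ortholog lacking one of two reference domains: forward < 1 while
        # backward = 1 when the shared domain overlaps fully
        pair = bidirectional_fas(
            arch("seed", 100, ("PFAM:MFS_1", 5, 50), ("PFAM:ALF_C", 60, 95)),
            arch("orth", 100, ("PFAM:MFS_1", 5, 50)),
        )
        assert pair.fas_f < 1.0
        assert pair.fas_b == pytest.approx(1.0)

    def test_multiplied_domain_pattern_direction(self):
        # ortholog with the reference domain quadruplicated on a longer
        # protein: forward exceeds backward, backward clearly below 1
        seed = arch("seed", 60, ("PFAM:GH28", 6, 55))
        quad = Architecture(
            "orth",
            240,
            [FeatureInstance("PFAM:GH28", 6 + 60 * i, 55 + 60 * i) for i in range(4)],
        )
        pair = bidirectional_fas(seed, quad)
        assert pair.fas_f > pair.fas_b
        assert pair.fas_b < 1.0

    def test_empty_reference_convention(self):
        empty = Architecture("e", 10, [])
        assert fas_score(empty, empty) == 1.0
        assert fas_score(empty, arch("q", 10, ("TM:helix", 1, 5))) == 0.0

    def test_namespace_weights_reweight_types(self):
        a = arch("p", 100, ("PFAM:PF_A", 10, 40), ("TM:helix", 50, 90))
        b = arch("q", 100, ("PFAM:PF_A", 10, 40))
        # down-weighting the missing TM namespace raises the forward score
        assert fas_score(a, b, {"TM": 0.5}) == pytest.approx(1 / 1.5)

    def test_removing_matched_instance_never_raises_score(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            length = 80
            types = [f"PFAM:PF{k}" for k in range(3)] + ["TM:helix"]
            feats = []
            for t in types:
                for _ in range(rng.integers(0, 3)):
                    s = int(rng.integers(1, length - 5))
                    feats.append((t, s, int(rng.integers(s, length))))
            if len(feats) < 2:
                continue
            ref = arch("r", length, *feats)
            qry_feats = [f for f in feats if rng.random() < 0.8]
            if not qry_feats:
                continue
            qry = arch("q", length, *qry_feats)
            full = fas_score(ref, qry)
            reduced = fas_score(ref, arch("q2", length, *qry_feats[:-1]) if len(qry_feats) > 1 else Architecture("q2", length, []))
            assert reduced <= full + 1e-12

    def test_scores_always_within_unit_interval(self):
        rng = np.random.default_rng(5)
        pool = [f"PFAM:PF{k}" for k in range(4)] + ["TM:helix", "SP:signal"]
        for _ in range(2000):
            la, lb = int(rng.integers(20, 200)), int(rng.integers(20, 200))
            def rand_arch(pid, length):
                feats = []
                for _ in range(rng.integers(0, 5)):
                    t = pool[rng.integers(len(pool))]
                    s = int(rng.integers(1, length))
                    feats.append(FeatureInstance(t, s, int(rng.integers(s, length + 1))))
                return Architecture(pid, length, feats)
            a, b = rand_arch("a", la), rand_arch("b", lb)
            assert 0.0 <= fas_score(a, b) <= 1.0
            assert 0.0 <= fas_score(b, a) <= 1.0


class TestFasPair:
    def test_identical_pair(self):
        a = arch("p", 100, ("PFAM:PF_A", 10, 40))
        pair = bidirectional_fas(a, a)
        assert (pair.fas_f, pair.fas_b) == (1.0, 1.0)
        assert pair.mean == 1.0

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ArchitectureError):
            FasPair(1.2, 0.5)


class TestArchitectureDiff:
    def test_identical_architectures_empty_diff(self):
        a = arch("p", 100, ("PFAM:PF_A", 10, 40))
        assert architecture_diff(a, a).empty

    def test_multiplicity_gain_reported(self):
        # three extra instances of a binding motif in the ortholog
        seed = arch("s", 100, ("PFAM:GH9", 40, 90), ("PFAM:CBM", 5, 20))
        orth = arch(
            "o", 130, ("PFAM:GH9", 70, 120), ("PFAM:CBM", 5, 20),
            ("PFAM:CBM", 25, 40), ("PFAM:CBM", 45, 60), ("PFAM:CBM", 61, 69),
        )
        diff = architecture_diff(seed, orth)
        assert diff.multiplicity_changes == {"PFAM:CBM": (1, 4)}
        assert "multiplicity change" in diff.to_text()

    def test_diff_is_type_multiset_difference(self):
        rng = np.random.default_rng(6)
        pool = [f"PFAM:PF{k}" for k in range(3)] + ["TM:helix"]
        for _ in range(100):
            def counts(n):
                return {t: int(rng.integers(0, 3)) for t in pool[: n]}
            ca, cb = counts(4), counts(4)
            def build(pid, cnt):
                feats = []
                for t, n in cnt.items():
                    feats += [(t, 1 + 5 * i, 5 + 5 * i) for i in range(n)]
                return arch(pid, 60, *feats)
            diff = architecture_diff(build("a", ca), build("b", cb))
            for t in pool:
                na, nb = ca.get(t, 0), cb.get(t, 0)
                if na and not nb:
                    assert diff.only_in_seed[t] == na
                elif nb and not na:
                    assert diff.only_in_ortholog[t] == nb
                elif na and nb and na != nb:
                    assert diff.multiplicity_changes[t] == (na, nb)
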