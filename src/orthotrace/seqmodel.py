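"""Protein sequences, pairwise global alignment and the core-group aligner.

The candidate score of the core-compilation phase uses the ratio between the
global alignment score of a candidate against the seed protein and the seed's
self-alignment score (its maximally achievable score).  Alignments use
BLOSUM62 with affine gaps (open 10, extend 1) throughout; these are
conventional defaults for protein search tools.

Evolutionary distances between proteins are Kimura-corrected p-distances,
``d = -ln(1 - p - 0.2 p^2)``, the standard protein variant used by classic
phylogeny packages.  Distances at or beyond the saturation point of the
correction are reported as +infinity.

Core-ortholog groups are aligned with a small deterministic progressive
aligner (neighbor-joining guide tree on pairwise p-distances, profile-profile
merges); a hook allows substituting an external aligner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
GAP = "-"


class SequenceError(ValueError):
    pass


@dataclass(frozen=True)
class Protein:
    """An amino-acid sequence with its identifier and source taxon."""

    id: str
    taxon: int
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise SequenceError(f"protein {self.id}: empty sequence")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise SequenceError(f"protein {self.id}: illegal residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Proteome:
    """All proteins of one taxon; optionally a gene -> isoform map."""

    taxon: int
    proteins: list[Protein] = field(default_factory=list)
    isoform_map: Optional[dict[str, list[str]]] = None

    def __post_init__(self):
        ids = [p.id for p in self.proteins]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SequenceError(f"duplicate protein id(s) {dupes} in proteome {self.taxon}")
        self._index = {p.id: p for p in self.proteins}

    def __iter__(self):
        return iter(self.proteins)

    def __len__(self) -> int:
        return len(self.proteins)

    def __contains__(self, pid: str) -> bool:
        return pid in self._index

    def get(self, pid: str) -> Protein:
        return self._index[pid]


# ----------------------------------------------------------------- FASTA I/O


def read_fasta(path, taxon: int = 0) -> Proteome:
    """Read a protein FASTA file into a :class:`Proteome`.

    The first whitespace-delimited token of each description line is the
    protein id.  Residues are uppercased on read.
    """
    proteins = []
    for rec in SeqIO.parse(str(path), "fasta"):
        proteins.append(Protein(rec.id, taxon, str(rec.seq).upper()))
    if not proteins:
        raise SequenceError(f"no FASTA records in {path}")
    return Proteome(taxon, proteins)


def write_fasta(records: Iterable[Protein], path) -> None:
    seqrecords = [
        SeqRecord(Seq(p.residues), id=p.id, description="") for p in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


# ------------------------------------------------------------------ alignment


@dataclass(frozen=True)
class ScoringParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0


@dataclass
class AlignmentResult:
    score: float
    aligned_a: str
    aligned_b: str
    p_distance: float


_ALIGNER_CACHE: dict[ScoringParams, PairwiseAligner] = {}


def _aligner(params: ScoringParams) -> PairwiseAligner:
    aligner = _ALIGNER_CACHE.get(params)
    if aligner is None:
        aligner = PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load(params.matrix)
        aligner.open_gap_score = -params.gap_open
        aligner.extend_gap_score = -params.gap_extend
        aligner.mode = "global"
        _ALIGNER_CACHE[params] = aligner
    return aligner


def _p_distance(aligned_a: str, aligned_b: str) -> float:
    pairs = [(x, y) for x, y in zip(aligned_a, aligned_b) if x != GAP and y != GAP]
    if not pairs:
        return 1.0
    mismatches = sum(1 for x, y in pairs if x != y)
    return mismatches / len(pairs)


def global_align(a: Protein | str, b: Protein | str, params: ScoringParams = ScoringParams()) -> AlignmentResult:
    """Optimal global alignment of two proteins under affine gap penalties.

    Deterministic: the first optimal traceback reported by the aligner is
    used, which prefers aligned residue pairs over gaps at equal score.
    """
    sa = a.residues if isinstance(a, Protein) else a
    sb = b.residues if isinstance(b, Protein) else b
    aln = _aligner(params).align(sa, sb)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return AlignmentResult(float(aln.score), ga, gb, _p_distance(ga, gb))


def pairwise_score(a: Protein | str, b: Protein | str, params: ScoringParams = ScoringParams()) -> float:
    """Alignment score only (no traceback); faster than :func:`global_align`."""
    sa = a.residues if isinstance(a, Protein) else a
    sb = b.residues if isinstance(b, Protein) else b
    return float(_aligner(params).score(sa, sb))


def self_score(a: Protein | str, params: ScoringParams = ScoringParams()) -> float:
    """Maximally achievable alignment score of a sequence (against itself)."""
    return pairwise_score(a, a, params)


# --------------------------------------------------------------- Kimura distance


def kimura_from_p(p: float) -> float:
    """Kimura's protein-distance correction of a p-distance.

    ``d = -ln(1 - p - 0.2 p^2)``; returns +inf when the correction is
    saturated (argument of the logarithm <= 0), so saturated distances lose
    every minimum-distance comparison.
    """
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0.0:
        return math.inf
    return -math.log(arg) + 0.0  # avoid negative zero at p = 0


def kimura_distance(aln: AlignmentResult) -> float:
    """Kimura protein distance of an alignment (gap columns excluded)."""
    return kimura_from_p(aln.p_distance)


def kimura_between(a: Protein | str, b: Protein | str, params: ScoringParams = ScoringParams()) -> float:
    return kimura_distance(global_align(a, b, params))


# ------------------------------------------------------- multiple alignment


@dataclass
class Alignment:
    """A multiple sequence alignment as (id, gapped sequence) rows."""

    rows: list[tuple[str, str]]

    def __post_init__(self):
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise SequenceError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def sequences(self) -> list[str]:
        return [s for _, s in self.rows]

    def write_fasta(self, path) -> None:
        SeqIO.write(
            [SeqRecord(Seq(s), id=i, description="") for i, s in self.rows],
            str(path),
            "fasta",
        )


_PROFILE_GAP = 4.0  # linear per-column gap cost for profile-profile merges

_AA_ORDER = {aa: i for i, aa in enumerate(AMINO_ACIDS + "X")}


def _profile_counts(profile: list[tuple[str, str]]) -> np.ndarray:
    """Residue counts per column, shape (L, 21); gaps are not counted."""
    length = len(profile[0][1])
    counts = np.zeros((length, len(_AA_ORDER)))
    for _, seq in profile:
        for j, ch in enumerate(seq):
            if ch != GAP:
                counts[j, _AA_ORDER[ch]] += 1
    return counts


def _substitution_array(matrix) -> np.ndarray:
    letters = AMINO_ACIDS + "X"
    return np.array([[matrix[x, y] for y in letters] for x in letters])


def _merge_profiles(pa: list[tuple[str, str]], pb: list[tuple[str, str]], sub: np.ndarray) -> list[tuple[str, str]]:
    """Needleman-Wunsch on profile columns with a linear gap cost.

    The column score is the mean substitution score over residue pairs
    (gap-containing pairs excluded), computed for all column pairs at once
    as a count-matrix product.
    """
    ca, cb = _profile_counts(pa), _profile_counts(pb)
    la, lb = ca.shape[0], cb.shape[0]
    pair_counts = np.outer(ca.sum(axis=1), cb.sum(axis=1))
    with np.errstate(invalid="ignore"):
        colscore = np.where(pair_counts > 0, (ca @ sub @ cb.T) / pair_counts, 0.0)
    score = np.zeros((la + 1, lb + 1))
    ptr = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up(gap in b), 2 left(gap in a)
    score[:, 0] = -_PROFILE_GAP * np.arange(la + 1)
    score[0, :] = -_PROFILE_GAP * np.arange(lb + 1)
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, la + 1):
        row_prev = score[i - 1]
        row = score[i]
        cs = colscore[i - 1]
        for j in range(1, lb + 1):
            diag = row_prev[j - 1] + cs[j - 1]
            up = row_prev[j] - _PROFILE_GAP
            left = row[j - 1] - _PROFILE_GAP
            best = diag if diag >= up else up
            if left > best:
                best = left
            row[j] = best
            ptr[i, j] = 0 if best == diag else (1 if best == up else 2)
    # traceback
    path = []
    i, j = la, lb
    while i > 0 or j > 0:
        move = ptr[i, j]
        path.append(move)
        if move == 0:
            i, j = i - 1, j - 1
        elif move == 1:
            i -= 1
        else:
            j -= 1
    path.reverse()
    out_a = {k: [] for k, _ in pa}
    out_b = {k: [] for k, _ in pb}
    ia = jb = 0
    for move in path:
        if move in (0, 1):
            for (k, s) in pa:
                out_a[k].append(s[ia])
            ia += 1
        else:
            for (k, s) in pa:
                out_a[k].append(GAP)
        if move in (0, 2):
            for (k, s) in pb:
                out_b[k].append(s[jb])
            jb += 1
        else:
            for (k, s) in pb:
                out_b[k].append(GAP)
    merged = [(k, "".join(out_a[k])) for k, _ in pa]
    merged += [(k, "".join(out_b[k])) for k, _ in pb]
    return merged


def _nj_merge_order(dist: np.ndarray) -> list[tuple[int, int]]:
    """Neighbor-joining agglomeration order on a distance matrix.

    Returns the sequence of (i, j) cluster-index joins; new clusters get the
    next free index.  Ties are broken by the smaller index pair, which makes
    the guide tree deterministic.
    """
    n = dist.shape[0]
    active = list(range(n))
    d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(n) if i < j}

    def get(i, j):
        return d[(i, j) if i < j else (j, i)]

    joins = []
    nxt = n
    while len(active) > 2:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best, pair = None, None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * get(i, j) - r[i] - r[j]
                if best is None or q < best - 1e-12:
                    best, pair = q, (i, j)
        i, j = pair
        dij = get(i, j)
        for k in active:
            if k in (i, j):
                continue
            d[(min(k, nxt), max(k, nxt))] = 0.5 * (get(i, k) + get(j, k) - dij)
        joins.append((i, j))
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    if len(active) == 2:
        joins.append((active[0], active[1]))
    return joins


def align_core_group(
    seqs: Sequence[Protein],
    params: ScoringParams = ScoringParams(),
    aligner_hook: Optional[Callable[[Sequence[Protein]], Alignment]] = None,
) -> Alignment:
    """Progressively align a core-ortholog group.

    Guide tree: neighbor joining on pairwise p-distances from global
    alignments; clusters are merged by profile-profile alignment.  The result
    is deterministic for a fixed input order.  ``aligner_hook`` substitutes an
    external multiple aligner with the same contract.
    """
    if aligner_hook is not None:
        return aligner_hook(seqs)
    if not seqs:
        raise SequenceError("cannot align an empty sequence set")
    if len(seqs) == 1:
        return Alignment([(seqs[0].id, seqs[0].residues)])
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = global_align(seqs[i], seqs[j], params).p_distance
    sub = _substitution_array(substitution_matrices.load(params.matrix))
    profiles: dict[int, list[tuple[str, str]]] = {
        i: [(p.id, p.residues)] for i, p in enumerate(seqs)
    }
    nxt = n
    for i, j in _nj_merge_order(dist):
        profiles[nxt] = _merge_profiles(profiles.pop(i), profiles.pop(j), sub)
        nxt += 1
    (merged,) = profiles.values()
    order = {p.id: k for k, p in enumerate(seqs)}
    merged.sort(key=lambda row: order[row[0]])
    return Alignment(merged)


def sum_of_pairs_score(aln: Alignment, params: ScoringParams = ScoringParams()) -> float:
    """Sum-of-pairs substitution score of an alignment (gap pairs score 0)."""
    matrix = substitution_matrices.load(params.matrix)
    seqs = aln.sequences()
    total = 0.0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            for x, y in zip(seqs[i], seqs[j]):
                if x != GAP and y != GAP:
                    total += matrix[x, y]
    return total
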