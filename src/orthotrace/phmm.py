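"""Profile hidden Markov models: training from a core-group alignment and
log-odds search against proteomes.

The model follows a Plan-7-like topology: one match, insert and delete state
per alignment column that qualifies as a match column (at most 50% gaps),
with local entry and exit.  Local alignment uses the uniform-fragment
convention: a homologous fragment may start at any match state and end at any
later match state, each of the ``L(L+1)/2`` fragments carrying prior weight
``2/(L(L+1))``; sequence outside the fragment, and insert-state residues,
emit from the background distribution and therefore cancel in the log-odds.

Match emissions and transitions are maximum-likelihood estimates from the
training alignment with Laplace pseudocounts (emission weight configurable,
default 1; one pseudo-observation per allowed transition).  Scores are
reported in bits against a uniform residue background.  Both the forward
(sum over paths) and Viterbi (best path) scores are available; hit lists use
the forward score.

A backend hook on :func:`search_phmm` allows delegating the search to an
external HMM engine with the same hit contract.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .seqmodel import GAP, AMINO_ACIDS, Alignment, Proteome

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_N_AA = len(AMINO_ACIDS)

_TRANSITION_KEYS = ("MM", "MI", "MD", "IM", "II", "ID", "DM", "DI", "DD")
_SOURCE_GROUPS = {"M": ("MM", "MI", "MD"), "I": ("IM", "II", "ID"), "D": ("DM", "DI", "DD")}

_NEG = -np.inf


class PhmmError(ValueError):
    pass


@dataclass
class ProfileHMM:
    """A trained profile HMM over the 20-letter amino-acid alphabet.

    ``match_emissions`` has shape (L, 20); ``transitions`` maps each of the
    nine transition kinds to a length-L array indexed by the source column.
    Every emission row and per-source outgoing-transition triple sums to 1.
    """

    match_emissions: np.ndarray
    transitions: dict[str, np.ndarray]
    trained_from: str = ""
    pseudocount: float = 1.0
    background: np.ndarray = field(default_factory=lambda: np.full(_N_AA, 1.0 / _N_AA))

    def __post_init__(self):
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        if self.match_emissions.ndim != 2 or self.match_emissions.shape[1] != _N_AA:
            raise PhmmError("match_emissions must have shape (L, 20)")
        if self.length < 1:
            raise PhmmError("a profile HMM needs at least one match column")
        self.transitions = {k: np.asarray(v, dtype=float) for k, v in self.transitions.items()}
        self._log_cache: Optional[dict] = None

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    # -------------------------------------------------------------- serialization

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema": "orthotrace-phmm-1",
                "alphabet": AMINO_ACIDS,
                "length": self.length,
                "trained_from": self.trained_from,
                "pseudocount": self.pseudocount,
                "match_emissions": self.match_emissions.tolist(),
                "transitions": {k: v.tolist() for k, v in self.transitions.items()},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ProfileHMM":
        payload = json.loads(text)
        return cls(
            match_emissions=np.array(payload["match_emissions"]),
            transitions={k: np.array(v) for k, v in payload["transitions"].items()},
            trained_from=payload.get("trained_from", ""),
            pseudocount=payload.get("pseudocount", 1.0),
        )

    # ---------------------------------------------------------------- scoring

    def _logs(self) -> dict:
        if self._log_cache is None:
            with np.errstate(divide="ignore"):
                logem = np.log(self.match_emissions / self.background)  # log-odds
                tr = {k: np.log(v) for k, v in self.transitions.items()}
            L = self.length
            self._log_cache = {
                "em": logem,
                "tr": tr,
                "entry": math.log(2.0 / (L * (L + 1))),
                "cum_dd": np.concatenate(([0.0], np.cumsum(tr["DD"][:-1]))),
            }
        return self._log_cache

    def _score_rows(self, batch: list[str]) -> np.ndarray:
        """Per-residue match log-odds, shape (k, n, L) for k equal-length
        sequences of length n."""
        logem = self._logs()["em"]
        k, n = len(batch), len(batch[0])
        rows = np.zeros((k, n, L := self.length))
        for s, residues in enumerate(batch):
            for i, aa in enumerate(residues):
                idx = _AA_INDEX.get(aa)
                if idx is not None:
                    rows[s, i] = logem[:, idx]
        return rows

    def _dp_batch(self, batch: list[str], viterbi: bool) -> np.ndarray:
        """Shared forward/Viterbi recursion over equal-length sequences;
        returns log-odds in nats, shape (k,)."""
        logs = self._logs()
        tr, entry = logs["tr"], logs["entry"]
        cum_dd = logs["cum_dd"]
        S = self._score_rows(batch)
        k, n, L = S.shape
        combine = np.maximum if viterbi else np.logaddexp

        def reduce_cols(x):  # (k, L) -> (k,)
            if viterbi:
                return np.max(x, axis=1)
            m = np.max(x, axis=1, keepdims=True)
            return (m + np.log(np.sum(np.exp(x - m), axis=1, keepdims=True)))[:, 0]

        M_prev = S[:, 0, :] + entry
        I_prev = np.full((k, L), _NEG)
        D_prev = _delete_scan(M_prev, I_prev, tr, cum_dd, viterbi)
        total = reduce_cols(M_prev)
        for i in range(1, n):
            cont = combine(
                combine(M_prev[:, :-1] + tr["MM"][:-1], I_prev[:, :-1] + tr["IM"][:-1]),
                D_prev[:, :-1] + tr["DM"][:-1],
            )
            M_row = np.empty((k, L))
            M_row[:, 0] = entry
            M_row[:, 1:] = combine(cont, entry)
            M_row += S[:, i, :]
            I_row = combine(
                combine(M_prev + tr["MI"], I_prev + tr["II"]), D_prev + tr["DI"]
            )
            D_row = _delete_scan(M_row, I_row, tr, cum_dd, viterbi)
            total = combine(total, reduce_cols(M_row))
            M_prev, I_prev, D_prev = M_row, I_row, D_row
        return total

    def score_batch(self, sequences: list[str], viterbi: bool = False) -> np.ndarray:
        """Log-odds scores in bits for arbitrary sequences (internally
        batched by length for speed)."""
        out = np.empty(len(sequences))
        by_len: dict[int, list[int]] = {}
        for i, s in enumerate(sequences):
            by_len.setdefault(len(s), []).append(i)
        for _, idxs in sorted(by_len.items()):
            scores = self._dp_batch([sequences[i] for i in idxs], viterbi)
            out[idxs] = scores / math.log(2)
        return out

    def forward_bits(self, residues: str) -> float:
        """Forward log-odds score (sum over all alignments), in bits."""
        return float(self._dp_batch([residues], viterbi=False)[0]) / math.log(2)

    def viterbi_bits(self, residues: str) -> float:
        """Best-path log-odds score, in bits; never exceeds the forward score."""
        return float(self._dp_batch([residues], viterbi=True)[0]) / math.log(2)


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    if m == _NEG:
        return _NEG
    return m + math.log(np.sum(np.exp(x - m)))


def _delete_scan(M_row: np.ndarray, I_row: np.ndarray, tr, cum_dd, viterbi: bool) -> np.ndarray:
    """In-row delete recursion D[m] = op(A[m-1], D[m-1] + tDD[m-1]) as a scan.

    With c[m] the cumulative tDD log-probability, h[m] = D[m] - c[m] is a
    running accumulate of A[m-1] - c[m], so each whole row is one
    ``logaddexp``/``maximum`` accumulate.  Rows are (k, L) batches.
    """
    k, L = M_row.shape
    combine = np.maximum if viterbi else np.logaddexp
    A = combine(M_row + tr["MD"], I_row + tr["ID"])
    u = np.empty((k, L))
    u[:, 0] = _NEG
    u[:, 1:] = A[:, :-1] - cum_dd[1:]
    acc = (
        np.maximum.accumulate(u, axis=1)
        if viterbi
        else np.logaddexp.accumulate(u, axis=1)
    )
    return acc + cum_dd


# ------------------------------------------------------------------- training


def match_columns(msa: Alignment) -> list[int]:
    """Indices of alignment columns with at most 50% gap characters."""
    seqs = msa.sequences()
    n = len(seqs)
    cols = []
    for j in range(msa.length):
        gaps = sum(1 for s in seqs if s[j] == GAP)
        if gaps / n <= 0.5:
            cols.append(j)
    return cols


def _state_path(row: str, match_cols: list[int]) -> list[tuple[str, int]]:
    is_match = {j: m for m, j in enumerate(match_cols)}
    path: list[tuple[str, int]] = []
    last_match = -1
    for j, ch in enumerate(row):
        if j in is_match:
            m = is_match[j]
            path.append(("M" if ch != GAP else "D", m))
            last_match = m
        elif ch != GAP:
            path.append(("I", last_match))
    return path


#: transition pseudo-observations, shaped like the usual profile-HMM prior:
#: staying on the match path is strongly favoured a priori, so that sparse
#: training alignments do not pay a per-column gap-open tax on the log-odds.
_TRANSITION_PRIOR = {
    "MM": 0.90, "MI": 0.05, "MD": 0.05,
    "IM": 0.70, "II": 0.20, "ID": 0.10,
    "DM": 0.70, "DD": 0.20, "DI": 0.10,
}


def train_phmm(
    msa: Alignment,
    pseudocount_weight: float = 1.0,
    transition_pseudocount: float = 1.0,
) -> ProfileHMM:
    """Train a profile HMM from a multiple alignment.

    Match columns are those with at most 50% gaps.  Emission probabilities
    are Laplace-smoothed relative frequencies over the 20-letter alphabet,
    e.g. a column observing A/A/C with pseudocount 1 yields P(A) = 3/23 and
    P(C) = 2/23.  With a single-row alignment the match emissions are the
    pseudocount-smoothed one-hot residues of that sequence.  Transitions
    receive ``transition_pseudocount`` pseudo-observations distributed
    according to a match-favouring prior.
    """
    cols = match_columns(msa)
    if not cols:
        raise PhmmError("alignment has no match columns (every column >50% gaps)")
    L = len(cols)
    em_counts = np.zeros((L, _N_AA))
    tr_counts = {k: np.zeros(L) for k in _TRANSITION_KEYS}
    for _, row in msa.rows:
        path = _state_path(row, cols)
        # emissions
        residues = [ch for ch in row if ch != GAP]
        ri = 0
        for state, m in path:
            if state in ("M", "I"):
                ch = residues[ri]
                ri += 1
                if state == "M" and ch in _AA_INDEX:
                    em_counts[m, _AA_INDEX[ch]] += 1
        # transitions (begin/end excluded; inserts before the first match too)
        for (s1, m1), (s2, m2) in zip(path, path[1:]):
            if m1 < 0:
                continue
            tr_counts[s1 + s2][m1] += 1
    w = pseudocount_weight
    emissions = (em_counts + w) / (em_counts.sum(axis=1, keepdims=True) + w * _N_AA)
    transitions = {}
    raw = {
        k: tr_counts[k] + transition_pseudocount * _TRANSITION_PRIOR[k]
        for k in _TRANSITION_KEYS
    }
    for src, keys in _SOURCE_GROUPS.items():
        denom = sum(raw[k] for k in keys)
        for k in keys:
            transitions[k] = raw[k] / denom
    row_ids = ",".join(i for i, _ in msa.rows)
    return ProfileHMM(emissions, transitions, trained_from=row_ids, pseudocount=w)


# --------------------------------------------------------------------- search


@dataclass(frozen=True)
class HmmHit:
    protein: str
    taxon: int
    log_odds: float  # bits, forward score
    rank: int


def search_phmm(
    hmm: ProfileHMM,
    proteome: Proteome,
    bit_threshold: float = 10.0,
    backend: Optional[Callable[[ProfileHMM, Proteome, float], list[HmmHit]]] = None,
) -> list[HmmHit]:
    """Score every protein of a proteome against the profile.

    Returns hits with forward log-odds at or above ``bit_threshold``, sorted
    by decreasing score (ties by protein id) with consecutive 1-based ranks.
    """
    if backend is not None:
        return backend(hmm, proteome, bit_threshold)
    proteins = list(proteome)
    bits = hmm.score_batch([p.residues for p in proteins])
    scored = [(float(b), p.id) for b, p in zip(bits, proteins) if b >= bit_threshold]
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [
        HmmHit(pid, proteome.taxon, bits, rank)
        for rank, (bits, pid) in enumerate(scored, start=1)
    ]
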