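"""Protein feature architectures and the architecture similarity score (FAS).

A feature architecture is the ordered list of annotated feature instances
(Pfam/SMART domains, transmembrane helices, signal peptides, coiled coils,
low-complexity regions) along a protein.  Annotations are consumed
pre-computed from a versioned JSON layout; this package never runs the
underlying annotation tools.

The similarity score implemented here is a documented surrogate for the
published FAS algorithm, preserving its contract: it is asymmetric (the sum
runs over the feature types of the *reference* architecture only), bounded in
[0, 1], equals 1 for identical architectures and 0 when no reference feature
type occurs in the query.  For each reference type ``t`` the type score is

    s(t) = min(n_ref(t), n_qry(t)) / n_ref(t)  *  mean best-pair overlap,

where the overlap of two instances is the Jaccard index of their residue
intervals after linear normalization by protein length, and the mean runs
over the ``min(n_ref, n_qry)`` best reference-instance matches.  The final
score is the weight-normalized sum over reference types; weights are
per-namespace (the prefix before ``:``) and default to 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

KNOWN_NAMESPACES = {"PFAM", "SMART", "TM", "SP", "COILS", "LCR", "FLPS"}

ARCHITECTURE_SCHEMA_VERSION = 1


class ArchitectureError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureInstance:
    """One feature occurrence: namespaced type and 1-based inclusive coords."""

    type: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ArchitectureError(
                f"feature {self.type}: invalid coordinates [{self.start}, {self.end}]"
            )

    @property
    def namespace(self) -> str:
        return self.type.split(":", 1)[0]


@dataclass
class Architecture:
    protein: str
    length: int
    instances: list[FeatureInstance] = field(default_factory=list)

    def __post_init__(self):
        if self.length < 1:
            raise ArchitectureError(f"{self.protein}: non-positive length")
        for inst in self.instances:
            if inst.end > self.length:
                raise ArchitectureError(
                    f"{self.protein}: feature {inst.type} end {inst.end} "
                    f"exceeds protein length {self.length}"
                )
        self.instances = sorted(self.instances, key=lambda i: (i.start, i.end, i.type))

    def types(self) -> dict[str, list[FeatureInstance]]:
        by_type: dict[str, list[FeatureInstance]] = {}
        for inst in self.instances:
            by_type.setdefault(inst.type, []).append(inst)
        return by_type


# ----------------------------------------------------------------------- I/O


def read_architectures(path) -> dict[str, Architecture]:
    """Read an architecture JSON file into a map protein-id -> Architecture.

    Features with an unknown namespace are kept with a warning.
    """
    with open(path) as fh:
        payload = json.load(fh)
    out: dict[str, Architecture] = {}
    for entry in payload["architectures"]:
        instances = [
            FeatureInstance(f["type"], int(f["start"]), int(f["end"]))
            for f in entry.get("features", [])
        ]
        for inst in instances:
            if inst.namespace not in KNOWN_NAMESPACES:
                warnings.warn(
                    f"unknown feature namespace {inst.namespace!r} on {entry['protein']}; kept",
                    stacklevel=2,
                )
        out[entry["protein"]] = Architecture(entry["protein"], int(entry["length"]), instances)
    return out


def write_architectures(architectures: Mapping[str, Architecture], path) -> None:
    payload = {
        "version": ARCHITECTURE_SCHEMA_VERSION,
        "architectures": [
            {
                "protein": arch.protein,
                "length": arch.length,
                "features": [
                    {"type": i.type, "start": i.start, "end": i.end}
                    for i in arch.instances
                ],
            }
            for _, arch in sorted(architectures.items())
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


# -------------------------------------------------------------------- scoring


def _interval_jaccard(a: FeatureInstance, la: int, b: FeatureInstance, lb: int) -> float:
    # residue intervals on length-normalized [0, 1] coordinates
    a0, a1 = (a.start - 1) / la, a.end / la
    b0, b1 = (b.start - 1) / lb, b.end / lb
    inter = max(0.0, min(a1, b1) - max(a0, b0))
    union = max(a1, b1) - min(a0, b0)
    return inter / union if union > 0 else 0.0


def _namespace_weight(feature_type: str, weights: Optional[Mapping[str, float]]) -> float:
    if not weights:
        return 1.0
    return float(weights.get(feature_type.split(":", 1)[0], 1.0))


def fas_score(
    reference: Architecture,
    query: Architecture,
    weights: Optional[Mapping[str, float]] = None,
) -> float:
    """Architecture similarity of ``query`` measured against ``reference``.

    Asymmetric by construction: only feature types of the reference
    contribute.  An empty reference scores 1 against an empty query and 0
    otherwise.  The result is clamped to [0, 1].
    """
    ref_types = reference.types()
    if not ref_types:
        return 1.0 if not query.instances else 0.0
    qry_types = query.types()
    num = den = 0.0
    for ftype, ref_insts in ref_types.items():
        w = _namespace_weight(ftype, weights)
        den += w
        qry_insts = qry_types.get(ftype)
        if not qry_insts:
            continue
        n_ref, n_qry = len(ref_insts), len(qry_insts)
        multiplicity = min(n_ref, n_qry) / n_ref
        best = sorted(
            (
                max(
                    _interval_jaccard(r, reference.length, q, query.length)
                    for q in qry_insts
                )
                for r in ref_insts
            ),
            reverse=True,
        )[: min(n_ref, n_qry)]
        positional = sum(best) / len(best)
        num += w * multiplicity * positional
    score = num / den if den > 0 else 0.0
    return min(1.0, max(0.0, score))


@dataclass(frozen=True)
class FasPair:
    """Bidirectional architecture similarity: seed-as-reference (forward)
    and ortholog-as-reference (backward)."""

    fas_f: float
    fas_b: float

    def __post_init__(self):
        for v in (self.fas_f, self.fas_b):
            if not (0.0 <= v <= 1.0):
                raise ArchitectureError(f"FAS score {v} outside [0, 1]")

    @property
    def mean(self) -> float:
        return 0.5 * (self.fas_f + self.fas_b)


def bidirectional_fas(
    seed: Architecture,
    ortholog: Architecture,
    weights: Optional[Mapping[str, float]] = None,
) -> FasPair:
    """FAS in both directions, using in turn the seed and the ortholog as
    the reference architecture."""
    return FasPair(
        fas_f=fas_score(seed, ortholog, weights),
        fas_b=fas_score(ortholog, seed, weights),
    )


# ----------------------------------------------------------------------- diff


@dataclass
class ArchitectureDiff:
    """Feature gains, losses and multiplicity changes between two proteins."""

    seed: str
    ortholog: str
    only_in_seed: dict[str, int]
    only_in_ortholog: dict[str, int]
    multiplicity_changes: dict[str, tuple[int, int]]  # type -> (n_seed, n_ortholog)

    @property
    def empty(self) -> bool:
        return not (self.only_in_seed or self.only_in_ortholog or self.multiplicity_changes)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "ortholog": self.ortholog,
                "only_in_seed": self.only_in_seed,
                "only_in_ortholog": self.only_in_ortholog,
                "multiplicity_changes": {
                    t: {"seed": a, "ortholog": b}
                    for t, (a, b) in self.multiplicity_changes.items()
                },
            },
            indent=1,
        )

    def to_text(self) -> str:
        if self.empty:
            return f"{self.seed} vs {self.ortholog}: identical feature architectures"
        lines = [f"{self.seed} vs {self.ortholog}:"]
        for t, n in sorted(self.only_in_seed.items()):
            lines.append(f"  lost in ortholog: {t} (x{n})")
        for t, n in sorted(self.only_in_ortholog.items()):
            lines.append(f"  gained in ortholog: {t} (x{n})")
        for t, (a, b) in sorted(self.multiplicity_changes.items()):
            lines.append(f"  multiplicity change: {t} {a} -> {b}")
        return "\n".join(lines)


def architecture_diff(seed: Architecture, ortholog: Architecture) -> ArchitectureDiff:
    """Structured report of feature-type differences between two architectures.

    Consistent with the directional score semantics: a type listed under
    ``only_in_seed`` depresses the forward score, one under
    ``only_in_ortholog`` the backward score.
    """
    ts = {t: len(v) for t, v in seed.types().items()}
    to = {t: len(v) for t, v in ortholog.types().items()}
    only_s = {t: n for t, n in ts.items() if t not in to}
    only_o = {t: n for t, n in to.items() if t not in ts}
    mult = {
        t: (ts[t], to[t])
        for t in ts.keys() & to.keys()
        if ts[t] != to[t]
    }
    return ArchitectureDiff(seed.protein, ortholog.protein, only_s, only_o, mult)
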