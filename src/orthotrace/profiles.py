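"""Feature-architecture-aware phylogenetic profiles: assembly, filtering,
binarization, 2-D embedding and paralog-representative selection.

A profile matrix holds, for every (seed, taxon) pair, the list of accepted
ortholog records with their bidirectional architecture similarity (FAS)
scores.  The FAS scores allow post-hoc stringency filtering (forward,
backward or mean direction), binarization into presence/absence vectors
(default: at least one ortholog with mean FAS >= 0.3), and a UMAP embedding
of taxa by repertoire similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ortholog_search import OrthologRecord
from .taxonomy import TaxonomyTree, taxonomic_distance

FAS_MODES = ("forward", "backward", "mean")


def _record_fas(record: OrthologRecord, mode: str) -> float:
    if record.fas is None:
        return 0.0
    if mode == "forward":
        return record.fas.fas_f
    if mode == "backward":
        return record.fas.fas_b
    if mode == "mean":
        return record.fas.mean
    raise ValueError(f"unknown FAS mode {mode!r}; expected one of {FAS_MODES}")


@dataclass
class ProfileMatrix:
    seeds: list[str]
    taxa: list[int]
    cells: dict[tuple[str, int], list[OrthologRecord]] = field(default_factory=dict)

    def __post_init__(self):
        for (seed, taxon), records in self.cells.items():
            for r in records:
                if r.seed != seed or r.taxon != taxon:
                    raise ValueError(
                        f"record {r.protein} filed under ({seed}, {taxon}) "
                        f"but references ({r.seed}, {r.taxon})"
                    )

    @classmethod
    def from_records(
        cls,
        records: Iterable[OrthologRecord],
        seeds: Optional[Sequence[str]] = None,
        taxa: Optional[Sequence[int]] = None,
    ) -> "ProfileMatrix":
        records = list(records)
        seeds = list(seeds) if seeds is not None else sorted({r.seed for r in records})
        taxa = list(taxa) if taxa is not None else sorted({r.taxon for r in records})
        cells: dict[tuple[str, int], list[OrthologRecord]] = {}
        for r in records:
            cells.setdefault((r.seed, r.taxon), []).append(r)
        return cls(seeds, taxa, cells)

    def records(self, seed: str, taxon: int) -> list[OrthologRecord]:
        return self.cells.get((seed, taxon), [])

    def all_records(self) -> list[OrthologRecord]:
        out = []
        for seed in self.seeds:
            for taxon in self.taxa:
                out.extend(self.records(seed, taxon))
        return out


def filter_by_fas(matrix: ProfileMatrix, threshold: float, mode: str = "mean") -> ProfileMatrix:
    """Drop records whose selected FAS score is below ``threshold``.

    ``mode`` selects the seed-as-reference score ("forward"), the
    ortholog-as-reference score ("backward") or their mean.  Idempotent and
    monotone in the threshold.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    cells = {}
    for key, records in matrix.cells.items():
        kept = [r for r in records if _record_fas(r, mode) >= threshold]
        if kept:
            cells[key] = kept
    return ProfileMatrix(list(matrix.seeds), list(matrix.taxa), cells)


def binarize(matrix: ProfileMatrix, fas_min: float = 0.3, mode: str = "mean") -> pd.DataFrame:
    """Presence/absence matrix: taxa rows, seed columns, 1 iff the cell holds
    at least one record with selected FAS score >= ``fas_min``."""
    data = np.zeros((len(matrix.taxa), len(matrix.seeds)), dtype=int)
    for j, seed in enumerate(matrix.seeds):
        for i, taxon in enumerate(matrix.taxa):
            if any(_record_fas(r, mode) >= fas_min for r in matrix.records(seed, taxon)):
                data[i, j] = 1
    return pd.DataFrame(data, index=list(matrix.taxa), columns=list(matrix.seeds))


@dataclass
class EmbeddingResult:
    coordinates: dict[int, tuple[float, float]]
    n_neighbors: int
    min_dist: float
    metric: str
    rng_seed: int

    def frame(self) -> pd.DataFrame:
        rows = [(t, x, y) for t, (x, y) in self.coordinates.items()]
        return pd.DataFrame(rows, columns=["taxon", "x", "y"])


def embed(
    binary: pd.DataFrame,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    metric: str = "jaccard",
    rng_seed: int = 42,
) -> EmbeddingResult:
    """Project binary repertoire vectors into 2-D with UMAP.

    Deterministic for a fixed ``rng_seed``: the embedding is computed on the
    distinct repertoire patterns (duplicate rows make stock UMAP's
    nearest-neighbour graph order-dependent), and taxa sharing a pattern
    receive identical coordinates.  The neighbour count is clamped (with a
    warning) when fewer patterns than neighbours are supplied.
    """
    import umap  # deferred: heavy import

    n = len(binary)
    if n < 2:
        raise ValueError("embedding needs at least two taxa")
    data = binary.to_numpy(dtype=float)
    patterns, inverse = np.unique(data, axis=0, return_inverse=True)
    n_unique = patterns.shape[0]
    if n_unique < 2:
        warnings.warn("all repertoire vectors identical; placing all taxa at the origin")
        coords = np.zeros((n, 2))
        eff_neighbors = 0
    else:
        eff_neighbors = n_neighbors
        if eff_neighbors >= n_unique:
            eff_neighbors = n_unique - 1
            warnings.warn(
                f"n_neighbors={n_neighbors} clamped to {eff_neighbors} "
                f"for {n_unique} distinct patterns",
                stacklevel=2,
            )
        reducer = umap.UMAP(
            n_neighbors=eff_neighbors,
            min_dist=min_dist,
            metric=metric,
            random_state=rng_seed,
            n_components=2,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # umap chatters about exact metrics
            coords = reducer.fit_transform(patterns)[inverse]
    coordinates = {
        taxon: (float(x), float(y)) for taxon, (x, y) in zip(binary.index, coords)
    }
    return EmbeddingResult(coordinates, eff_neighbors, min_dist, metric, rng_seed)


# ---------------------------------------------------- paralog representatives


@dataclass
class ParalogCall:
    representative: str
    origin_taxon: Optional[int]  # None: duplication within the seed species

    @property
    def origin_label(self) -> str:
        return "within seed species" if self.origin_taxon is None else str(self.origin_taxon)


def select_paralog_representative(
    paralog_seeds: Sequence[str],
    matrix: ProfileMatrix,
    tree: TaxonomyTree,
    focal_lineage: int,
    seed_taxon: int,
) -> ParalogCall:
    """Date a seed-gene duplication and pick a representative seed.

    Walking target taxa outward from the seed species, the duplication origin
    is approximated by the closest relative in which one target protein is an
    ortholog of at least two of the paralogous seeds.  The representative is
    the seed with the most ortholog-bearing taxa below ``focal_lineage``
    (ties by seed id).
    """
    if len(paralog_seeds) < 2:
        raise ValueError("need at least two paralogous seeds")
    taxa = sorted(
        (t for t in matrix.taxa if t != seed_taxon),
        key=lambda t: (taxonomic_distance(tree, seed_taxon, t), t),
    )
    origin: Optional[int] = None
    for taxon in taxa:
        shared: dict[str, int] = {}
        for seed in paralog_seeds:
            for r in matrix.records(seed, taxon):
                shared[r.protein] = shared.get(r.protein, 0) + 1
        if any(n >= 2 for n in shared.values()):
            origin = taxon
            break
    focal_taxa = [t for t in matrix.taxa if focal_lineage in tree.lineage(t)]
    counts = {
        seed: sum(1 for t in focal_taxa if matrix.records(seed, t))
        for seed in paralog_seeds
    }
    representative = min(counts, key=lambda s: (-counts[s], s))
    return ParalogCall(representative, origin)


def rank_taxa_by_repertoire(
    binary: pd.DataFrame, seed_family: Mapping[str, str]
) -> pd.DataFrame:
    """Rank taxa by the number of distinct seed families with a presence call.

    Returns a frame (taxon, n_families) sorted by descending count, ties in
    ascending taxon order.
    """
    rows = []
    for taxon in binary.index:
        present = binary.loc[taxon]
        families = {seed_family.get(s, s) for s in binary.columns if present[s] == 1}
        rows.append((taxon, len(families)))
    df = pd.DataFrame(rows, columns=["taxon", "n_families"])
    return df.sort_values(
        ["n_families", "taxon"], ascending=[False, True], ignore_index=True
    )


# -------------------------------------------------------------------- exports


def write_profile_tsv(matrix: ProfileMatrix, path) -> None:
    from .ortholog_search import records_to_rows

    pd.DataFrame(records_to_rows(matrix.all_records())).to_csv(path, sep="\t", index=False)


def write_binary_tsv(binary: pd.DataFrame, path) -> None:
    binary.rename_axis("taxon").to_csv(path, sep="\t")


def write_embedding_tsv(result: EmbeddingResult, binary: pd.DataFrame, path) -> None:
    df = result.frame()
    counts = binary.sum(axis=1)
    df["count"] = [int(counts.loc[t]) for t in df["taxon"]]
    df.to_csv(path, sep="\t", index=False)


def write_phyloprofile(matrix: ProfileMatrix, path) -> None:
    """Profile file for the PhyloProfile viewer: geneID, ncbiID, orthoID,
    FAS_F, FAS_B."""
    rows = []
    for r in matrix.all_records():
        rows.append(
            (
                r.seed,
                f"ncbi{r.taxon}",
                r.protein,
                "NA" if r.fas is None else round(r.fas.fas_f, 6),
                "NA" if r.fas is None else round(r.fas.fas_b, 6),
            )
        )
    pd.DataFrame(rows, columns=["geneID", "ncbiID", "orthoID", "FAS_F", "FAS_B"]).to_csv(
        path, sep="\t", index=False
    )


def plot_embedding(result: EmbeddingResult, binary: pd.DataFrame, path=None):
    """Scatter of the embedding, dot size proportional to repertoire size."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.frame()
    counts = binary.sum(axis=1)
    sizes = np.array([10 + 20 * counts.loc[t] for t in df["taxon"]])
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(df["x"], df["y"], s=sizes, alpha=0.7, edgecolor="none")
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
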