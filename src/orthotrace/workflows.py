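"""End-to-end workflows combining the training and search phases.

These helpers wire the module pipeline together the way the command-line
interface exposes it: compile (or load) one profile per seed, search it
across a taxon collection, and assemble the feature-architecture-aware
phylogenetic profile matrix.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from .core_compile import CompileOptions, CoreGroup, compile_core_group
from .features import Architecture
from .ortholog_search import FullSearchResult, SearchParams, run_full_search
from .profiles import ProfileMatrix
from .seqmodel import Protein, Proteome
from .taxonomy import TaxonomyTree


def compile_groups(
    seeds: Sequence[Protein],
    proteomes: Mapping[int, Proteome],
    tree: TaxonomyTree,
    architectures: Mapping[str, Architecture],
    opts: CompileOptions = CompileOptions(),
) -> dict[str, CoreGroup]:
    """Compile one core ortholog group per seed protein."""
    groups = {}
    for seed in seeds:
        group, _ = compile_core_group(seed, proteomes, tree, architectures, opts)
        groups[seed.id] = group
    return groups


def profile_search(
    groups: Mapping[str, CoreGroup],
    proteomes: Mapping[int, Proteome],
    architectures: Mapping[str, Architecture],
    params: SearchParams = SearchParams(),
    n_workers: int = 1,
    taxa_subset: Optional[Sequence[int]] = None,
) -> tuple[ProfileMatrix, FullSearchResult]:
    """Search every group across the collection and assemble the profile
    matrix (seeds ordered by id, taxa by id)."""
    result = run_full_search(
        list(groups.values()),
        proteomes,
        architectures,
        params,
        n_workers=n_workers,
        taxa_subset=taxa_subset,
    )
    taxa = sorted(taxa_subset) if taxa_subset is not None else sorted(proteomes)
    matrix = ProfileMatrix.from_records(
        result.records, seeds=sorted(groups), taxa=taxa
    )
    return matrix, result


def taxa_in_clade(tree: TaxonomyTree, clade: int) -> list[int]:
    """All leaf taxa descending from (or equal to) a clade node."""
    return [t for t in tree.leaves() if clade in tree.lineage(t)]
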