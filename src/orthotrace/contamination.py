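"""Classification of genes as native, contamination, or horizontally acquired.

Genome assemblies — in particular of invertebrates feeding on plant or
microbial material — frequently contain sequences from other organisms.  An
ortholog detected in such an assembly may therefore be (a) a native gene,
(b) an assembly contamination, or (c) a genuinely horizontally acquired gene.
This module separates the three cases from pre-computed similarity-search hit
tables and gene-to-contig maps; it never runs the similarity search itself.

Rules: the self-hit of a query is discarded; hits within a 10% bit-score
margin of the best remaining hit vote for the taxonomic assignment (their
lowest common ancestor).  A gene is *foreign* when its assigned taxon is not
on the path from the assembly's species to the root.  A foreign gene is a
*contamination* when it resides on a contig shorter than the assembly's mean
contig length and all of its direct contig neighbours are foreign too
(single-gene contigs satisfy the neighbour condition vacuously); otherwise it
is flagged *horizontally acquired*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .seqmodel import Protein
from .taxonomy import TaxonomyTree

STATUS_NATIVE = "native"
STATUS_CONTAMINATION = "foreign-contamination"
STATUS_HGT = "foreign-hgt"


@dataclass(frozen=True)
class Hit:
    query: str
    subject: str
    subject_taxon: int
    bits: float

    def __post_init__(self):
        if self.bits <= 0:
            raise ValueError(f"hit {self.query}->{self.subject}: bit score must be positive")


@dataclass(frozen=True)
class GenePlacement:
    contig: str
    start: int
    end: int
    strand: str  # carried but unused by classification
    ordinal: int  # 0-based position of the gene on its contig


@dataclass
class ContigMap:
    """Gene placements plus contig lengths for one assembly."""

    genes: dict[str, GenePlacement]
    contig_lengths: dict[str, int]
    _by_contig: dict[str, list[str]] = field(init=False, repr=False)

    def __post_init__(self):
        by_contig: dict[str, list[tuple[int, str]]] = {}
        for gid, placement in self.genes.items():
            if placement.contig not in self.contig_lengths:
                raise ValueError(f"gene {gid} on unknown contig {placement.contig}")
            by_contig.setdefault(placement.contig, []).append((placement.ordinal, gid))
        self._by_contig = {}
        for contig, entries in by_contig.items():
            entries.sort()
            ordinals = [o for o, _ in entries]
            if ordinals != list(range(len(ordinals))):
                raise ValueError(f"contig {contig}: ordinals not consecutive from 0")
            self._by_contig[contig] = [g for _, g in entries]

    def neighbors(self, gene: str) -> list[str]:
        """Ordinal predecessor and successor on the gene's contig."""
        placement = self.genes[gene]
        order = self._by_contig[placement.contig]
        i = placement.ordinal
        out = []
        if i > 0:
            out.append(order[i - 1])
        if i + 1 < len(order):
            out.append(order[i + 1])
        return out

    def mean_contig_length(self) -> float:
        return sum(self.contig_lengths.values()) / len(self.contig_lengths)


@dataclass(frozen=True)
class GeneFlag:
    gene: str
    assigned_taxon: Optional[int]  # None when unassigned
    status: str


# ------------------------------------------------------------------ operations


def pick_query_isoform(
    isoform_map: Mapping[str, Sequence[str]], proteins: Mapping[str, Protein]
) -> dict[str, Protein]:
    """Per gene, the longest annotated isoform (ties by protein id)."""
    out = {}
    for gene, isoforms in isoform_map.items():
        if not isoforms:
            raise ValueError(f"gene {gene} has no isoforms")
        out[gene] = min((proteins[i] for i in isoforms), key=lambda p: (-len(p), p.id))
    return out


def assign_taxon(
    hits: Sequence[Hit],
    tree: TaxonomyTree,
    margin: float = 0.10,
) -> Optional[int]:
    """Taxonomic assignment of one query from its hit list.

    The query's self-hit is excluded; hits with bit score >= (1 - margin)
    times the best remaining bit score vote, and the assignment is the lowest
    common ancestor of their subject taxa.  Returns None (unassigned) when
    only the self-hit exists.
    """
    informative = [h for h in hits if h.subject != h.query]
    if not informative:
        return None
    best = max(h.bits for h in informative)
    kept = [h for h in informative if h.bits >= (1.0 - margin) * best]
    return tree.lca(*(h.subject_taxon for h in kept))


def is_foreign(assigned: int, species: int, tree: TaxonomyTree) -> bool:
    """True iff the assigned taxon lies off the species' root path (it is
    neither the species itself nor one of its ancestors)."""
    tree._resolve(assigned)
    return assigned not in tree.lineage(species)


def classify(gene: str, foreign: Mapping[str, bool], contigs: ContigMap) -> GeneFlag:
    """Status of one gene given the assembly-wide foreign flags.

    Pure function of the flags and the contig map; see the module docstring
    for the short-contig and foreign-neighbour rules.
    """
    if gene not in contigs.genes:
        raise KeyError(f"gene {gene} missing from contig map")
    if not foreign.get(gene, False):
        return GeneFlag(gene, None, STATUS_NATIVE)
    placement = contigs.genes[gene]
    short = contigs.contig_lengths[placement.contig] < contigs.mean_contig_length()
    neighbors_foreign = all(foreign.get(n, False) for n in contigs.neighbors(gene))
    status = STATUS_CONTAMINATION if (short and neighbors_foreign) else STATUS_HGT
    return GeneFlag(gene, None, status)


def classify_assembly(
    hit_table: Mapping[str, Sequence[Hit]],
    contigs: ContigMap,
    species: int,
    tree: TaxonomyTree,
    margin: float = 0.10,
) -> list[GeneFlag]:
    """Full pipeline for one assembly: assign, flag foreign, classify.

    ``hit_table`` maps each query gene to its similarity hits.  Genes without
    informative hits are treated as native (no evidence of foreignness).
    """
    assigned: dict[str, Optional[int]] = {
        gene: assign_taxon(hits, tree, margin) for gene, hits in hit_table.items()
    }
    foreign = {
        gene: (tax is not None and is_foreign(tax, species, tree))
        for gene, tax in assigned.items()
    }
    flags = []
    for gene in sorted(contigs.genes):
        flag = classify(gene, foreign, contigs)
        flags.append(GeneFlag(gene, assigned.get(gene), flag.status))
    return flags


# ------------------------------------------------------------------------ I/O


def read_hit_table(path) -> dict[str, list[Hit]]:
    """4-column TSV (qseqid, sseqid, staxid, bitscore) -> hits per query."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["qseqid", "sseqid", "staxid", "bitscore"],
        header=0,
    )
    out: dict[str, list[Hit]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.qseqid, []).append(
            Hit(row.qseqid, row.sseqid, int(row.staxid), float(row.bitscore))
        )
    return out


def write_hit_table(hits: Iterable[Hit], path) -> None:
    rows = [(h.query, h.subject, h.subject_taxon, h.bits) for h in hits]
    pd.DataFrame(rows, columns=["qseqid", "sseqid", "staxid", "bitscore"]).to_csv(
        path, sep="\t", index=False
    )


def read_contig_map(path) -> ContigMap:
    """GFF-like TSV with gene rows and contig rows.

    Gene rows: ``gene <tab> contig <tab> start <tab> end <tab> strand <tab>
    ordinal``; contig rows use ``#contig`` in the first column followed by
    contig id and length.
    """
    genes: dict[str, GenePlacement] = {}
    lengths: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()  # noqa: F841  (column header line)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "#contig":
                lengths[parts[1]] = int(parts[2])
            else:
                gene, contig, start, end, strand, ordinal = parts[:6]
                genes[gene] = GenePlacement(contig, int(start), int(end), strand, int(ordinal))
    return ContigMap(genes, lengths)


def write_contig_map(contigs: ContigMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcontig\tstart\tend\tstrand\tordinal\n")
        for contig in sorted(contigs.contig_lengths):
            fh.write(f"#contig\t{contig}\t{contigs.contig_lengths[contig]}\n")
        for gene in sorted(contigs.genes):
            p = contigs.genes[gene]
            fh.write(f"{gene}\t{p.contig}\t{p.start}\t{p.end}\t{p.strand}\t{p.ordinal}\n")


def write_flags(flags: Iterable[GeneFlag], path) -> None:
    rows = [
        (f.gene, "" if f.assigned_taxon is None else f.assigned_taxon, f.status)
        for f in flags
    ]
    pd.DataFrame(rows, columns=["gene", "assigned_taxon", "status"]).to_csv(
        path, sep="\t", index=False
    )
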