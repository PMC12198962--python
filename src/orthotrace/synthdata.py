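"""Synthetic evolution scenarios: taxonomy, proteomes with planted orthologs,
paralogs, HGT and contamination, feature architectures, and the ground-truth
tables that make every pipeline stage testable without downloads.

The default scenario evolves gene families over a 16-species "ladder"
taxonomy that provides exactly one candidate clade per taxonomic distance
class 1..7 from the seed species, so the core-compilation phase can be
exercised across its full distance range.  Sequences evolve by i.i.d. residue
substitution at a fixed per-edge rate with no indels, which keeps alignment
and identity oracles exact while still exercising all pipeline logic.
Feature architectures are inherited from a per-family template with optional
gain/loss/multiplication events.

Planted events per family: terminal losses, a duplication after speciation
(in-paralog pair in one species), a duplication before the radiation of the
seed species' class (a pair of paralogous seed genes that share orthologs in
the outgroup), and a horizontal transfer from the most distant clade into a
relative of the seed species.  Scenario-level contamination places near-copies
of distant-clade genes on short single-gene contigs of a recipient assembly.
Every planted protein is recorded in a ground-truth table
(seed, taxon, protein, relation) with relation in {ortholog, in-paralog,
out-paralog, hgt, contaminant, absent}.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .contamination import ContigMap, GenePlacement, Hit, write_contig_map, write_hit_table
from .features import Architecture, FeatureInstance, write_architectures
from .seqmodel import AMINO_ACIDS, Protein, Proteome, write_fasta
from .taxonomy import TaxonNode, TaxonomyTree, write_taxonomy

#: internal node id of the duplication point used for before-speciation
#: duplications (the class-level ancestor of the seed species)
SPLIT_NODE = 7

SEED_TAXON = 101


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a synthetic evolution scenario.

    Rates are probabilities per family (events) or per site and edge
    (substitutions); the defaults are the package's standard test conditions.
    """

    n_families: int = 20
    protein_length: int = 60
    subst_rate: float = 0.03  # per site per tree edge
    p_loss: float = 0.1  # per family and non-seed leaf
    p_dup_after: float = 0.1  # per family: in-paralog pair in one species
    p_dup_before: float = 0.1  # per family: paralogous seed pair
    p_hgt: float = 0.1  # per family: one horizontal transfer
    n_contaminant_contigs: int = 3
    n_decoys: int = 5  # random proteins per proteome
    feature_gain: float = 0.1  # architecture events per non-seed ortholog
    feature_loss: float = 0.1
    feature_dup: float = 0.1
    genes_per_contig: int = 8
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("p_loss", "p_dup_after", "p_dup_before", "p_hgt",
                     "feature_gain", "feature_loss", "feature_dup", "subst_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_families < 1:
            raise ValueError("need at least one gene family")


# ------------------------------------------------------------------ taxonomies


def ladder_taxonomy() -> TaxonomyTree:
    """16 species with one clade per taxonomic distance class 1..7 from the
    seed species 101."""
    nodes = [
        TaxonNode(1, None, "superkingdom", "SK1"),
        TaxonNode(2, 1, "kingdom", "K1"),
        TaxonNode(3, 1, "kingdom", "K2"),
        TaxonNode(4, 2, "phylum", "PH1"),
        TaxonNode(5, 2, "phylum", "PH2"),
        TaxonNode(6, 3, "phylum", "PH3"),
        TaxonNode(7, 4, "class", "CL1"),
        TaxonNode(8, 4, "class", "CL2"),
        TaxonNode(9, 5, "class", "CL3"),
        TaxonNode(10, 6, "class", "CL4"),
        TaxonNode(11, 7, "order", "OR1"),
        TaxonNode(12, 7, "order", "OR2"),
        TaxonNode(13, 8, "order", "OR3"),
        TaxonNode(14, 9, "order", "OR4"),
        TaxonNode(15, 10, "order", "OR5"),
        TaxonNode(16, 11, "family", "FA1"),
        TaxonNode(17, 11, "family", "FA2"),
        TaxonNode(18, 12, "family", "FA3"),
        TaxonNode(19, 13, "family", "FA4"),
        TaxonNode(20, 14, "family", "FA5"),
        TaxonNode(21, 15, "family", "FA6"),
        TaxonNode(22, 16, "genus", "GE1"),
        TaxonNode(23, 16, "genus", "GE2"),
        TaxonNode(24, 17, "genus", "GE3"),
        TaxonNode(25, 18, "genus", "GE4"),
        TaxonNode(26, 19, "genus", "GE5"),
        TaxonNode(27, 20, "genus", "GE6"),
        TaxonNode(28, 21, "genus", "GE7"),
        TaxonNode(29, 21, "genus", "GE8"),
    ]
    species_parent = [22, 22, 23, 23, 24, 24, 25, 25, 26, 26, 27, 27, 28, 28, 29, 29]
    for i, parent in enumerate(species_parent):
        sid = 101 + i
        nodes.append(TaxonNode(sid, parent, "species", f"S{sid}"))
    return TaxonomyTree(nodes)


def balanced_taxonomy(n_species: int = 16, n_genera: int = 4, n_families: int = 2) -> TaxonomyTree:
    """A balanced taxonomy (root > families > genera > species) for small
    structural tests; species are distributed evenly."""
    if n_genera % n_families or n_species % n_genera:
        raise ValueError("species/genera must divide evenly")
    nodes = [TaxonNode(1, None, "superkingdom", "ROOT")]
    fam_ids = [10 + i for i in range(n_families)]
    for i, fid in enumerate(fam_ids):
        nodes.append(TaxonNode(fid, 1, "family", f"FAM{i + 1}"))
    gen_ids = [50 + i for i in range(n_genera)]
    per_fam = n_genera // n_families
    for i, gid in enumerate(gen_ids):
        nodes.append(TaxonNode(gid, fam_ids[i // per_fam], "genus", f"GEN{i + 1}"))
    per_gen = n_species // n_genera
    for i in range(n_species):
        sid = 101 + i
        nodes.append(TaxonNode(sid, gen_ids[i // per_gen], "species", f"SP{sid}"))
    return TaxonomyTree(nodes)


# ------------------------------------------------------------------- fixture


@dataclass
class Fixture:
    spec: ScenarioSpec
    tree: TaxonomyTree
    proteomes: dict[int, Proteome]
    architectures: dict[str, Architecture]
    truth: pd.DataFrame  # columns: family, seed, taxon, protein, relation
    seeds: dict[str, Protein]  # seed id -> seed protein (all from SEED_TAXON)
    seed_taxon: int
    contig_maps: dict[int, ContigMap]
    hit_tables: dict[int, dict[str, list[Hit]]]

    def truth_cell(self, seed: str, taxon: int, relations=("ortholog", "in-paralog")) -> set[str]:
        sub = self.truth
        mask = (sub["seed"] == seed) & (sub["taxon"] == taxon) & sub["relation"].isin(relations)
        return set(sub.loc[mask, "protein"])

    def write(self, outdir) -> None:
        out = Path(outdir)
        (out / "proteomes").mkdir(parents=True, exist_ok=True)
        (out / "contigs").mkdir(exist_ok=True)
        (out / "hits").mkdir(exist_ok=True)
        write_taxonomy(self.tree, out / "taxonomy.tsv")
        for taxon, proteome in sorted(self.proteomes.items()):
            write_fasta(proteome, out / "proteomes" / f"{taxon}.fasta")
        write_architectures(self.architectures, out / "architectures.json")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(s, p.id) for s, p in sorted(self.seeds.items())],
            columns=["seed", "protein"],
        ).to_csv(out / "seeds.tsv", sep="\t", index=False)
        for taxon, cmap in sorted(self.contig_maps.items()):
            write_contig_map(cmap, out / "contigs" / f"{taxon}.tsv")
        for taxon, table in sorted(self.hit_tables.items()):
            hits = [h for gene in sorted(table) for h in table[gene]]
            write_hit_table(hits, out / "hits" / f"{taxon}.tsv")


# ----------------------------------------------------------------- evolution


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(seq: str, rng: np.random.Generator, rate: float, n_edges: int = 1) -> str:
    residues = list(seq)
    for _ in range(n_edges):
        mask = rng.random(len(residues)) < rate
        for i in np.flatnonzero(mask):
            alternatives = [a for a in AMINO_ACIDS if a != residues[i]]
            residues[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(residues)


def _evolve_family(
    tree: TaxonomyTree,
    root_seq: str,
    rng: np.random.Generator,
    rate: float,
    split_node: Optional[int] = None,
) -> dict[int, list[tuple[Optional[str], str]]]:
    """Evolve a sequence down the taxonomy; returns leaf -> [(copy tag, seq)].

    Without a split node each leaf receives one untagged copy.  With one, the
    gene duplicates there: leaves below it carry tagged copies "A" and "B"
    (each duplicate takes one extra edge of divergence), leaves outside carry
    the single pre-duplication gene.
    """
    out: dict[int, list[tuple[Optional[str], str]]] = {}

    def descend(node: int, seq: str, tag: Optional[str]) -> None:
        if node == split_node and tag is None:
            for copy_tag in ("A", "B"):
                descend(node, _mutate(seq, rng, rate), copy_tag)
            return
        if tree.is_leaf(node):
            out.setdefault(node, []).append((tag, seq))
            return
        for child in tree.children[node]:
            descend(child, _mutate(seq, rng, rate), tag)

    descend(tree.root, root_seq, None)
    return out


def sequence_identity(a: str, b: str) -> float:
    """Fraction of identical positions of two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


# -------------------------------------------------------------- architectures


_EXTRA_NAMESPACES = ("TM:helix", "SP:signal", "LCR:seg", "COILS:cc")


def _family_template(fam: int, length: int, rng: np.random.Generator) -> list[FeatureInstance]:
    feats = [FeatureInstance(f"PFAM:PF{1000 + fam}", 6, length // 2)]
    if rng.random() < 0.6:
        extra = _EXTRA_NAMESPACES[rng.integers(len(_EXTRA_NAMESPACES))]
        feats.append(FeatureInstance(extra, length // 2 + 5, length - 5))
    return feats


def _mutate_architecture(
    template: list[FeatureInstance],
    length: int,
    fam: int,
    rng: np.random.Generator,
    spec: ScenarioSpec,
) -> list[FeatureInstance]:
    feats = list(template)
    if feats and rng.random() < spec.feature_loss:
        feats.pop(rng.integers(len(feats)))
    if rng.random() < spec.feature_gain:
        feats.append(FeatureInstance(f"PFAM:PFG{fam}", max(1, length - 10), length - 2))
    if feats and rng.random() < spec.feature_dup:
        src = feats[rng.integers(len(feats))]
        width = src.end - src.start
        start = max(1, length - width - 1)
        feats.append(FeatureInstance(src.type, start, min(length, start + width)))
    return feats


# ------------------------------------------------------------------ generator


def generate(spec: ScenarioSpec = ScenarioSpec()) -> Fixture:
    """Generate a complete scenario fixture; byte-identical for equal specs."""
    rng = np.random.default_rng(spec.rng_seed)
    tree = ladder_taxonomy()
    leaves = tree.leaves()
    L = spec.protein_length
    ingroup = [t for t in leaves if SPLIT_NODE in tree.lineage(t)]  # relatives of the seed
    outgroup_far = [t for t in leaves if 3 in tree.lineage(t)]  # the distant kingdom
    recipients = [t for t in ingroup if t != SEED_TAXON]

    sequences: dict[int, list[Protein]] = {t: [] for t in leaves}
    family_copies: dict[str, list[tuple[int, str, str]]] = {}  # family -> (taxon, pid, seq)
    architectures: dict[str, Architecture] = {}
    truth_rows: list[tuple] = []
    seeds: dict[str, Protein] = {}
    split_families: set[str] = set()

    def add_protein(taxon: int, pid: str, seq: str, family: str, feats) -> None:
        sequences[taxon].append(Protein(pid, taxon, seq))
        architectures[pid] = Architecture(pid, len(seq), list(feats))
        family_copies.setdefault(family, []).append((taxon, pid, seq))

    for fam in range(spec.n_families):
        family = f"F{fam:02d}"
        template = _family_template(fam, L, rng)
        root_seq = _random_seq(rng, L)
        split = rng.random() < spec.p_dup_before
        evolved = _evolve_family(tree, root_seq, rng, spec.subst_rate,
                                 split_node=SPLIT_NODE if split else None)
        lost = {
            t for t in leaves
            if t != SEED_TAXON and rng.random() < spec.p_loss
        }
        seed_ids: dict[Optional[str], str] = {}
        for tag in (("A", "B") if split else (None,)):
            suffix = tag or ""
            seed_ids[tag] = f"{family}{suffix}@{SEED_TAXON}"
        # materialize copies
        for taxon in leaves:
            if taxon in lost:
                continue
            for tag, seq in evolved[taxon]:
                suffix = tag or ""
                pid = f"{family}{suffix}@{taxon}"
                feats = (
                    template
                    if taxon == SEED_TAXON
                    else _mutate_architecture(template, L, fam, rng, spec)
                )
                add_protein(taxon, pid, seq, family, feats)
        for sid in seed_ids.values():
            seeds[sid] = next(p for p in sequences[SEED_TAXON] if p.id == sid)
        if split:
            split_families.add(family)
        # truth for vertically inherited copies
        for taxon in leaves:
            if taxon == SEED_TAXON:
                continue
            if taxon in lost:
                for sid in seed_ids.values():
                    truth_rows.append((family, sid, taxon, "", "absent"))
                continue
            copies = {tag: f"{family}{tag or ''}@{taxon}" for tag, _ in evolved[taxon]}
            for seed_tag, sid in seed_ids.items():
                for copy_tag, pid in copies.items():
                    if copy_tag is None or copy_tag == seed_tag:
                        relation = "ortholog"
                    else:
                        relation = "out-paralog"
                    truth_rows.append((family, sid, taxon, pid, relation))
        # duplication after speciation: an in-paralog pair in one species
        if not split and rng.random() < spec.p_dup_after:
            present = [t for t in leaves if t != SEED_TAXON and t not in lost]
            if present:
                taxon = present[rng.integers(len(present))]
                base = next(p for p in sequences[taxon] if p.id == f"{family}@{taxon}")
                pid = f"{family}@{taxon}_p"
                add_protein(taxon, pid, _mutate(base.residues, rng, spec.subst_rate),
                            family, _mutate_architecture(template, L, fam, rng, spec))
                truth_rows.append((family, seed_ids[None], taxon, pid, "in-paralog"))
        # horizontal transfer from the distant kingdom into a seed relative
        if not split and rng.random() < spec.p_hgt:
            donors = [t for t in outgroup_far if t not in lost]
            targets = [t for t in recipients if t not in lost]
            if donors and targets:
                donor = donors[rng.integers(len(donors))]
                recipient = targets[rng.integers(len(targets))]
                donor_seq = next(
                    s for t, p, s in family_copies[family] if t == donor and p == f"{family}@{donor}"
                )
                pid = f"{family}@{recipient}_h"
                add_protein(recipient, pid, _mutate(donor_seq, rng, spec.subst_rate),
                            family, _mutate_architecture(template, L, fam, rng, spec))
                truth_rows.append((family, seed_ids[None], recipient, pid, "hgt"))

    # scenario-level contamination: foreign genes on short single-gene contigs
    contaminants: dict[int, list[str]] = {}
    plain_families = sorted(f for f in family_copies if f not in split_families)
    for k in range(spec.n_contaminant_contigs):
        family = plain_families[int(rng.integers(len(plain_families)))]
        donors = [
            (t, p, s) for t, p, s in family_copies[family]
            if t in outgroup_far and "@" in p and not p.endswith(("_h", "_p", "_c"))
        ]
        if not donors:
            continue
        donor_taxon, _, donor_seq = donors[int(rng.integers(len(donors)))]
        recipient = recipients[int(rng.integers(len(recipients)))]
        pid = f"{family}@{recipient}_c{k}"
        add_protein(recipient, pid, _mutate(donor_seq, rng, 0.01), family,
                    architectures[f"{family}@{donor_taxon}"].instances)
        contaminants.setdefault(recipient, []).append(pid)
        truth_rows.append((family, f"{family}@{SEED_TAXON}", recipient, pid, "contaminant"))

    # decoys: unrelated random proteins
    for taxon in leaves:
        for k in range(spec.n_decoys):
            pid = f"DEC@{taxon}_{k}"
            seq = _random_seq(rng, L)
            sequences[taxon].append(Protein(pid, taxon, seq))
            feats = []
            if rng.random() < 0.3:
                feats = [FeatureInstance(f"PFAM:PFD{k}", 10, 30)]
            architectures[pid] = Architecture(pid, L, feats)

    proteomes = {
        t: Proteome(t, sorted(sequences[t], key=lambda p: p.id),
                    isoform_map={p.id: [p.id] for p in sequences[t]})
        for t in leaves
    }
    contig_maps = {
        t: _build_contig_map(proteomes[t], contaminants.get(t, []), spec)
        for t in leaves
    }
    hit_tables = {t: _build_hit_table(t, proteomes[t], family_copies, L) for t in leaves}
    truth = pd.DataFrame(
        truth_rows, columns=["family", "seed", "taxon", "protein", "relation"]
    ).sort_values(["family", "seed", "taxon", "protein"], ignore_index=True)
    return Fixture(
        spec=spec,
        tree=tree,
        proteomes=proteomes,
        architectures=architectures,
        truth=truth,
        seeds=dict(sorted(seeds.items())),
        seed_taxon=SEED_TAXON,
        contig_maps=contig_maps,
        hit_tables=hit_tables,
    )


def _build_contig_map(proteome: Proteome, contaminant_ids: list[str], spec: ScenarioSpec) -> ContigMap:
    normal = sorted(p.id for p in proteome if p.id not in contaminant_ids)
    genes: dict[str, GenePlacement] = {}
    lengths: dict[str, int] = {}
    span = 2000
    for k in range(0, len(normal), spec.genes_per_contig):
        chunk = normal[k:k + spec.genes_per_contig]
        contig = f"c{proteome.taxon}_{k // spec.genes_per_contig}"
        lengths[contig] = 2500 * len(chunk)
        for i, gid in enumerate(chunk):
            genes[gid] = GenePlacement(contig, 1 + i * span, (i + 1) * span, "+", i)
    for j, gid in enumerate(sorted(contaminant_ids)):
        contig = f"cc{proteome.taxon}_{j}"
        lengths[contig] = 1200
        genes[gid] = GenePlacement(contig, 1, 1100, "+", 0)
    return ContigMap(genes, lengths)


def _build_hit_table(
    taxon: int,
    proteome: Proteome,
    family_copies: dict[str, list[tuple[int, str, str]]],
    length: int,
    max_hits: int = 8,
) -> dict[str, list[Hit]]:
    """Similarity hit tables emulating a search against a reference database.

    Bit scores scale with sequence identity as 2 * L * identity (the
    ungapped self-hit ceiling times the matched fraction), so a 10% bit-score
    margin keeps hits down to 90% of the best hit's identity — close
    relatives vote, distant homologs do not.  Vertically inherited
    genes additionally hit their own species' database record (annotated
    reference proteomes are part of such databases; the record is a distinct
    accession, so it survives the self-hit exclusion), whereas recently
    acquired or contaminating sequences have no conspecific database entry —
    their closest records come from the donor lineage.
    """
    by_family: dict[str, str] = {}
    for fam, copies in family_copies.items():
        for t, pid, seq in copies:
            by_family[pid] = fam
    table: dict[str, list[Hit]] = {}
    for protein in proteome:
        fam = by_family.get(protein.id)
        hits = [Hit(protein.id, protein.id, taxon, float(2 * length))]
        if fam is not None:
            native = "_h" not in protein.id and "_c" not in protein.id
            scored = []
            if native:  # the species' own database record, distinct accession
                scored.append(Hit(protein.id, f"{protein.id}/db", taxon, float(2 * length)))
            for t, pid, seq in family_copies[fam]:
                # foreign copies planted in other assemblies are not part of
                # a curated reference database and never act as subjects
                if pid == protein.id or "_h" in pid or "_c" in pid:
                    continue
                ident = sequence_identity(protein.residues, seq)
                scored.append(Hit(protein.id, pid, t, round(2 * length * max(ident, 0.05), 1)))
            scored.sort(key=lambda h: (-h.bits, h.subject))
            hits.extend(scored[:max_hits])
        table[protein.id] = hits
    return table


# ----------------------------------------------------------------- evaluation


def evaluate_recovery(records, fixture: Fixture) -> dict:
    """Precision/recall of representative orthologs against the truth table.

    A predicted representative is correct when the truth lists it as an
    ortholog or in-paralog of that seed in that taxon.  Recall counts truth
    cells (seed, taxon) with at least one acceptable protein.
    """
    predicted: dict[tuple[str, int], str] = {}
    for r in records:
        if r.is_representative:
            predicted[(r.seed, r.taxon)] = r.protein
    truth_cells: dict[tuple[str, int], set[str]] = {}
    t = fixture.truth
    for row in t[t["relation"].isin(["ortholog", "in-paralog"])].itertuples(index=False):
        truth_cells.setdefault((row.seed, row.taxon), set()).add(row.protein)
    tp = sum(
        1 for cell, pid in predicted.items() if pid in truth_cells.get(cell, set())
    )
    precision = tp / len(predicted) if predicted else 1.0
    recall = tp / len(truth_cells) if truth_cells else 1.0
    return {
        "precision": precision,
        "recall": recall,
        "n_predicted": len(predicted),
        "n_truth": len(truth_cells),
        "tp": tp,
    }
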