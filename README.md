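# orthotrace

Feature-architecture-aware targeted ortholog search and phylogenetic
profiling.

Orthologs — genes separated by speciation rather than duplication — are the
best guess when transferring functional knowledge across species, but
computing them for the taxon collections produced by today's biodiversity
genomics projects overwhelms all-vs-all orthology tools.  `orthotrace`
addresses this with a *targeted* search: starting from a **single seed
protein**, it

1. iteratively compiles a small, taxonomically diverse **core ortholog
   group** and trains a profile HMM on it (the training phase),
2. searches that profile across an arbitrary collection of proteomes,
   validating every candidate with a **reciprocity criterion** against the
   seed species and selecting per-taxon representatives by minimal Kimura
   distance (the search phase), and
3. scores the **feature-architecture similarity (FAS)** between the seed and
   every ortholog in both directions, yielding phylogenetic profiles that
   carry information about functional divergence, not just presence and
   absence.

The core candidate score of the training phase is

    score(c_i) = AS(c0, c_i) / AS(c0, c0) + ( FAS(c0→c_i) + FAS(c_i→c0) ) / 2

with AS the BLOSUM62 global alignment score, AS(c0, c0) the seed's
self-score and FAS the directional architecture similarity in [0, 1]; the
maximum is 2, and candidates reaching it (or coming within a configurable
margin of it) are accepted immediately.  Downstream, profiles can be
filtered by FAS threshold and direction, binarized (presence = at least one
ortholog with FAS ≥ 0.3), embedded in 2-D with UMAP to survey repertoires
across thousands of taxa, and screened for genes that are assembly
contaminations or horizontal acquisitions.  Details, defaults and
limitations are documented in [`docs/methods.md`](docs/methods.md); note in
particular that the FAS score is a documented surrogate reproducing the
published contract, not the published algorithm's exact values.

A bundled scenario generator (`orthotrace.synthdata`) produces complete
synthetic inputs — ranked taxonomy, proteomes with planted orthologs,
paralogs, losses, horizontal transfers and contaminated contigs, feature
architectures, similarity hit tables and ground-truth labels — so the entire
pipeline is testable offline.

## Worked example

```python
from orthotrace.synthdata import ScenarioSpec, generate
from orthotrace.core_compile import CompileOptions, compile_core_group
from orthotrace.ortholog_search import run_full_search
from orthotrace.profiles import ProfileMatrix, binarize

fixture = generate(ScenarioSpec(rng_seed=1))          # 16 taxa, 20 families
seed = fixture.seeds["F00@101"]                       # seed protein, species 101

group, log = compile_core_group(
    seed, fixture.proteomes, fixture.tree, fixture.architectures,
    CompileOptions(rng_seed=7),
)
for m in group.members[1:]:
    s = m.score
    print(f"{m.protein.id}  taxon={m.taxon}  AS={s.as_ratio:.3f}  "
          f"FAS_F={s.fas_f:.2f}  FAS_B={s.fas_b:.2f}  total={s.total:.3f}")
```

prints the five core orthologs picked across increasingly distant clades —
the alignment-score ratio decays with taxonomic distance while the planted
architectures stay identical:

```
F00@104  taxon=104  AS=1.000  FAS_F=1.00  FAS_B=1.00  total=2.000
F00@106  taxon=106  AS=0.878  FAS_F=1.00  FAS_B=1.00  total=1.878
F00@107  taxon=107  AS=0.832  FAS_F=1.00  FAS_B=1.00  total=1.832
F00@111  taxon=111  AS=0.726  FAS_F=1.00  FAS_B=1.00  total=1.726
F00@110  taxon=110  AS=0.628  FAS_F=1.00  FAS_B=1.00  total=1.628
```

(The first candidate happens to be sequence-identical to the seed and
triggers the hard maximum-score stop at 2.)  The full search then recovers
the ortholog in every taxon still carrying the family:

```python
result = run_full_search([group], fixture.proteomes, fixture.architectures)
matrix = ProfileMatrix.from_records(result.records,
                                    seeds=["F00@101"],
                                    taxa=sorted(fixture.proteomes))
print(binarize(matrix, fas_min=0.3)["F00@101"].tolist())
```

```
[0, 1, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 1, 1, 1, 1]
```

— 14 of the 15 other taxa carry the ortholog (taxon 108 lost the family in
this scenario; the leading 0 is the seed taxon itself, which is not
searched).  A distant record looks like
`F00@113  bits=85.3  kimura=0.439  FAS_F=1.00  FAS_B=1.00`: still an
unambiguous profile hit at ~66% identity, with an unchanged domain
architecture.

The same steps are available from the shell:

```
orthotrace synth   --out fx --seed 1
orthotrace compile --seed seed.fasta --seed-taxon 101 \
                   --proteome-dir fx/proteomes --taxonomy fx/taxonomy.tsv \
                   --annotations fx/architectures.json --out lib
orthotrace search  --hmm-lib lib --proteome-dir fx/proteomes \
                   --taxonomy fx/taxonomy.tsv \
                   --annotations fx/architectures.json --out results
orthotrace profile --profiles-tsv results/profiles.tsv --out viz --embed-profiles
```

`search` writes the profile table, ortholog FASTA, and a
PhyloProfile-compatible file (`geneID  ncbiID  orthoID  FAS_F  FAS_B`).

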