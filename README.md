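# plasphage

Detection and classification of putative **plasmid prophages** — temperate
phage genomes that replicate as extrachromosomal plasmids instead of
integrating into the host chromosome — among bacterial plasmid sequences.

Surveys of complete plasmid records (e.g. from the *Bacillus cereus sensu
lato* group) show that a surprising fraction of deposited "plasmids" are in
fact phage genomes in their prophage state. `plasphage` turns the manual
workflow of such surveys into a tested, reusable pipeline:

1. **Deduplication** — plasmid genomes are clustered greedily at 99%
   identity / 99% bidirectional coverage (global alignment; a banded
   affine-gap DP handles genome-scale sequences) and one representative per
   cluster is kept.
2. **Marker profiles** — reference protein sets for seven marker families
   (large terminase, major capsid protein, tape measure protein, XerC-like
   tyrosine recombinase, and the ParA / ParM / TubZ partitioning motors)
   plus tail sheath and serine recombinase are clustered at 20% identity /
   80% coverage; clusters with ≥ 10 members are aligned (center-star MSA)
   and turned into Krogh-style profile HMMs with Laplace-smoothed emissions.
3. **Two-marker screen** — genomes of 15–500 kbp are kept, every protein is
   scored against every profile with a local log-odds Viterbi (free entry /
   exit, background-scoring flanks), and a genome is *selected* only if it
   carries hits for **both** the terminase and the major capsid protein —
   the minimal phage signature. Optional decoy calibration fits a Gumbel
   null so hits can be thresholded by E-value instead of bits.
4. **Ortholog clustering** — all-vs-all local protein alignment
   (E ≤ 1e-5, query coverage ≥ 75%), bidirectional best hits, and the
   COGtriangles rule: clusters are seeded by triangles of pairwise-BBH
   proteins from three genomes and merged when they share a BBH edge.
5. **Protein-sharing network and grouping** — the genome × cluster
   presence/absence (pangenome) matrix is exported as a bipartite GraphML
   network; genomes are grouped by connected components of
   `sim(i,j) = |shared clusters| / min(|clusters_i|, |clusters_j|) ≥ 0.5`,
   everything else remaining a singleton.
6. **Classification** — a deterministic rule cascade formalises the expert
   calls: no terminase+MCP → *non-phage plasmid*; phage signature without
   any partitioning motor or recombinase → *putative virulent phage*;
   truncated terminase or a tape measure protein split across CDSs →
   *putative degenerated plasmid prophage*; otherwise *putative active
   plasmid prophage*. Morphotype is *myovirus-like* iff a tail sheath
   protein is found, else *siphovirus-like* when a TMP is present.

A first-class synthetic-data generator (`plasphage.synth`) emulates the real
inputs: 15–120 kbp plasmids carrying diverged marker cassettes, planted
duplicates (exact and 99.5% identity), near-threshold 98% decoy pairs,
split/truncated genes and group structure, together with a machine-readable
truth table — so the whole pipeline is testable against planted ground
truth.

## Worked example

```python
from plasphage.pipeline import run_pipeline

result = run_pipeline({"seed": 1, "out": "out", "synthetic": {}})
print(result.counts_table.to_string(index=False))
```

On the default synthetic world (40 unique genomes: 12 active / 6 degenerated
/ 2 virulent-like / 20 non-phage, plus 3 planted duplicate genomes) this
prints:

```
                                state  count  percent
     putative_active_plasmid_prophage     12     30.0
putative_degenerated_plasmid_prophage      6     15.0
              putative_virulent_phage      2      5.0
                    non_phage_plasmid     20     50.0
```

i.e. deduplication collapses 43 genomes to 40, the two-marker screen selects
the 20 phage-like genomes, grouping recovers the 3 planted groups of 5 (the
rest are singletons), and every genome's state and morphotype matches its
planted truth. Stage artifacts (cluster tables, marker table, pangenome
matrix, GraphML network, per-genome calls) are written under `out/`.

The same stages are available from the shell:

```bash
plasphage synth --out data --seed 1
plasphage run --config config.yaml
plasphage dedup --genomes data/genomes.fna --out clusters.tsv
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from scratch
— generating the default synthetic world from the given seed and executing
every pipeline stage — and writes its JSON report to `--out`:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/plasphage/align.py` — pairwise global/local affine-gap alignment,
  Karlin–Altschul bit scores and E-values, banded global DP
- `src/plasphage/cluster.py` — greedy identity/coverage clustering
- `src/plasphage/msa.py`, `hmm.py` — center-star MSA; profile HMM build,
  Viterbi/Forward, local search, Gumbel decoy calibration
- `src/plasphage/screen.py` — size filter, two-marker screen, ORF-scan
  fallback for unannotated genomes
- `src/plasphage/orthology.py` — all-vs-all, BBH, COGtriangles, pangenome
- `src/plasphage/grouping.py` — bipartite network export and grouping
- `src/plasphage/classify.py` — feature extraction and the rule cascade
- `src/plasphage/synth.py` — synthetic plasmid generator with planted truth
- `src/plasphage/pipeline.py`, `cli.py` — orchestration and CLI

See `docs/methods.md` for the models, thresholds and their rationale.
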