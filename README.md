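# funfams

Identification of **functional families (FunFams)** inside protein domain
superfamilies, and domain-based prediction of whole-protein Gene Ontology
(GO) functions.

Structural domain superfamilies (CATH/Gene3D-style groupings) collect
evolutionarily related domains that may perform very different functions.
This package partitions a superfamily into functionally coherent families by
combining unsupervised sequence clustering with a *supervised selection
step* driven by the GO annotations of the domains' parent proteins, then
uses the families as a probabilistic function-prediction library. It is
aimed at computational biologists who work with domain-level function
assignment and want a transparent, fully scriptable implementation of the
whole chain: annotation filtering, clustering, coherence assessment,
dendrogram pruning, profile-HMM libraries, per-term probabilities, and an
enzyme-based quality benchmark.

## The method

1. **Annotation preparation.** UniProtKB-GOA annotations are reduced to a
   high-quality subset: all non-IEA annotations, plus IEA annotations to
   SwissProt proteins made by the Keyword2GO or EC2GO mappings. Per
   protein, only the most specific terms are kept.
2. **Clustering.** Superfamily domain sequences are pre-clustered at 90%
   pairwise identity (greedy incremental, CD-HIT style). Clusters without
   an annotated sequence are removed; the remaining *starting clusters* are
   agglomerated — always merging the most similar pair — into a dendrogram
   with recorded merge scores.
3. **Coherence assessment.** For every dendrogram node, a *core set* of
   putatively essential molecular-function terms is seeded from the
   smallest sequence MF term sets, extended with their more specific
   descendants, and reduced to an antichain. An iterative *annotation
   editing* step finds terms that merely co-occur with core terms
   (ancillary activities, terms contributed by other domains) and filters
   them out. A node is *coherent* if at least one member sequence's term
   set (namespace order MF → BP → CC) covers the whole edited cluster set.
4. **Pruning.** The maximal coherent nodes — coherent nodes with no
   coherent ancestor — become the FunFams; they partition the annotated
   starting clusters.
5. **Function association.** Each family is associated with every GO term
   supported by its members after up-propagation in the GO DAG, with
   probability `p = T/N` (T = distinct supporting member domains, N =
   family size).
6. **Prediction.** Target domains are scanned against their superfamily's
   profile-HMM library (HMMER3 via pyhmmer); only the top bit-score model
   counts, and the whole-protein score of each term is the maximum over the
   protein's domains.
7. **Benchmark.** A partitioning is scored against four-digit EC numbers:
   `raw = (diversity + division) / 2`, where diversity is the mean number
   of distinct EC4s per family and division the mean number of families per
   EC4. The floor, 1.0, means perfectly pure and unsplit families.

## Worked example

```python
from funfams.examples import worked_example, YELLOW, ORANGE, VIOLET
from funfams.predict import ModelLibrary, predict_protein

ex = worked_example(seed=1)
print(ex.family_two_function.term_probs[YELLOW],
      ex.family_two_function.term_probs[ORANGE])
print(ex.family_single_function.term_probs[VIOLET])

libraries = {"SFA": ModelLibrary([ex.family_two_function]),
             "SFB": ModelLibrary([ex.family_single_function])}
pred = predict_protein("T1", ex.target_domains, libraries)
print(sorted(pred.term_scores.items()))
```

prints

```
0.5 0.5
1.0
[('GO:0000001', 1.0), ('GO:0000010', 0.5), ('GO:0000011', 0.5), ('GO:0000012', 1.0)]
```

The first family has six member domains whose parent proteins split 3/3
between two functions, so each function gets probability 3/6 = 0.5. The
second family's three members all carry one function: 3/3 = 1.0. The
two-domain target protein inherits, per term, the maximum over its domain
assignments: 0.5, 0.5 and 1.0 (the extra `GO:0000001` is the ontology root,
supported by every member through up-propagation).

The full pipeline is also available from the shell:

```bash
funfams simulate --seed 1 --out fixture/
funfams build-families --fasta fixture/domains.fa --obo fixture/ontology.obo \
    --gaf fixture/annotations.gaf --subset fixture/subset.tsv --out run/
funfams benchmark --fasta fixture/domains.fa --obo fixture/ontology.obo \
    --gaf fixture/annotations.gaf --subset fixture/subset.tsv \
    --ec fixture/ec.tsv --out bench/
```

which writes the family membership table, a Newick dendrogram, per-family
term probabilities and the EC-based quality report for a synthetic
superfamily with known ground truth.

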