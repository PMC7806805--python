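# foodgraph

Build a heterogeneous food–chemical graph from recipe co-occurrence and
ingredient–compound relations, learn node embeddings with metapath random
walks and skip-gram plus a chemical-structure prediction head, and evaluate
the embeddings on clustering, pairing recommendation, and compound–food
relation prediction.

## What's inside

| module | role |
| --- | --- |
| `foodgraph.graph` | typed node/edge container (ingredients, flavor & drug compounds), hub classification, 881-bit fingerprints |
| `foodgraph.io` | CSV dialects for nodes/edges/fingerprints, word2vec-text embeddings |
| `foodgraph.cooccurrence` | recipe co-occurrence counts, PMI/NPMI, three-rule ingredient-edge selection |
| `foodgraph.walks` | class-constrained metapath walks (`C–H–N–H'–C'`, `N–H–C–H'–N'`, cyclically extended to length 50) and uniform walks |
| `foodgraph.embedding` | skip-gram with negative sampling + λ-weighted semi-supervised fingerprint head; deterministic single-threaded SGD |
| `foodgraph.evaluation` | k-means/NMI clustering, cosine pairing queries, Jaccard category matrix, thresholded relation prediction with confusion metrics |
| `foodgraph.synthetic` | deterministic fixtures: planted ingredient communities, community-specific fingerprint bit signatures |

## CLI

The stages chain through plain text/CSV files:

```bash
# synthetic fixture (recipes, nodes, compound edges, fingerprints)
foodgraph synth --preset small --seed 7 -o fixtures/

# NPMI scoring + edge selection + graph assembly
foodgraph build-graph --recipes fixtures/recipes.txt --nodes fixtures/nodes.csv \
    --compound-edges fixtures/edges.csv --npmi-min 0.25 --min-unigram 20 \
    --min-joint 5 --rescue-top-k 20 -o graph/

# walk corpus (metapath + uniform), then training
foodgraph walk --graph graph/ --schemas chnhc,nhchn,uniform \
    --walks-per-start 100 --max-len 50 --seed 42 -o walks.txt
foodgraph train --walks walks.txt --fingerprints fixtures/fingerprints.csv \
    --dim 300 --window 5 --negatives 5 --lambda 0.5 --epochs 5 --seed 42 -o model/

# evaluation
foodgraph evaluate cluster --model model/ --labels graph/nodes.csv --k 9 --seed 0
foodgraph recommend --model model/ --query ing_c0_000+ing_c1_000 -k 20 \
    --restrict nonhub --graph graph/
foodgraph evaluate relations --model model/ --gold gold.csv \
    --universe universe.csv --threshold 0.5
```

## Notes

- Training is bit-reproducible under a fixed seed (single-threaded
  reference implementation); `lambda 0` reduces exactly to plain skip-gram.
- The fingerprint head is semi-supervised: tokens without an 881-bit label
  simply skip the auxiliary loss, so partially labeled corpora train fine,
  and the trained head can predict fingerprints for unlabeled nodes
  (`EmbeddingModel.predict_fingerprint`).
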