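# netextract

Extract edge-weighted spatial graphs from 2D images of network-like
structures — slime-mould (*Physarum polycephalum*) plasmodia, insect wing
venation, leaf veins, crack patterns — and evaluate how faithfully
different segmentation methods recover a known ground truth.

Biological networks are usually available as images, not as graphs. To
study them with graph theory one first needs the graph: vertex positions,
which vertices are connected, how long and how thick each connection is.
`netextract` automates that step as a configurable four-stage pipeline:

1. **preprocessing** — optional Gaussian/median/bilateral smoothing or
   non-local-means denoising;
2. **segmentation** — Otsu or adaptive thresholding, guided (compact)
   watershed or GrabCut with interchangeable marker strategies
   (erosion, distance transform, adaptive);
3. **graph detection** — Guo–Hall thinning to a one-pixel skeleton, a
   local node criterion (a skeleton pixel is a vertex if its removal
   leaves exactly one or at least three 4-connected white components in
   its 3×3 neighbourhood), simultaneous breadth-first edge tracing, edge
   lengths in chain units (axial step = 1, diagonal step = √2) and stroke
   widths read off the Euclidean distance transform;
4. **graph filtering** — largest connected component, degree-2 smoothing,
   and a cycle filter that removes every bridge and dead-end.

The result is an undirected spatial multigraph (a thin wrapper around
`networkx.MultiGraph`): vertices carry pixel coordinates `(x, y)`, edges
carry `length`, `width_median`, `width_var` and the traced pixel path.
Graphs are written as GraphML, GML, or a plain-text edge list.

A synthetic evaluation module closes the loop: it generates random planar
spatial graphs, renders them as images whose geometry is exactly known,
corrupts the renders (random per-edge brightness, a background intensity
gradient, global blur), re-extracts, and scores the result against the
ground truth with a similarity measure `s ∈ [0, 1]` plus pooled
sensitivity `TP/(TP+FN)` and precision `TP/(TP+FP)` over vertex and edge
correspondences.

## Worked example

```python
import numpy as np
from netextract import (build_test_set, run_pipeline, score_pair,
                        load_config, write_graphml)
from netextract.similarity import standard_method_pipelines

# one synthetic ground-truth pair: a known graph and its rendered image
pair = build_test_set(n_images=1, condition="ideal", seed=0)[0]
print(pair.truth)

cfg = standard_method_pipelines()["otsu"]     # otsu -> thin -> detect
result = run_pipeline(pair.image, cfg)
graph = result.final_graph
print(graph)

report = score_pair(pair.truth, graph, radius=10.0)
print(f"s={report.s:.3f} sensitivity={report.sensitivity:.3f} "
      f"precision={report.precision:.3f}")

write_graphml(graph, "extracted.graphml")
```

prints

```
SpatialGraph(30 vertices, 49 edges)
SpatialGraph(30 vertices, 49 edges)
s=0.978 sensitivity=1.000 precision=1.000
```

The extracted graph recovers every vertex and edge of the ground truth
(sensitivity and precision 1.0); the similarity score 0.98 additionally
penalizes the remaining sub-pixel jitter in vertex positions and the
small residual disagreement in traced lengths and measured widths.

### Command line

```sh
netextract fixtures --n 10 --condition gradient --seed 7 --out fx/
netextract evaluate --manifest fx/manifest.json \
    --config otsu=src/netextract/pipelines/otsu_basic.yaml \
    --config adaptive=src/netextract/pipelines/adaptive_basic.yaml \
    --out eval/
netextract extract my_network.png --config my_pipeline.yaml --out results/
netextract filters results/my_network/graph.graphml \
    --apply keep_largest_component --apply keep_cycles --out clean.graphml
```

`extract` writes the graph in three formats plus an overlay image (red
edge paths, blue vertex squares over the input) for visual inspection,
and processes batches with per-file error logging.

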