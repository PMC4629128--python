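schema_version: 1
steps:
  - {stage: segmentation, name: adaptive_threshold, params: {block: 51, offset: 4.0}}
  - {stage: graph_detection, name: guo_hall, params: {}}
  - {stage: graph_detection, name: detect_graph, params: {}}
  - {stage: graph_filtering, name: keep_largest_component, params: {}}
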