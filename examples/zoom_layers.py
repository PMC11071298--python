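"""Multi-resolution index: layer structure and zoom-layer selection.

Indexes a 2 Mb sequence with 4 kb base windows.  Each coarser layer doubles
window size and sparsity and is sampled from the previous layer's sketches
(never rescanning the sequence), so total storage stays linear.  A zoom
query picks the coarsest layer that still gives at least one matrix cell
per display pixel.
"""

from dotsketch import SequenceRecord, build_hierarchy, select_layer
from dotsketch.synthetic import random_dna

record = SequenceRecord("chr_sim", random_dna(2_000_000, seed=7))
index = build_hierarchy(record, base_window=4_000, target_sketch=500, r_min=100)

print(f"{index.n_layers} layers for {index.n:,} bp "
      f"(base window {index.base_window:,}, base sparsity {index.base_sparsity}):")
for layer in index.layers:
    print(f"  level {layer.level}: window {layer.window_size:>6,} positions, "
          f"sparsity {layer.sparsity:>2}, {layer.r:>4} windows, "
          f"{layer.total_hashes():>8,} stored hashes")

for viewport in (2_000_000, 1_000_000, 200_000):
    level = select_layer(index, viewport, display_cells=100)
    print(f"viewport {viewport:>9,} bp at 100 display cells -> level {level} "
          f"(window {index.layer(level).window_size:,})")
# halving the viewport steps one level finer until the base layer is reached
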