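"""Generate a synthetic tissue phantom and inspect its ground truth.

The phantom emulates an ion-beam-imaged hippocampal field: nucleated
somata for neurons and glia, elongated vessels, plaque and tangle
aggregates, Poisson count noise, and a gold slide-background channel.
"""

from mibipipe import PhantomSpec, generate_phantom

spec = PhantomSpec(
    raster_px=512, field_width_um=200.0,
    n_cells_per_class={"neuron": 30, "microglia": 20, "astrocyte": 15,
                       "endothelial": 8},
    n_objects_per_class={"plaque": 10, "tangle": 15},
    slide_border_px=24, seed=7)

stack, truth = generate_phantom(spec)

print(f"field: {spec.raster_px} px at {spec.pixel_size_um:.4f} um/px")
print(f"channels: {', '.join(stack.channel_names)}")
print(f"cells planted: {truth.cell_labels.n_labels}; "
      f"objects planted: {truth.object_labels.n_labels}")
print(f"cell-object overlap pairs: {len(truth.true_overlap_pairs)}")
# each pair is (cell label, object label, shared pixels): the in-silico
# record of which aggregates physically touch which cells
print("first pairs:", truth.true_overlap_pairs[:3])
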