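"""Generate a small synthetic pooled siRNA adhesion screen.

Builds a 60-gene library (3 duplexes per gene), arrays it on a 384-well
plate next to a 32-well control block, samples a latent ground truth with
two receptor genes, and draws per-well (nuclei, bacteria) counts.
"""

import adhescreen as a

lib = a.build_library(60, 3, seed=1)
plates = a.layout_plates(lib, pooled=True, controls_per_plate=32)
truth = a.sample_ground_truth(lib, receptor_fraction=2 / 60, seed=1)
counts = a.simulate_screen_counts(plates, truth, a.RenderSpec(), seed=1)

print(f"library: {lib.n_genes} genes, {lib.n_duplexes} duplexes")
print(f"plates: {len(plates)} ({plates[0].n_sample_wells} sample + "
      f"{plates[0].n_control_wells} control wells)")
print(f"planted receptors: {truth.receptor_genes}")
print(counts.groupby("content_class")["bac_nuc_ratio"].median().round(2))
# The antiserum-block wells sit near the assay floor (~5% of the negative-
# control ratio); receptor-gene wells fall below the ~4 bacteria/nucleus
# baseline in proportion to effect x knockdown.
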