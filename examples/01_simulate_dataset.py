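"""Generate a synthetic cell-mixture methylation dataset.

Builds a case-control study of 10,000 CpGs and 100 whole-blood-like
samples: eight leukocyte subtypes from two lineages, Dirichlet cell
proportions confounded with the phenotype, 1% planted DMPs, five
batches, individual variation and measurement error.
"""
import numpy as np

from smartsva import SimulationConfig, assemble_dataset

config = SimulationConfig(seed=1)
dataset = assemble_dataset(config)

Y = dataset.Y
truth = dataset.truth
print(f"matrix: {Y.p} probes x {Y.n} samples (scale={Y.scale})")
print(f"beta-value range: [{dataset.beta_view.values.min():.4f}, "
      f"{dataset.beta_view.values.max():.4f}]")
print(f"planted DMPs: {truth.dmp_index.size} "
      f"(mean |effect| {np.abs(truth.effect).mean():.2f} on the M scale)")
print(f"mean cell proportions: {np.round(truth.B.mean(axis=0), 3)}")
print(f"batch sizes: {np.bincount(truth.batch_label)}")
# The proportions are the hidden confounder: their group difference is
# what a reference-free adjustment method has to remove.
diff = truth.B[truth.phenotype == 1].mean(0) - truth.B[truth.phenotype == 0].mean(0)
print(f"group difference in mean proportions: {np.round(diff, 3)}")
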