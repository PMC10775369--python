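"""Single-cell marker profiling and rule-based phenotyping.

Aggregates background-subtracted marker intensities over ground-truth
cell masks, calls per-marker positivity with the bimodality-guarded Otsu
thresholds, gates cells through the marker-combination rules, and
compares against the planted phenotypes.
"""

import numpy as np
import pandas as pd

from mifpipe import SyntheticConfig, generate_dataset, preprocess_dataset
from mifpipe.profiling import profile_cells

config = SyntheticConfig(n_cycles=4, n_fovs=2, n_channels_per_cycle=4,
                         image_shape=(512, 512), n_cells=200, max_shift=0,
                         seed=23)
dataset, truth = generate_dataset(config)
# quantification uses the absolute background-subtracted scale
quantify = preprocess_dataset(dataset, normalize=False)

stacks = {
    i: {quantify.marker(j, c): np.asarray(quantify.pair(i, j, c).stain.pixels)
        for j in range(config.n_cycles)
        for c in range(config.n_channels_per_cycle)}
    for i in range(config.n_fovs)
}
table = profile_cells(truth.instance_maps, stacks, mad_k=None,
                      threshold_method="otsu")

print(f"profiled {len(table)} cells x {len(table.markers)} markers")
print("phenotype calls:")
print(table.phenotypes.value_counts().to_string())

planted = pd.concat([truth.cell_tables[i].assign(fov=i)
                     for i in range(config.n_fovs)])
merged = table.data.assign(phenotype=table.phenotypes.values).merge(
    planted, on=["fov", "cell_id"], suffixes=("", "_gt"))
agree = (merged["phenotype"] == merged["phenotype_gt"]).mean()
print(f"agreement with planted phenotypes: {100 * agree:.1f}%")
# with well-separated on/off intensities the gating rules reproduce the
# planted immune populations almost perfectly
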