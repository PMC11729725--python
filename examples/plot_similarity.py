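"""Heatmap of the sample similarity matrix from `vgstats similarity` output.

Usage: python examples/plot_similarity.py similarity.tsv similarity.png
"""

import sys

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

matrix = pd.read_csv(sys.argv[1], sep="\t", index_col=0)
fig, ax = plt.subplots(figsize=(5, 4))
im = ax.imshow(matrix.values, vmin=0, vmax=1, cmap="viridis")
ax.set_xticks(range(len(matrix)), matrix.columns, rotation=90)
ax.set_yticks(range(len(matrix)), matrix.index)
fig.colorbar(im, label="weighted Jaccard")
fig.tight_layout()
fig.savefig(sys.argv[2], dpi=150)
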