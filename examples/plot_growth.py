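"""Plot a pangenome growth curve from `vgstats growth` TSV output.

Usage: python examples/plot_growth.py growth.tsv growth.png
"""

import sys

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

table = pd.read_csv(sys.argv[1], sep="\t", comment="#")
fig, ax = plt.subplots(figsize=(5, 4))
ax.plot(table["k"], table["pan_bp"], "o-", label="pangenome bp")
ax.plot(table["k"], table["core_bp"], "s-", label="core bp")
ax.set_xlabel("samples drawn (k)")
ax.set_ylabel("bp")
ax.legend()
fig.tight_layout()
fig.savefig(sys.argv[2], dpi=150)
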