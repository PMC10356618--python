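"""Generate a synthetic comparative-transcriptomics dataset.

Builds a random 9-species tree, simulates orthogroups with gain/loss
presence structure, plants trait regulation at the root of the tree for
10% of orthogroups, and writes the whole fixture (tree, orthogroup table,
per-species DE statistics, proteome, config) to disk.
"""
from pathlib import Path

from phylorecruit.simulate import write_fixture

out = write_fixture(Path("scratch/example_fixture"), seed=11, n_hogs=2000)
print(f"fixture written to {out}")
for name in sorted(p.name for p in out.iterdir()):
    print(" ", name)
print(
    "\ntruth.tsv records, per orthogroup, the node where the gene family\n"
    "originated and (when planted) the node where its trait regulation was\n"
    "recruited — the ground truth the analysis should recover."
)
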