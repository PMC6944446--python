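#!/usr/bin/env python
"""Metagene 5'->3' coverage profiles.

Bins every transcript's coverage into 20 equal-weight segments, averages
them with equal gene weight, and contrasts the 5'-skewed gene set against
the background, reporting the detected bins-1-2 excess.
"""

from pathlib import Path

import pandas as pd

from gcfate.pipeline import RunConfig, run_metagene

OUT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    skew = set(pd.read_csv(OUT / "synth/skew_genes.tsv", sep="\t")["gene_id"])
    cfg = RunConfig(out_dir=OUT, seed=7, n_genes=300,
                    fasta=OUT / "synth/transcripts.fa",
                    annotation=OUT / "synth/annotation.gtf",
                    coverage=OUT / "synth/coverage.tsv")
    paths = run_metagene(cfg, target_genes=skew)
    gp = pd.read_csv(paths["group_profile"], sep="\t")
    print(f"group profile over {gp['n'].iloc[0]} transcripts "
          f"-> {paths['group_profile']}")
    print(f"  bins 1-2 carry {gp['mean'].iloc[:2].sum():.3f} of the reads "
          "(0.100 expected for uniform coverage)")
    if "contrast" in paths:
        print(f"  target-vs-all contrast -> {paths['contrast']}")
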