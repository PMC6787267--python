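"""Classify every pair into an ecological process and aggregate the
contribution percentages per within-site and between-site module.

Reads results/data/ and results/pairwise_indices.tsv, writes
results/pairwise_processes.tsv and results/process_fractions.tsv.
"""

from pathlib import Path

import pandas as pd

from fungal_assembly import classify_pair, enumerate_modules, fractions_table
from fungal_assembly.community_io import read_metadata, write_result_table

BASE = Path(__file__).resolve().parents[1] / "results"

def main() -> None:
    metadata = read_metadata(BASE / "data" / "metadata.tsv")
    pairwise = pd.read_csv(BASE / "pairwise_indices.tsv", sep="\t")
    pairwise["process"] = [
        classify_pair(row.beta_nti, row.rc_bray).value
        for row in pairwise.itertuples()
    ]
    write_result_table(pairwise, BASE / "pairwise_processes.tsv")

    modules = enumerate_modules(metadata)
    fractions = fractions_table(pairwise, modules)
    write_result_table(fractions, BASE / "process_fractions.tsv")

    within = fractions[~fractions["module"].str.contains("-")]
    between = fractions[fractions["module"].str.contains("-")]
    print("within-site deterministic total: "
          f"{within['deterministic_total'].min():.2f}-"
          f"{within['deterministic_total'].max():.2f}%")
    print("between-site deterministic total: "
          f"{between['deterministic_total'].min():.2f}-"
          f"{between['deterministic_total'].max():.2f}%")
    print(fractions.to_string(index=False))

if __name__ == "__main__":
    main()
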