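"""Alpha diversity along the gradient, distance decay of beta diversity,
and the ANOSIM test of among-site community differences.

Reads results/data/, writes results/alpha_diversity.tsv,
results/diversity_gradient_stats.tsv.
"""

from pathlib import Path

import pandas as pd

from fungal_assembly import anosim, distance_decay, pearson
from fungal_assembly.community_io import (
    read_community_table,
    read_metadata,
    write_result_table,
)
from fungal_assembly.diversity import alpha_diversity, beta_diversity

BASE = Path(__file__).resolve().parents[1] / "results"

def main() -> None:
    table = read_community_table(BASE / "data" / "otu_table.tsv")
    metadata = read_metadata(BASE / "data" / "metadata.tsv")

    alpha = alpha_diversity(table)
    alpha.to_csv(BASE / "alpha_diversity.tsv", sep="\t")

    rows = []
    for index in ("shannon", "richness"):
        r, p = pearson(alpha[index], metadata.loc[alpha.index, "elevation"])
        rows.append({"analysis": f"alpha_{index}_vs_elevation",
                     "statistic": r, "p_value": p})
        print(f"{index} vs elevation: r = {r:+.3f}, p = {p:.2g}")

    elev = metadata["elevation"]
    for metric in ("bray", "jaccard"):
        dm = beta_diversity(table, metric=metric)
        decay = distance_decay(dm, elev, permutations=999, seed=1)
        rows.append({"analysis": f"distance_decay_{metric}",
                     "statistic": decay.r, "p_value": decay.p_value,
                     "slope": decay.slope})
        print(f"distance decay ({metric}): slope = {decay.slope:.3e}/m, "
              f"r = {decay.r:.3f}, p = {decay.p_value:.3f}")
        res = anosim(dm, metadata.loc[list(dm.ids), "group"],
                     permutations=999, seed=1)
        rows.append({"analysis": f"anosim_{metric}",
                     "statistic": res.statistic, "p_value": res.p_value})
        print(f"anosim ({metric}): R = {res.statistic:.3f}, "
              f"p = {res.p_value:.3f}")

    write_result_table(pd.DataFrame(rows),
                       BASE / "diversity_gradient_stats.tsv")

if __name__ == "__main__":
    main()
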