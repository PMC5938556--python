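"""Alpha diversity and absolute-abundance contrasts.

Computes per-sample richness and Shannon index on the filtered table,
compares every environment pair (seasons pooled) and every within-
environment season pair with Wilcoxon rank-sum tests and Hodges–Lehmann
magnitudes, and does the same for the qPCR 16S copies per m².  Writes
diversity.tsv and comparisons.tsv under results/alpha/.
"""

from pathlib import Path

import pandas as pd

from dustair import alpha
from dustair.io_tables import read_count_table, read_metadata
from dustair.pipeline import compare_all_groups

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts = read_count_table(BASE / "qc" / "counts.filtered.tsv")
    metadata = read_metadata(BASE / "qc" / "metadata.filtered.tsv")
    qpcr = pd.read_csv(BASE / "dataset" / "qpcr.tsv", sep="\t", comment="#")

    diversity = alpha.diversity_table(counts)
    env = {s: metadata.environment_of(s) for s in diversity.index}
    group_means = diversity.assign(environment=[env[s] for s in diversity.index]) \
        .groupby("environment")[["richness", "shannon"]].mean()
    print("group-mean diversity:")
    print(group_means.round(2).to_string())

    metrics = diversity.join(
        qpcr.set_index("sample_id")["measured_copies_per_m2"].rename("copies_per_m2"),
        how="outer",
    )
    comparisons = compare_all_groups(metrics, metadata)
    sig = comparisons[comparisons["significant"] == True]  # noqa: E712
    print(f"{len(sig)}/{len(comparisons)} comparisons significant at 0.05")
    for _, row in comparisons[comparisons["contrast"] == "pooled"].iterrows():
        print(f"  {row['metric']:>14} {row['group_a']} vs {row['group_b']}: "
              f"p={row['p_value']:.2e} |HL|={row['hl_abs']:.3g}")

    out = BASE / "alpha"
    out.mkdir(parents=True, exist_ok=True)
    diversity.to_csv(out / "diversity.tsv", sep="\t")
    comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
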