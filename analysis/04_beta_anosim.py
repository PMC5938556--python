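"""Community structure: rarefied Bray–Curtis + ANOSIM.

Rarefies the filtered table to 8000 reads per sample, computes the
Bray–Curtis dissimilarity matrix, and runs ANOSIM for every environment
pair (seasons pooled) and every within-environment season contrast.
Writes the matrix and anosim.tsv under results/beta/.
"""

import itertools
from pathlib import Path

import pandas as pd

from dustair import beta, qc
from dustair.io_tables import ENVIRONMENTS, read_count_table, read_metadata

BASE = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 42) -> None:
    counts = read_count_table(BASE / "qc" / "counts.filtered.tsv")
    metadata = read_metadata(BASE / "qc" / "metadata.filtered.tsv")

    keep = [s for s in counts.sample_ids if counts.sample_totals()[s] >= 8000]
    rarefied = qc.rarefy(counts.select_samples(keep), 8000, seed=seed)
    dm = beta.bray_curtis_matrix(rarefied)
    env = {s: metadata.environment_of(s) for s in rarefied.sample_ids}

    results = []
    for a, b in itertools.combinations(ENVIRONMENTS, 2):
        sids = [s for s in rarefied.sample_ids if env[s] in (a, b)]
        res = beta.anosim(dm.filter(sids), {s: env[s] for s in sids},
                          n_permutations=999, seed=seed, grouping=f"{a} vs {b}")
        results.append(res)
        print(f"ANOSIM {res.grouping}: R={res.r:.3f} p={res.p_value:.4f}")
    for environment in ENVIRONMENTS:
        sids = [s for s in rarefied.sample_ids if env[s] == environment]
        seasons = {s: metadata.season_of(s) for s in sids}
        res = beta.anosim(dm.filter(sids), seasons, n_permutations=999, seed=seed,
                          grouping=f"{environment}: winter vs summer")
        results.append(res)
        print(f"ANOSIM {res.grouping}: R={res.r:.3f} p={res.p_value:.4f}")

    out = BASE / "beta"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        out / "braycurtis.tsv", sep="\t")
    pd.DataFrame([{"grouping": r.grouping, "R": r.r, "p_value": r.p_value,
                   "n_permutations": r.n_permutations} for r in results]).to_csv(
        out / "anosim.tsv", sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
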