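"""Clean the simulated OTU table with the study's filtering rules.

Applies, in order: singleton-OTU removal, non-target-taxon removal
(Archaea/Eukaryota/unknown domains, Chloroplast class, Mitochondrion
family), negative-control contaminant removal (max-in-blanks rule), empty
row cleanup and the 8000-read minimum-depth filter; then checks technical
replicate concordance by average-linkage clustering of Bray–Curtis
dissimilarities and collapses each replicate pair to one representative.
Writes the filtered table and the filter log under results/qc/.
"""

import json
from pathlib import Path

import pandas as pd

from dustair import qc
from dustair.io_tables import read_count_table, read_metadata, read_taxonomy, write_count_table, write_metadata

BASE = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 42) -> None:
    counts = read_count_table(BASE / "dataset" / "counts.tsv")
    metadata = read_metadata(BASE / "dataset" / "metadata.tsv")
    taxonomy = read_taxonomy(BASE / "dataset" / "taxonomy.tsv")
    truth = json.loads((BASE / "dataset" / "truth.json").read_text())

    logs = []
    counts, log = qc.remove_singletons(counts); logs.append(log)
    counts, log = qc.remove_nontarget_taxa(counts, taxonomy); logs.append(log)
    counts, log = qc.remove_contaminant_otus(counts, metadata); logs.append(log)
    counts, log = qc.drop_empty_otus(counts); logs.append(log)
    counts, log = qc.filter_min_depth(counts); logs.append(log)
    for log in logs:
        print(log.summary())

    flagged = set(logs[2].otus_removed)
    planted = set(truth["contaminant_otus"])
    print(f"contaminant recovery: {len(flagged & planted)}/{len(planted)} planted, "
          f"{len(flagged - planted)} false flags")

    metadata = metadata.subset([s for s in metadata.sample_ids if s in counts.sample_ids])
    rep = qc.replicate_concordance(counts, metadata, seed=seed)
    print(f"replicate concordance: {rep.attrs['concordant_fraction']:.2f} "
          f"({rep.attrs['n_evaluable']} evaluable pairs)")
    counts, metadata = qc.collapse_replicates(counts, metadata)

    out = BASE / "qc"
    out.mkdir(parents=True, exist_ok=True)
    write_count_table(counts, out / "counts.filtered.tsv")
    write_metadata(metadata, out / "metadata.filtered.tsv")
    pd.DataFrame(
        [{"stage": l.stage, "otus_removed": len(l.otus_removed),
          "samples_removed": len(l.samples_removed)} for l in logs]
    ).to_csv(out / "filter_log.tsv", sep="\t", index=False)
    rep.to_csv(out / "replicates.tsv", sep="\t", index=False)
    print(f"filtered table: {counts.n_otus} OTUs x {counts.n_samples} samples -> {out}")


if __name__ == "__main__":
    main()
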