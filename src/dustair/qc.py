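"""OTU-table cleaning: singleton removal, non-target taxa, negative-control
contaminants, depth filtering, rarefaction, and technical-replicate handling.

The stages are designed to be applied in the order singleton -> non-target
-> contaminant -> depth filter -> (rarefy); each returns the filtered table
plus a :class:`FilterLog` recording what was removed and the per-sample read
fraction lost, so the cumulative accounting can be reported alongside the
results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .errors import ConfigurationError, DataError
from .io_tables import CountTable, SampleMetadata, TaxonomyTable

DEFAULT_MIN_READS = 8000
DEFAULT_RAREFACTION_DEPTH = 8000

#: Lineage labels whose OTUs are off-target for a bacterial 16S survey.
NONTARGET_DOMAINS = frozenset({"archaea", "eukaryota", "unknown"})
NONTARGET_CLASSES = frozenset({"chloroplast"})
NONTARGET_FAMILIES = frozenset({"mitochondrion"})


@dataclass
class FilterLog:
    """Record of one filtering stage."""

    stage: str
    parameters: dict = field(default_factory=dict)
    otus_removed: list[str] = field(default_factory=list)
    samples_removed: list[str] = field(default_factory=list)
    read_fraction_removed: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        frac = self.read_fraction_removed
        if len(frac) and ((frac < -1e-12) | (frac > 1 + 1e-12)).any():
            raise ValueError("read fractions must lie in [0, 1]")

    def summary(self) -> str:
        n_reads = len(self.read_fraction_removed)
        med = self.read_fraction_removed.median() if n_reads else 0.0
        return (
            f"{self.stage}: removed {len(self.otus_removed)} OTUs, "
            f"{len(self.samples_removed)} samples; median read fraction removed "
            f"{med:.4f}"
        )


def _read_fraction(before: CountTable, removed_otus: list[str]) -> pd.Series:
    totals = before.sample_totals().astype(float)
    if not removed_otus:
        return pd.Series(0.0, index=before.sample_ids)
    lost = before.df.loc[removed_otus].sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (lost / totals).fillna(0.0)
    return frac


# ---------------------------------------------------------------------------
# OTU-level filters
# ---------------------------------------------------------------------------


def remove_singletons(counts: CountTable) -> tuple[CountTable, FilterLog]:
    """Drop OTUs whose total count across all samples equals exactly 1."""
    totals = counts.otu_totals()
    singletons = list(totals.index[totals == 1])
    log = FilterLog(
        "remove_singletons",
        otus_removed=singletons,
        read_fraction_removed=_read_fraction(counts, singletons),
    )
    return counts.drop_otus(singletons), log


def remove_nontarget_taxa(
    counts: CountTable, taxonomy: TaxonomyTable
) -> tuple[CountTable, FilterLog]:
    """Drop OTUs classified outside the bacterial 16S target.

    An OTU is removed iff its domain is Archaea, Eukaryota or unknown, its
    class is Chloroplast, or its family is Mitochondrion (case-insensitive,
    each rule scoped to its own rank).
    """
    missing = [o for o in counts.otu_ids if o not in taxonomy.lineages]
    if missing:
        raise DataError(f"OTUs missing from taxonomy: {missing}")

    def is_nontarget(otu: str) -> bool:
        domain = taxonomy.rank_label(otu, "domain")
        cls = taxonomy.rank_label(otu, "class")
        family = taxonomy.rank_label(otu, "family")
        return (
            (domain or "").lower() in NONTARGET_DOMAINS
            or (cls or "").lower() in NONTARGET_CLASSES
            or (family or "").lower() in NONTARGET_FAMILIES
        )

    removed = [o for o in counts.otu_ids if is_nontarget(o)]
    log = FilterLog(
        "remove_nontarget_taxa",
        parameters={
            "domains": sorted(NONTARGET_DOMAINS),
            "classes": sorted(NONTARGET_CLASSES),
            "families": sorted(NONTARGET_FAMILIES),
        },
        otus_removed=removed,
        read_fraction_removed=_read_fraction(counts, removed),
    )
    return counts.drop_otus(removed), log


def remove_contaminant_otus(
    counts: CountTable, metadata: SampleMetadata
) -> tuple[CountTable, FilterLog]:
    """Drop OTUs better represented in negative controls than in any sample.

    An OTU is a contaminant iff its maximum count over all negative-control
    columns strictly exceeds its maximum over all real-sample columns (ties
    keep the OTU — a read misassigned into a blank by tag-switching should
    not disqualify a genuinely abundant OTU).  Control columns are dropped
    from the returned table.
    """
    controls = [s for s in metadata.controls() if s in counts.sample_ids]
    if not controls:
        raise DataError(
            "no negative-control samples present; skip the contaminant stage "
            "explicitly if the study design has no controls"
        )
    real = [s for s in counts.sample_ids if s not in set(controls)]
    ctrl_max = counts.df[controls].max(axis=1)
    real_max = (
        counts.df[real].max(axis=1) if real else pd.Series(0, index=counts.df.index)
    )
    removed = list(counts.df.index[ctrl_max > real_max])
    log = FilterLog(
        "remove_contaminant_otus",
        parameters={"n_controls": len(controls)},
        otus_removed=removed,
        samples_removed=controls,
        read_fraction_removed=_read_fraction(counts, removed)[real],
    )
    return counts.drop_otus(removed).drop_samples(controls), log


def drop_empty_otus(counts: CountTable) -> tuple[CountTable, FilterLog]:
    """Final cleanup: drop OTU rows that became all-zero upstream."""
    totals = counts.otu_totals()
    empty = list(totals.index[totals == 0])
    log = FilterLog(
        "drop_empty_otus",
        otus_removed=empty,
        read_fraction_removed=pd.Series(0.0, index=counts.sample_ids),
    )
    return counts.drop_otus(empty), log


# ---------------------------------------------------------------------------
# sample-level filters
# ---------------------------------------------------------------------------


def filter_min_depth(
    counts: CountTable, min_reads: int = DEFAULT_MIN_READS
) -> tuple[CountTable, FilterLog]:
    """Drop sample columns with fewer than ``min_reads`` total reads."""
    if min_reads < 0:
        raise ConfigurationError("min_reads must be >= 0")
    totals = counts.sample_totals()
    removed = list(totals.index[totals < min_reads])
    log = FilterLog(
        "filter_min_depth",
        parameters={"min_reads": min_reads},
        samples_removed=removed,
        read_fraction_removed=pd.Series(
            [1.0 if s in set(removed) else 0.0 for s in counts.sample_ids],
            index=counts.sample_ids,
        ),
    )
    return counts.drop_samples(removed), log


def rarefy(counts: CountTable, depth: int = DEFAULT_RAREFACTION_DEPTH,
           seed: int | None = None) -> CountTable:
    """Subsample every column to exactly ``depth`` reads without replacement.

    Each column is drawn from the multivariate hypergeometric distribution
    on its counts, matching "randomly subsample N reads" semantics exactly:
    column totals equal ``depth`` and no OTU exceeds its input count.
    """
    if depth < 0:
        raise ConfigurationError("depth must be >= 0")
    totals = counts.sample_totals()
    shallow = list(totals.index[totals < depth])
    if shallow:
        raise DataError(
            f"sample(s) below rarefaction depth {depth}: {shallow}; "
            "apply filter_min_depth first"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts.counts)
    for j, sid in enumerate(counts.sample_ids):
        col = counts.counts[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return CountTable(pd.DataFrame(out, index=counts.df.index, columns=counts.df.columns))


# ---------------------------------------------------------------------------
# technical replicates
# ---------------------------------------------------------------------------


def _replicate_pairs(metadata: SampleMetadata) -> list[tuple[str, str]]:
    pairs = []
    for sid, ref in metadata.df["replicate_of"].items():
        if ref:
            pairs.append((ref, sid))
    return pairs


def replicate_concordance(
    counts: CountTable,
    metadata: SampleMetadata,
    depth: int = DEFAULT_RAREFACTION_DEPTH,
    seed: int | None = None,
    rarefied: bool = False,
) -> pd.DataFrame:
    """Do technical replicates cluster with their partner?

    Samples are rarefied to a common depth (unless ``rarefied=True``),
    average-linkage hierarchical clustering is built on Bray–Curtis
    dissimilarities, and a pair is concordant iff its two members are each
    other's first merge partner (they are joined as two singleton leaves).
    Pairs whose partner is missing from ``counts`` (e.g. depth-filtered) are
    marked unevaluable.  Returns one row per pair plus the overall fraction
    in ``DataFrame.attrs["concordant_fraction"]``.
    """
    pairs = _replicate_pairs(metadata)
    if not pairs:
        raise DataError("no replicate pairs in metadata")
    work = counts
    if not rarefied:
        deep = [s for s in work.sample_ids
                if work.sample_totals()[s] >= depth]
        work = rarefy(work.select_samples(deep), depth, seed)
    ids = work.sample_ids
    index = {s: i for i, s in enumerate(ids)}
    mat = work.counts.T.astype(float)
    z = linkage(pdist(mat, metric="braycurtis"), method="average")
    # leaves merged directly as two singletons
    direct = {(int(a), int(b)) for a, b, _, _ in z if a < len(ids) and b < len(ids)}
    rows = []
    n_eval = n_conc = 0
    for orig, rep in pairs:
        if orig not in index or rep not in index:
            rows.append({"sample_id": orig, "replicate_id": rep, "verdict": "unevaluable"})
            continue
        i, j = sorted((index[orig], index[rep]))
        concordant = (i, j) in direct
        n_eval += 1
        n_conc += concordant
        rows.append({
            "sample_id": orig,
            "replicate_id": rep,
            "verdict": "concordant" if concordant else "discordant",
        })
    report = pd.DataFrame(rows)
    report.attrs["concordant_fraction"] = (n_conc / n_eval) if n_eval else float("nan")
    report.attrs["n_evaluable"] = n_eval
    return report


def collapse_replicates(
    counts: CountTable, metadata: SampleMetadata
) -> tuple[CountTable, SampleMetadata]:
    """Keep one member per replicate group (lexicographically first id).

    A deterministic stand-in for choosing a representative arbitrarily:
    replicate groups are formed by following ``replicate_of`` links, the
    smallest sample id present in ``counts`` is retained, and the rest are
    dropped from both tables.
    """
    parent: dict[str, str] = {}

    def find(s: str) -> str:
        while parent.get(s, s) != s:
            parent[s] = parent.get(parent[s], parent[s])
            s = parent[s]
        return s

    for sid, ref in metadata.df["replicate_of"].items():
        if ref:
            ra, rb = find(sid), find(ref)
            if ra != rb:
                parent[ra] = rb
    groups: dict[str, list[str]] = {}
    for sid in metadata.sample_ids:
        groups.setdefault(find(sid), []).append(sid)

    drop: list[str] = []
    present = set(counts.sample_ids)
    for members in groups.values():
        if len(members) < 2:
            continue
        candidates = sorted(m for m in members if m in present) or sorted(members)
        drop.extend(m for m in members if m != candidates[0])
    drop_counts = [s for s in drop if s in present]
    new_counts = counts.drop_samples(drop_counts)
    new_meta = metadata.df.drop(index=[s for s in drop if s in metadata.df.index]).copy()
    new_meta["replicate_of"] = ""
    return new_counts, SampleMetadata(new_meta)
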