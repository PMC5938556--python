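"""End-to-end orchestration: simulate (or load) -> QC -> analyses -> report.

One :func:`run_pipeline` call executes the full settled-dust analysis under
a single :class:`PipelineConfig`: QC filtering in the fixed order singleton
-> non-target -> contaminant -> depth filter, replicate concordance and
collapse, alpha diversity with all group comparisons, qPCR abundance
comparisons, rarefied Bray–Curtis + ANOSIM for every environment pair and
within-environment season contrast, CLR differential abundance at four
taxonomic ranks, and the matched stable–home transfer ranking.  All
randomness is seeded from ``config.seed`` through named child streams, so
identical configs give identical reports.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alpha, beta, qc, transfer
from .errors import ConfigurationError, DustairError
from .io_tables import (
    ENVIRONMENTS,
    SEASONS,
    CountTable,
    SampleMetadata,
    TaxonomyTable,
    read_count_table,
    read_metadata,
    read_taxonomy,
    validate_dataset,
)
from .synthetic import SyntheticConfig, SyntheticDataset, generate_dataset, child_rng

_PIPELINE_STREAMS = {"rarefaction": 11, "anosim": 12, "diffabund": 13,
                     "replicates": 14, "transfer": 15}


def pipeline_rng_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage integer seed split off the master seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_PIPELINE_STREAMS[stage],))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    """Stage switches and parameters for one pipeline run."""

    seed: int = 0
    input_dir: str | None = None  # None = simulate
    simulate: SyntheticConfig | None = None
    min_depth: int = qc.DEFAULT_MIN_READS
    rarefaction_depth: int = qc.DEFAULT_RAREFACTION_DEPTH
    permutations: int = 999
    mc_instances: int = beta.DEFAULT_INSTANCES
    prior: float = beta.DEFAULT_PRIOR
    alpha_level: float = 0.05
    alpha_on_rarefied: bool = False
    stratify_season_diffabund: bool = False
    diffabund_ranks: tuple[str, ...] = ("phylum", "order", "family", "genus")
    pooled_transfer_ranking: bool = False
    run_qc: bool = True
    run_alpha: bool = True
    run_beta: bool = True
    run_diffabund: bool = True
    run_transfer: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_level < 1.0:
            raise ConfigurationError("alpha_level must lie in (0, 1)")
        for name in ("min_depth", "rarefaction_depth", "permutations", "mc_instances"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.prior <= 0:
            raise ConfigurationError("prior must be > 0")
        if self.input_dir is None and self.simulate is None:
            self.simulate = SyntheticConfig(seed=self.seed)


@dataclass
class AnalysisReport:
    """Structured results of one full run."""

    config: PipelineConfig
    validation: list[str] = field(default_factory=list)
    filter_logs: list[qc.FilterLog] = field(default_factory=list)
    replicate_report: pd.DataFrame | None = None
    diversity: pd.DataFrame | None = None
    comparisons: pd.DataFrame | None = None
    anosim_results: list[beta.AnosimResult] = field(default_factory=list)
    diffabund: dict[str, dict[str, pd.DataFrame]] = field(default_factory=dict)
    transfer_records: pd.DataFrame | None = None
    transfer_result: transfer.TransferSummary | None = None
    skipped: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _load_inputs(config: PipelineConfig):
    if config.input_dir is not None:
        d = Path(config.input_dir)
        counts = read_count_table(d / "counts.tsv")
        metadata = read_metadata(d / "metadata.tsv")
        taxonomy = read_taxonomy(d / "taxonomy.tsv")
        qpcr_path = d / "qpcr.tsv"
        qpcr = pd.read_csv(qpcr_path, sep="\t", comment="#") if qpcr_path.exists() else None
        return counts, metadata, taxonomy, qpcr
    dataset: SyntheticDataset = generate_dataset(config.simulate)
    return dataset.counts, dataset.metadata, dataset.taxonomy, dataset.qpcr


def _environment_groups(metadata: SampleMetadata, sample_ids) -> dict[str, str]:
    present = [s for s in sample_ids]
    return {s: metadata.environment_of(s) for s in present}


def compare_all_groups(
    metrics: pd.DataFrame, metadata: SampleMetadata, alpha_level: float = 0.05
) -> pd.DataFrame:
    """Every environment-pair (seasons pooled) and within-environment season
    comparison, for every metric column.

    ``metrics`` is indexed by sample id with one column per metric
    (e.g. richness, shannon, copies_per_m2 — samples may differ per metric;
    NaN rows are ignored for that metric).  Groups with fewer than 2 values
    are marked ``insufficient n``.
    """
    rows = []
    meta = metadata.df

    def values(metric, environment, season=None):
        sids = [
            s
            for s in metrics.index
            if s in meta.index
            and not meta.at[s, "is_control"]
            and meta.at[s, "environment"] == environment
            and (season is None or meta.at[s, "season"] == season)
        ]
        vals = metrics.loc[sids, metric].dropna()
        return vals.to_numpy()

    for metric in metrics.columns:
        for env_a, env_b in itertools.combinations(ENVIRONMENTS, 2):
            x, y = values(metric, env_a), values(metric, env_b)
            rows.append(_comparison_row(metric, env_a, env_b, "pooled", x, y, alpha_level))
        for env in ENVIRONMENTS:
            x = values(metric, env, "winter")
            y = values(metric, env, "summer")
            rows.append(_comparison_row(metric, f"{env}:winter", f"{env}:summer",
                                        "season", x, y, alpha_level))
    return pd.DataFrame(rows)


def _comparison_row(metric, label_a, label_b, contrast, x, y, alpha_level):
    base = {"metric": metric, "group_a": label_a, "group_b": label_b,
            "contrast": contrast, "n_a": len(x), "n_b": len(y)}
    if len(x) < 2 or len(y) < 2:
        return {**base, "status": "insufficient n", "W": np.nan, "p_value": np.nan,
                "hl_estimate": np.nan, "hl_abs": np.nan, "significant": False}
    comp = alpha.wilcoxon_rank_sum(x, y, label_a, label_b)
    return {**base, "status": "degenerate" if comp.degenerate else "ok",
            "W": comp.statistic, "p_value": comp.p_value,
            "hl_estimate": comp.hl_estimate, "hl_abs": comp.hl_abs,
            "significant": bool(comp.p_value < alpha_level)}


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the full analysis under one config; deterministic given config."""
    report = AnalysisReport(config=config)
    counts, metadata, taxonomy, qpcr = _load_inputs(config)
    report.validation = validate_dataset(counts, metadata, taxonomy)
    fatal = [v for v in report.validation if "unpaired farm" not in v]
    if fatal:
        raise DustairError(f"input validation failed: {fatal}")

    # ---- QC ------------------------------------------------------------
    if config.run_qc:
        counts, log = qc.remove_singletons(counts)
        report.filter_logs.append(log)
        counts, log = qc.remove_nontarget_taxa(counts, taxonomy)
        report.filter_logs.append(log)
        if metadata.controls():
            counts, log = qc.remove_contaminant_otus(counts, metadata)
            report.filter_logs.append(log)
        counts, log = qc.drop_empty_otus(counts)
        report.filter_logs.append(log)
        counts, log = qc.filter_min_depth(counts, config.min_depth)
        report.filter_logs.append(log)
    else:
        report.skipped.append("qc")
        if metadata.controls():
            counts = counts.drop_samples(
                [s for s in metadata.controls() if s in counts.sample_ids]
            )
    metadata_kept = metadata.subset([s for s in metadata.sample_ids
                                     if s in set(counts.sample_ids)])

    if counts.n_samples == 0 or counts.n_otus == 0:
        report.skipped.extend(["replicates", "alpha", "beta", "diffabund", "transfer"])
        report.provenance = _provenance(config, note="empty-analysis: no samples/OTUs "
                                        "survived filtering")
        return report

    # ---- technical replicates ------------------------------------------
    has_reps = (metadata_kept.df["replicate_of"] != "").any()
    if has_reps:
        deep = counts.sample_totals() >= config.rarefaction_depth
        if deep.any():
            report.replicate_report = qc.replicate_concordance(
                counts, metadata_kept, config.rarefaction_depth,
                seed=pipeline_rng_seed(config.seed, "replicates"),
            )
        counts, metadata_kept = qc.collapse_replicates(counts, metadata_kept)

    # ---- alpha diversity + comparisons ---------------------------------
    if config.run_alpha:
        alpha_counts = counts
        if config.alpha_on_rarefied:
            alpha_counts = qc.rarefy(counts, config.rarefaction_depth,
                                     seed=pipeline_rng_seed(config.seed, "rarefaction"))
        report.diversity = alpha.diversity_table(alpha_counts)
        metrics = report.diversity.copy()
        if qpcr is not None and len(qpcr):
            copies = qpcr.set_index("sample_id")["measured_copies_per_m2"]
            metrics = metrics.join(copies.rename("copies_per_m2"), how="outer")
        report.comparisons = compare_all_groups(metrics, metadata, config.alpha_level)
    else:
        report.skipped.append("alpha")

    # ---- beta diversity ------------------------------------------------
    rarefied = None
    if config.run_beta or config.run_transfer:
        keep = [s for s in counts.sample_ids
                if counts.sample_totals()[s] >= config.rarefaction_depth]
        rarefied = qc.rarefy(counts.select_samples(keep), config.rarefaction_depth,
                             seed=pipeline_rng_seed(config.seed, "rarefaction"))
    if config.run_beta:
        dm = beta.bray_curtis_matrix(rarefied)
        env = _environment_groups(metadata_kept, rarefied.sample_ids)
        seed_anosim = pipeline_rng_seed(config.seed, "anosim")
        for env_a, env_b in itertools.combinations(ENVIRONMENTS, 2):
            sids = [s for s in rarefied.sample_ids if env[s] in (env_a, env_b)]
            if len({env[s] for s in sids}) < 2:
                continue
            res = beta.anosim(dm.filter(sids), {s: env[s] for s in sids},
                              config.permutations, seed_anosim,
                              grouping=f"{env_a} vs {env_b}")
            report.anosim_results.append(res)
        for environment in ENVIRONMENTS:
            sids = [s for s in rarefied.sample_ids if env[s] == environment]
            seasons = {s: metadata_kept.season_of(s) for s in sids}
            sizes = pd.Series(list(seasons.values())).value_counts()
            if len(sizes) < 2 or sizes.min() < 2:
                continue
            res = beta.anosim(dm.filter(sids), seasons, config.permutations,
                              seed_anosim, grouping=f"{environment}: winter vs summer")
            report.anosim_results.append(res)
    else:
        report.skipped.append("beta")

    # ---- differential abundance ----------------------------------------
    if config.run_diffabund:
        seed_da = pipeline_rng_seed(config.seed, "diffabund")
        env = _environment_groups(metadata_kept, counts.sample_ids)
        strata = SEASONS if config.stratify_season_diffabund else (None,)
        for env_a, env_b in itertools.combinations(ENVIRONMENTS, 2):
            for season in strata:
                key = f"{env_a}_vs_{env_b}"
                if season is not None:
                    key += f"_{season}"
                report.diffabund[key] = {}
                group_a = [s for s in counts.sample_ids if env[s] == env_a
                           and (season is None
                                or metadata_kept.season_of(s) == season)]
                group_b = [s for s in counts.sample_ids if env[s] == env_b
                           and (season is None
                                or metadata_kept.season_of(s) == season)]
                if len(group_a) < 2 or len(group_b) < 2:
                    continue
                for rank in config.diffabund_ranks:
                    res = beta.differential_abundance(
                        counts, taxonomy, rank, group_a, group_b,
                        n_instances=config.mc_instances, prior=config.prior,
                        seed=seed_da, label_a=env_a, label_b=env_b,
                    )
                    report.diffabund[key][rank] = res.table
    else:
        report.skipped.append("diffabund")

    # ---- transfer ranking ----------------------------------------------
    if config.run_transfer:
        dm = beta.bray_curtis_matrix(rarefied)
        records, log = transfer.matched_pair_ranks(
            dm, metadata_kept, pooled=config.pooled_transfer_ranking
        )
        report.skipped.extend(f"transfer:{entry}" for entry in log)
        if len(records) >= 2:
            report.transfer_records = transfer.records_table(records)
            report.transfer_result = transfer.transfer_summary(
                records, seed=pipeline_rng_seed(config.seed, "transfer")
            )
    else:
        report.skipped.append("transfer")

    report.provenance = _provenance(config)
    return report


def _provenance(config: PipelineConfig, note: str | None = None) -> dict:
    import dustair

    cfg = {k: v for k, v in asdict(config).items() if k != "simulate"}
    if config.simulate is not None:
        sim = {k: v for k, v in vars(config.simulate).items()
               if k not in ("profiles", "taxonomy_blocks", "contaminant_otus",
                            "group_sizes")}
        sim["group_sizes"] = {f"{e}/{s}": n
                              for (e, s), n in config.simulate.group_sizes.items()}
        cfg["simulate"] = sim
    prov = {"package": "dustair", "version": dustair.__version__,
            "seed": config.seed, "config": cfg}
    if note:
        prov["note"] = note
    return prov


# ---------------------------------------------------------------------------
# report serialisation
# ---------------------------------------------------------------------------


def write_report(report: AnalysisReport, outdir) -> None:
    """Write all report tables plus a machine-readable summary, atomically.

    Tables are TSV; the summary is JSON.  Files are first written to a
    temporary name and renamed, so a crashed run leaves ``*.INCOMPLETE``
    markers instead of truncated tables.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    def atomic(name: str, writer) -> None:
        tmp = out / (name + ".INCOMPLETE")
        writer(tmp)
        os.replace(tmp, out / name)

    if report.filter_logs:
        rows = [
            {"stage": log.stage, "n_otus_removed": len(log.otus_removed),
             "n_samples_removed": len(log.samples_removed),
             "median_read_fraction_removed":
                 float(log.read_fraction_removed.median())
                 if len(log.read_fraction_removed) else 0.0,
             "otus_removed": ",".join(log.otus_removed),
             "samples_removed": ",".join(log.samples_removed),
             "parameters": json.dumps(log.parameters, sort_keys=True)}
            for log in report.filter_logs
        ]
        atomic("filter_log.tsv",
               lambda p: pd.DataFrame(rows).to_csv(p, sep="\t", index=False))
    if report.diversity is not None:
        atomic("diversity.tsv", lambda p: report.diversity.to_csv(p, sep="\t"))
    if report.comparisons is not None:
        atomic("comparisons.tsv",
               lambda p: report.comparisons.to_csv(p, sep="\t", index=False))
    if report.anosim_results:
        df = pd.DataFrame([
            {"grouping": r.grouping, "R": r.r, "p_value": r.p_value,
             "n_permutations": r.n_permutations,
             "group_sizes": json.dumps(r.group_sizes, sort_keys=True)}
            for r in report.anosim_results
        ])
        atomic("anosim.tsv", lambda p: df.to_csv(p, sep="\t", index=False))
    for contrast, tables in report.diffabund.items():
        for rank, table in tables.items():
            atomic(f"diffabund_{rank}_{contrast}.tsv",
                   lambda p, t=table: t.to_csv(p, sep="\t"))
    if report.replicate_report is not None:
        atomic("replicates.tsv",
               lambda p: report.replicate_report.to_csv(p, sep="\t", index=False))
    if report.transfer_records is not None:
        atomic("pair_ranks.tsv",
               lambda p: report.transfer_records.to_csv(p, sep="\t", index=False))

    summary = summarise(report)
    atomic("summary.json", lambda p: Path(p).write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n", encoding="utf-8"))


def summarise(report: AnalysisReport) -> dict:
    """Condense a report into plain JSON-serialisable values."""
    summary: dict = {"provenance": report.provenance,
                     "validation": report.validation,
                     "skipped": report.skipped}
    if report.filter_logs:
        summary["filters"] = {log.stage: len(log.otus_removed)
                              for log in report.filter_logs}
    if report.replicate_report is not None:
        summary["replicate_concordant_fraction"] = float(
            report.replicate_report.attrs.get("concordant_fraction", float("nan")))
    if report.anosim_results:
        summary["anosim"] = {r.grouping: {"R": r.r, "p": r.p_value}
                             for r in report.anosim_results}
    if report.transfer_result is not None:
        t = report.transfer_result
        summary["transfer"] = {
            "n_pairs": t.n_pairs, "n_rank1": t.n_rank1,
            "binomial_p": t.binomial_p, "gof_p": t.gof_p,
            "mean_rank": t.mean_rank,
        }
    if report.diversity is not None:
        summary["n_samples_analysed"] = int(len(report.diversity))
    return summary
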