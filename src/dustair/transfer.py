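"""Matched stable–home similarity ranking: a test for direct airborne
transfer of bacteria from a farmer's pig stable to that farmer's home.

For every farm with both a stable and a home sample, the Bray–Curtis
dissimilarity between the farmer's home and the farmer's *own* stable is
ranked (ascending, rank 1 = most similar) among the dissimilarities between
that home and *every* stable in the same season stratum.  Under no transfer
the matched stable is exchangeable with the others and the rank is uniform
on {1..m}; an excess of rank-1 pairs indicates direct transfer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .errors import DataError
from .io_tables import SEASONS, SampleMetadata


@dataclass
class PairRankRecord:
    """Rank of one farm's matched stable–home dissimilarity."""

    farm_id: str
    season: str
    matched_dissimilarity: float
    rank: float  # midrank on ties
    comparison_set_size: int
    #: number of season strata this record is the best (minimum) rank over;
    #: the null rank-1 probability is 1 - (1 - 1/m)^n_strata
    n_strata: int = 1

    def __post_init__(self) -> None:
        if self.comparison_set_size < 2:
            raise ValueError("comparison set must have >= 2 members")
        if not 1.0 <= self.rank <= self.comparison_set_size:
            raise ValueError("rank outside [1, comparison_set_size]")


@dataclass
class TransferSummary:
    """Aggregate evidence for transfer across all matched pairs."""

    n_pairs: int
    n_rank1: int
    binomial_p: float  # P(X >= n_rank1) under per-pair success prob 1/m_i
    gof_statistic: float
    gof_p: float  # goodness of fit of the rank distribution vs uniform
    gof_method: str
    mean_rank: float
    ranks: list[float]


def matched_pair_ranks(
    dmatrix: DistanceMatrix,
    metadata: SampleMetadata,
    pooled: bool = False,
) -> tuple[list[PairRankRecord], list[str]]:
    """Rank every farm's own stable among all stables of the same season.

    Only samples present in ``dmatrix`` take part; farms missing either
    member in a stratum are skipped with a log entry.  When a farm has
    complete pairs in both seasons the better (minimum) rank is reported,
    avoiding cross-season dissimilarity inflation.  ``pooled=True`` instead
    ranks each matched dissimilarity within the pooled set of all
    non-matching stable–home dissimilarities of the stratum.

    Returns (records, log entries).
    """
    ids = set(dmatrix.ids)
    meta = metadata.df
    log: list[str] = []
    best: dict[str, PairRankRecord] = {}
    for season in SEASONS:
        in_season = meta[(~meta["is_control"]) & (meta["season"] == season)]
        stables = {
            row["farm_id"]: sid
            for sid, row in in_season[in_season["environment"] == "pig_stable"].iterrows()
            if sid in ids
        }
        homes = {
            row["farm_id"]: sid
            for sid, row in in_season[in_season["environment"] == "farm_home"].iterrows()
            if sid in ids
        }
        complete = sorted(set(stables) & set(homes))
        for farm in sorted(set(stables) ^ set(homes)):
            log.append(f"farm {farm!r} incomplete in {season}: skipped")
        if len(complete) < 2:
            if complete:
                log.append(
                    f"only one complete pair in {season}: no comparison set, skipped"
                )
            continue
        stable_ids = [stables[f] for f in sorted(stables)]
        if pooled:
            matched = {f: dmatrix[homes[f], stables[f]] for f in complete}
            non_matching = [
                dmatrix[homes[f], s_id]
                for f in complete
                for g, s_id in stables.items()
                if g != f
            ]
            pool = np.asarray(non_matching)
            for f in complete:
                d = matched[f]
                less, equal = (pool < d).sum(), (pool == d).sum()
                rank = less + (equal + 2) / 2.0  # midrank incl. the matched value
                rec = PairRankRecord(f, season, float(d), float(rank), pool.size + 1)
                if f in best:
                    keep = rec if rec.rank < best[f].rank else best[f]
                    keep.n_strata = best[f].n_strata + 1
                    best[f] = keep
                else:
                    best[f] = rec
        else:
            for f in complete:
                d_all = np.asarray([dmatrix[homes[f], s] for s in stable_ids])
                ranks = stats.rankdata(d_all)
                pos = stable_ids.index(stables[f])
                rec = PairRankRecord(
                    f, season, float(d_all[pos]), float(ranks[pos]), len(stable_ids)
                )
                if f in best:
                    keep = rec if rec.rank < best[f].rank else best[f]
                    keep.n_strata = best[f].n_strata + 1
                    best[f] = keep
                else:
                    best[f] = rec
    records = [best[f] for f in sorted(best)]
    return records, log


def _poisson_binomial_tail(k: int, success_probs: np.ndarray) -> float:
    """P(X >= k) for a sum of independent Bernoullis, by exact convolution."""
    pmf = np.array([1.0])
    for p in success_probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return float(pmf[k:].sum())


def transfer_summary(
    records: list[PairRankRecord], seed: int | None = None
) -> TransferSummary:
    """Summarise matched-pair ranks against the no-transfer null.

    ``binomial_p`` is the exact tail probability of observing at least the
    seen number of rank-1 pairs when each pair independently attains rank 1
    with its null probability: 1/m for a single-stratum record of
    comparison-set size m, and 1 - (1 - 1/m)^k for a record that is the
    best rank over k season strata.  The rank distribution
    is additionally tested against uniformity: an exact chi-square over the
    m rank categories (Monte-Carlo p, seeded) when all set sizes are equal
    and m <= 20, otherwise a chi-square over deciles of the normalised rank
    (rank - 0.5)/m.
    """
    if len(records) < 2:
        raise DataError("need >= 2 pair records to summarise")
    ranks = np.asarray([r.rank for r in records], dtype=float)
    sizes = np.asarray([r.comparison_set_size for r in records])
    strata = np.asarray([r.n_strata for r in records])
    n = len(records)
    k = int((ranks == 1.0).sum())
    # a best-of-k-strata record attains rank 1 with prob 1 - (1 - 1/m)^k
    binom_p = _poisson_binomial_tail(k, 1.0 - (1.0 - 1.0 / sizes) ** strata)

    if np.unique(sizes).size == 1 and sizes[0] <= 20:
        m = int(sizes[0])
        observed = np.array([(np.floor(ranks) == c).sum() for c in range(1, m + 1)])
        expected = np.full(m, n / m)
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        rng = np.random.default_rng(seed)
        n_sim = 10000
        sims = rng.multinomial(n, np.full(m, 1.0 / m), size=n_sim)
        sim_chi2 = ((sims - expected) ** 2 / expected).sum(axis=1)
        gof_p = float((1 + (sim_chi2 >= chi2 - 1e-12).sum()) / (1 + n_sim))
        method = "exact-mc-chi2"
    else:
        u = (ranks - 0.5) / sizes
        observed = np.histogram(u, bins=10, range=(0.0, 1.0))[0]
        chi2, gof_p = stats.chisquare(observed)
        chi2, gof_p = float(chi2), float(gof_p)
        method = "decile-chi2"
    return TransferSummary(
        n_pairs=n,
        n_rank1=k,
        binomial_p=binom_p,
        gof_statistic=chi2,
        gof_p=gof_p,
        gof_method=method,
        mean_rank=float(ranks.mean()),
        ranks=[float(r) for r in ranks],
    )


def records_table(records: list[PairRankRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "farm_id": r.farm_id,
                "season": r.season,
                "matched_dissimilarity": r.matched_dissimilarity,
                "rank": r.rank,
                "comparison_set_size": r.comparison_set_size,
                "n_strata": r.n_strata,
            }
            for r in records
        ]
    )
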