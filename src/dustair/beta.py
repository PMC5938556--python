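"""Bray–Curtis dissimilarity, ANOSIM, taxon aggregation and CLR-based
differential abundance.

Between-sample structure is summarised by Bray–Curtis dissimilarities and
tested with the rank-based ANOSIM permutation test.  Differential abundance
follows the Monte-Carlo Dirichlet / centered-log-ratio approach: each
sample's composition is drawn repeatedly from a Dirichlet posterior on its
counts (uniform prior 0.5), CLR-transformed, and the two groups compared per
taxon with a Wilcoxon rank-sum test inside every instance; per-taxon
expected p-values are Benjamini–Hochberg adjusted across taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError
from .io_tables import CountTable, TaxonomyTable

#: Default number of Monte-Carlo Dirichlet instances.
DEFAULT_INSTANCES = 128
#: Default uniform Dirichlet prior added to every count.
DEFAULT_PRIOR = 0.5

AGGREGATION_RANKS = ("phylum", "order", "family", "genus")
UNCLASSIFIED = "unclassified"


# ---------------------------------------------------------------------------
# Bray–Curtis
# ---------------------------------------------------------------------------


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("vectors must have equal length")
    denom = (x + y).sum()
    if denom == 0:
        raise DataError("Bray–Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(counts: CountTable) -> DistanceMatrix:
    """All-pairs Bray–Curtis dissimilarities as a labelled distance matrix."""
    mat = counts.counts.T.astype(float)  # samples x OTUs
    if (mat.sum(axis=1) == 0).any():
        zero = [s for s, t in zip(counts.sample_ids, mat.sum(axis=1)) if t == 0]
        raise DataError(f"all-zero sample column(s): {zero}")
    condensed = pdist(mat, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=counts.sample_ids)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


@dataclass
class AnosimResult:
    """ANOSIM R statistic and permutation p-value for one grouping."""

    grouping: str
    r: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("ANOSIM R outside [-1, 1]")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("permutation p-value outside (0, 1]")


def _anosim_r(ranked: np.ndarray, within: np.ndarray) -> float:
    # ranked: condensed midranks of all M dissimilarities; within: bool mask
    m = ranked.size
    return float((ranked[~within].mean() - ranked[within].mean()) / (m / 2.0))


def anosim(
    dmatrix: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
    grouping: str = "group",
) -> AnosimResult:
    """Analysis of similarities on a labelled dissimilarity matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) over the
    M = n(n-1)/2 midranked dissimilarities; the p-value is the permutation
    tail (1 + #{R_perm >= R_obs}) / (1 + n_permutations) under random
    relabelling with group sizes fixed.
    """
    labels = _align_groups(dmatrix, groups)
    uniq, counts_per = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise DataError("ANOSIM needs >= 2 groups")
    small = [str(g) for g, c in zip(uniq, counts_per) if c < 2]
    if small:
        raise DataError(f"group(s) with fewer than 2 members: {small}")
    condensed = dmatrix.condensed_form()
    ranked = stats.rankdata(condensed)
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    codes = np.searchsorted(uniq, labels)
    within = codes[iu] == codes[ju]
    r_obs = _anosim_r(ranked, within)

    rng = np.random.default_rng(seed)
    hits = 0
    perm = codes.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        if _anosim_r(ranked, perm[iu] == perm[ju]) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    sizes = {str(g): int(c) for g, c in zip(uniq, counts_per)}
    return AnosimResult(grouping, r_obs, p, n_permutations, sizes)


def _align_groups(dmatrix: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, dict):
        missing = [i for i in dmatrix.ids if i not in groups]
        if missing:
            raise DataError(f"samples without a group label: {missing}")
        return np.asarray([str(groups[i]) for i in dmatrix.ids])
    arr = np.asarray([str(g) for g in groups])
    if arr.size != len(dmatrix.ids):
        raise DataError("group vector length does not match distance matrix")
    return arr


# ---------------------------------------------------------------------------
# taxon aggregation
# ---------------------------------------------------------------------------


def collapse_counts(counts: CountTable, taxonomy: TaxonomyTable, rank: str) -> pd.DataFrame:
    """Sum OTU counts into taxa at ``rank`` (taxa x samples, integer).

    OTUs with no classification at that depth are pooled under
    ``"unclassified"``.
    """
    if rank not in AGGREGATION_RANKS:
        raise ConfigurationError(
            f"unknown rank {rank!r}; choose one of {list(AGGREGATION_RANKS)}"
        )
    missing = [o for o in counts.otu_ids if o not in taxonomy.lineages]
    if missing:
        raise DataError(f"OTUs missing from taxonomy: {missing}")
    labels = [taxonomy.rank_label(o, rank) or UNCLASSIFIED for o in counts.otu_ids]
    collapsed = counts.df.groupby(pd.Index(labels, name=rank), sort=True).sum()
    return collapsed


def sample_fractions(counts: CountTable, taxonomy: TaxonomyTable, rank: str) -> pd.DataFrame:
    """Per-sample relative abundance at ``rank`` (columns sum to 1)."""
    collapsed = collapse_counts(counts, taxonomy, rank)
    totals = collapsed.sum(axis=0)
    if (totals == 0).any():
        zero = list(totals.index[totals == 0])
        raise DataError(f"all-zero sample column(s): {zero}")
    return collapsed / totals


def aggregate_by_rank(
    counts: CountTable, taxonomy: TaxonomyTable, rank: str, groups: dict[str, str]
) -> pd.DataFrame:
    """Group-level mean relative abundance at ``rank``, taxa x groups.

    Every sample contributes equally to its group's fraction regardless of
    sequencing depth (unweighted mean of per-sample fractions), so each
    group column sums to 1.
    """
    fractions = sample_fractions(counts, taxonomy, rank)
    missing = [s for s in fractions.columns if s not in groups]
    if missing:
        raise DataError(f"samples without a group label: {missing}")
    labels = pd.Index([groups[s] for s in fractions.columns], name="group")
    return fractions.T.groupby(labels).mean().T


# ---------------------------------------------------------------------------
# CLR Monte-Carlo differential abundance
# ---------------------------------------------------------------------------


def clr_instances(
    column, n_instances: int = DEFAULT_INSTANCES, prior: float = DEFAULT_PRIOR,
    seed: int | None = None,
) -> np.ndarray:
    """Monte-Carlo CLR vectors for one sample column.

    Draws ``p ~ Dirichlet(counts + prior)`` ``n_instances`` times and returns
    the centered log-ratio of each draw as an (n_instances, K) array; every
    row sums to zero.
    """
    col = np.asarray(column, dtype=float)
    if n_instances < 1:
        raise ConfigurationError("n_instances must be >= 1")
    if prior <= 0:
        raise ConfigurationError("prior must be > 0")
    rng = np.random.default_rng(seed)
    gammas = rng.standard_gamma(col + prior, size=(n_instances, col.size))
    logs = np.log(gammas)  # clr is shift-invariant, normalisation cancels
    return logs - logs.mean(axis=1, keepdims=True)


def _welch_p(values: np.ndarray, n_a: int) -> np.ndarray:
    """Vectorised two-sided Welch t-test along the last axis (alternative to
    the rank-sum test inside the Monte-Carlo instances)."""
    a, b = values[..., :n_a], values[..., n_a:]
    na, nb = a.shape[-1], b.shape[-1]
    va = a.var(axis=-1, ddof=1) / na
    vb = b.var(axis=-1, ddof=1) / nb
    denom = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=-1) - b.mean(axis=-1)) / denom
        df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = np.ones_like(t)
    ok = np.isfinite(t) & np.isfinite(df) & (denom > 0)
    p[ok] = np.minimum(2 * stats.t.sf(np.abs(t[ok]), df[ok]), 1.0)
    return p


def _rank_sum_p(values: np.ndarray, n_a: int) -> np.ndarray:
    """Vectorised two-sided Wilcoxon rank-sum p along the last axis.

    ``values[..., :n_a]`` is group A.  Normal approximation with midranks,
    tie correction, and continuity correction — the regime used inside the
    Monte-Carlo instances, where CLR values are continuous and group sizes
    are the study's (>= 10 per group).  Zero-variance slices yield p = 1.
    """
    n = values.shape[-1]
    n_b = n - n_a
    ranks = stats.rankdata(values, axis=-1)
    u = ranks[..., :n_a].sum(axis=-1) - n_a * (n_a + 1) / 2.0
    mu = n_a * n_b / 2.0
    # tie correction over the pooled sample
    sorted_r = np.sort(ranks, axis=-1)
    tie_term = np.zeros(values.shape[:-1])
    # count runs of equal ranks: sum t^3 - t over tie groups
    eq = np.concatenate(
        [np.ones(values.shape[:-1] + (1,), dtype=bool),
         np.diff(sorted_r, axis=-1) != 0], axis=-1,
    )
    # run lengths via cumulative trick
    idx = np.cumsum(eq, axis=-1)
    for k in range(1, n + 1):
        t = (idx == k).sum(axis=-1)
        tie_term += t**3 - t
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(var)
    z = np.zeros_like(sd)
    nonzero = sd > 0
    z[nonzero] = (np.abs(u - mu)[nonzero] - 0.5).clip(min=0) / sd[nonzero]
    p = np.minimum(2 * stats.norm.sf(z), 1.0)
    p[~nonzero] = 1.0
    return p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DifferentialAbundanceResult:
    """Per-taxon CLR effect table for one two-group contrast."""

    rank: str
    group_a: str
    group_b: str
    n_instances: int
    table: pd.DataFrame  # index taxon; median_clr_diff, log2_fold_diff, expected_p, bh_adjusted_p


def differential_abundance(
    counts: CountTable,
    taxonomy: TaxonomyTable,
    rank: str,
    group_a: list[str],
    group_b: list[str],
    n_instances: int = DEFAULT_INSTANCES,
    prior: float = DEFAULT_PRIOR,
    seed: int | None = None,
    label_a: str = "a",
    label_b: str = "b",
    method: str = "wilcoxon",
) -> DifferentialAbundanceResult:
    """Monte-Carlo Dirichlet CLR differential abundance at a taxonomic rank.

    Counts are first aggregated to ``rank``.  For each of ``n_instances``
    Dirichlet draws, every taxon gets a Wilcoxon rank-sum p across the two
    groups of CLR values and the difference of group-median CLRs.  Reported
    per taxon: the median over instances of that group-median difference
    (positive = higher in ``group_a``), its log2-scale equivalent
    (median_clr_diff / ln 2), the expected p (mean over instances), and the
    BH adjustment of the expected p across taxa.  ``method`` selects the
    within-instance test: ``"wilcoxon"`` (rank-sum, the default) or
    ``"welch"`` (unequal-variance t-test); the rank test is robust to the
    heavy-tailed CLR values of low-count taxa, Welch is slightly more
    powerful when the CLR values are near-normal.
    """
    if method not in ("wilcoxon", "welch"):
        raise ConfigurationError(f"unknown method {method!r}")
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise DataError("each group needs >= 2 samples")
    collapsed = collapse_counts(counts, taxonomy, rank)
    missing = [s for s in group_a + group_b if s not in collapsed.columns]
    if missing:
        raise DataError(f"samples absent from counts: {missing}")

    # one Dirichlet draw stream per distinct sample, so a sample appearing in
    # both groups contributes identical CLR values to each
    uniq = list(dict.fromkeys(group_a + group_b))
    pos = {s: i for i, s in enumerate(uniq)}
    taxa = list(collapsed.index)
    mat = collapsed[uniq].to_numpy(dtype=float)  # taxa x unique samples
    rng = np.random.default_rng(seed)
    # (instances, taxa, samples) Dirichlet draws via gamma; clr over taxa axis
    gammas = rng.standard_gamma(mat + prior, size=(n_instances,) + mat.shape)
    logs = np.log(gammas)  # clr is shift-invariant, normalisation cancels
    clr = logs - logs.mean(axis=1, keepdims=True)

    a_idx = [pos[s] for s in group_a]
    b_idx = [pos[s] for s in group_b]
    n_a = len(group_a)
    med_a = np.median(clr[:, :, a_idx], axis=2)
    med_b = np.median(clr[:, :, b_idx], axis=2)
    median_diff = np.median(med_a - med_b, axis=0)  # per taxon
    both = np.concatenate([clr[:, :, a_idx], clr[:, :, b_idx]], axis=2)
    test = _rank_sum_p if method == "wilcoxon" else _welch_p
    p = test(both.transpose(1, 0, 2), n_a)  # (taxa, instances)
    expected_p = p.mean(axis=1)
    table = pd.DataFrame(
        {
            "median_clr_diff": median_diff,
            "log2_fold_diff": median_diff / np.log(2.0),
            "expected_p": expected_p,
            "bh_adjusted_p": bh_adjust(expected_p),
        },
        index=pd.Index(taxa, name=rank),
    )
    return DifferentialAbundanceResult(rank, label_a, label_b, n_instances, table)
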