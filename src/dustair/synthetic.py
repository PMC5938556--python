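"""Synthetic settled-dust study generator.

Emulates the three-environment, two-season study design so that every
downstream stage can be exercised and calibrated without the deposited
sequencing data: pig stables, the paired farmers' homes and suburban homes,
with the study's per-group sample counts (43/43/40/41/50/50), Dirichlet–
multinomial community sampling, environment-ordered absolute abundance,
Firmicutes-dominated stables grading into home compositions, negative
controls carrying planted reagent contaminants plus tag-switching leakage,
technical replicates, a qPCR panel, and a tunable stable->home transfer
fraction tau.

The count model is Dirichlet–multinomial: each environment has a base
composition over K OTUs and a concentration (Dirichlet precision); a
sample's composition is drawn from ``Dirichlet(concentration * base)`` and
its reads from a multinomial at the sample's depth.  A farmer's home with
``tau > 0`` mixes the *realized* composition of that farmer's own stable
into the home's expected composition, so the pairing signal is specific to
the farm, not just to the environment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .io_tables import (
    ENVIRONMENTS,
    SEASONS,
    CountTable,
    SampleMetadata,
    TaxonomyTable,
    write_count_table,
    write_metadata,
    write_taxonomy,
)

ENV_CODES = {"pig_stable": "PS", "farm_home": "FH", "suburban_home": "SU"}
SEASON_CODES = {"winter": "W", "summer": "S"}

#: Study-design sample counts per (environment, season).
DEFAULT_GROUP_SIZES = {
    ("pig_stable", "winter"): 43,
    ("farm_home", "winter"): 43,
    ("pig_stable", "summer"): 40,
    ("farm_home", "summer"): 41,
    ("suburban_home", "winter"): 50,
    ("suburban_home", "summer"): 50,
}

#: Named child-RNG streams split off the master seed, so toggling one
#: generation stage never perturbs another's draws.
_STREAMS = {
    "depth": 1,
    "composition": 2,
    "abundance": 3,
    "replicates": 4,
    "controls": 5,
    "qpcr": 6,
    "days": 7,
}

#: Free parameterization of the environment sources (calibrated once to the
#: study's qualitative structure; see docs/methods.md).
SOURCE_PARAMS = {
    # steep, Firmicutes-dominated animal source
    "pig_stable": dict(perm_key=0, decay=1.35, support=1.0, firmicutes_mass=0.75),
    # broad, even background source; the farm home is an equal mixture of
    # the stable source and this background, giving Firmicutes mass 0.55
    "background": dict(perm_key=1, decay=0.65, support=1.0, firmicutes_mass=0.35),
    # restricted-support urban source: lowest richness
    "suburban_home": dict(perm_key=2, decay=1.25, support=0.30, firmicutes_mass=0.35),
}
FARM_HOME_STABLE_WEIGHT = 0.5
NONTARGET_MASS = 0.008
#: Flattening exponent of the suburban winter composition tilt.
SUBURBAN_WINTER_FLATTEN = 0.25

PROFILE_PARAMS = {
    "pig_stable": dict(concentration=60.0, log10_abundance_mean=8.5,
                       log10_abundance_sd=0.5,
                       season_log10_shift={"winter": -0.25, "summer": 0.25}),
    "farm_home": dict(concentration=250.0, log10_abundance_mean=7.0,
                      log10_abundance_sd=0.5, season_log10_shift={}),
    "suburban_home": dict(concentration=80.0, log10_abundance_mean=4.5,
                          log10_abundance_sd=0.5, season_log10_shift={}),
}

DEFAULT_CONTAMINANT_LEVEL = 500.0


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Named child generator split off the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def default_taxonomy_blocks(n_otus: int) -> dict[str, tuple[int, int]]:
    """Contiguous OTU index ranges per phylum-level block."""
    if n_otus < 12:
        raise ConfigurationError("need at least 12 OTUs for the default blocks")
    n_nontarget = max(2, round(0.033 * n_otus))
    n_contam = max(2, round(0.02 * n_otus))
    n_real = n_otus - n_nontarget - n_contam
    fracs = {"Firmicutes": 0.41, "Proteobacteria": 0.27, "Actinobacteria": 0.17,
             "Bacteroidetes": 0.15}
    sizes = {}
    acc = 0
    names = list(fracs)
    for name in names[:-1]:
        sizes[name] = max(1, round(fracs[name] * n_real))
        acc += sizes[name]
    sizes[names[-1]] = n_real - acc
    blocks = {}
    start = 0
    for name in names:
        blocks[name] = (start, start + sizes[name])
        start += sizes[name]
    blocks["Nontarget"] = (start, start + n_nontarget)
    blocks["Contaminant"] = (start + n_nontarget, n_otus)
    return blocks


@dataclass
class EnvironmentProfile:
    """Generative description of one environment type.

    ``season_shift`` maps a season to a multiplicative tilt vector applied
    to ``base_composition`` before renormalisation (missing season =
    identity).  ``season_log10_shift`` shifts the absolute-abundance mean on
    the log10 scale per season.
    """

    name: str
    base_composition: np.ndarray
    concentration: float
    log10_abundance_mean: float
    log10_abundance_sd: float
    season_shift: dict[str, np.ndarray] = field(default_factory=dict)
    season_log10_shift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        base = np.asarray(self.base_composition, dtype=float)
        if not np.all(np.isfinite(base)):
            raise DataError(f"profile {self.name!r}: non-finite base composition")
        if (base < 0).any():
            raise DataError(f"profile {self.name!r}: negative base composition entries")
        if abs(base.sum() - 1.0) > 1e-9:
            raise DataError(f"profile {self.name!r}: base composition must sum to 1")
        if self.concentration <= 0:
            raise ConfigurationError(f"profile {self.name!r}: concentration must be > 0")
        if self.log10_abundance_sd < 0:
            raise ConfigurationError(f"profile {self.name!r}: log10_abundance_sd < 0")
        self.base_composition = base

    def tilted_composition(self, season: str | None) -> np.ndarray:
        """Base composition after the per-season tilt, renormalised."""
        base = self.base_composition
        tilt = self.season_shift.get(season) if season else None
        if tilt is None:
            return base
        tilt = np.asarray(tilt, dtype=float)
        comp = base * tilt
        total = comp.sum()
        if total <= 0:
            raise DataError(f"profile {self.name!r}: tilt annihilates the composition")
        return comp / total

    def log10_abundance(self, season: str | None) -> float:
        return self.log10_abundance_mean + self.season_log10_shift.get(season, 0.0)


@dataclass
class SyntheticConfig:
    """Full parameterisation of one simulated study."""

    n_otus: int = 300
    taxonomy_blocks: dict[str, tuple[int, int]] | None = None
    profiles: dict[str, EnvironmentProfile] | None = None
    group_sizes: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    transfer_tau: float = 0.0
    depth_log10_mean: float = 4.3
    depth_log10_sd: float = 0.12
    n_controls: int = 10
    contaminant_otus: dict[int, float] | None = None
    tag_switch_rate: float = 0.005
    contaminant_sample_level: float = 2.0
    n_replicate_pairs: int = 15
    replicate_noise: float = 0.002
    qpcr_measurement_sd: float = 0.15
    qpcr_samples_per_group: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.transfer_tau <= 1.0:
            raise ConfigurationError("transfer_tau must lie in [0, 1]")
        if not 0.0 <= self.tag_switch_rate < 1.0:
            raise ConfigurationError("tag_switch_rate must lie in [0, 1)")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ConfigurationError("group sizes must be >= 0")
        if self.n_replicate_pairs < 0 or self.n_controls < 0:
            raise ConfigurationError("counts must be >= 0")
        if self.replicate_noise < 0:
            raise ConfigurationError("replicate_noise must be >= 0")
        if self.contaminant_sample_level < 0:
            raise ConfigurationError("contaminant_sample_level must be >= 0")
        if self.taxonomy_blocks is None:
            self.taxonomy_blocks = default_taxonomy_blocks(self.n_otus)
        _validate_blocks(self.taxonomy_blocks, self.n_otus)
        if self.contaminant_otus is None:
            start, stop = self.taxonomy_blocks["Contaminant"]
            self.contaminant_otus = {i: DEFAULT_CONTAMINANT_LEVEL for i in range(start, stop)}
        for idx in self.contaminant_otus:
            if not 0 <= idx < self.n_otus:
                raise ConfigurationError(f"contaminant OTU index {idx} out of range")


def _validate_blocks(blocks: dict[str, tuple[int, int]], n_otus: int) -> None:
    covered = np.zeros(n_otus, dtype=int)
    for name, (start, stop) in blocks.items():
        if not 0 <= start < stop <= n_otus:
            raise ConfigurationError(
                f"taxonomy block {name!r} range ({start}, {stop}) invalid for K={n_otus}"
            )
        covered[start:stop] += 1
    over = np.flatnonzero(covered > 1)
    if over.size:
        bad = [n for n, (a, b) in blocks.items() if np.any(covered[a:b] > 1)]
        raise ConfigurationError(f"taxonomy blocks overlap: {bad}")
    missing = np.flatnonzero(covered == 0)
    if missing.size:
        raise ConfigurationError(
            f"taxonomy blocks leave {missing.size} OTU indices uncovered "
            f"(first: {int(missing[0])})"
        )


# ---------------------------------------------------------------------------
# environment profiles
# ---------------------------------------------------------------------------


def _source_composition(config: SyntheticConfig, params: dict) -> np.ndarray:
    """One latent source: per-block power-law weights on a fixed permutation."""
    blocks = config.taxonomy_blocks
    k = config.n_otus
    base = np.zeros(k)
    fm = params["firmicutes_mass"]
    real_blocks = [b for b in blocks if b not in ("Nontarget", "Contaminant")]
    other = [b for b in real_blocks if b != "Firmicutes"]
    other_total = 1.0 - fm - NONTARGET_MASS
    other_sizes = np.array([blocks[b][1] - blocks[b][0] for b in other], dtype=float)
    masses = dict(zip(other, other_total * other_sizes / other_sizes.sum()))
    masses["Firmicutes"] = fm
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=20180317, spawn_key=(params["perm_key"],))
    )
    for name in real_blocks:
        start, stop = blocks[name]
        nb = stop - start
        perm = rng.permutation(nb)
        keep = max(1, int(round(params["support"] * nb)))
        w = np.zeros(nb)
        w[perm[:keep]] = (np.arange(1, keep + 1, dtype=float)) ** (-params["decay"])
        base[start:stop] = masses[name] * w / w.sum()
    start, stop = blocks["Nontarget"]
    base[start:stop] = NONTARGET_MASS / (stop - start)
    # the Contaminant block carries no community mass: reagent contamination
    # enters real samples as a small depth-independent additive count instead
    return base / base.sum()


def build_environment_profiles(config: SyntheticConfig) -> dict[str, EnvironmentProfile]:
    """Default profiles: Firmicutes mass and absolute abundance ordered
    stable > farm home > suburban home, seasonal composition shift in
    suburban homes only, seasonal abundance shift in stables only."""
    if config.profiles is not None:
        for env in ENVIRONMENTS:
            if env not in config.profiles:
                raise ConfigurationError(f"profiles missing environment {env!r}")
        return dict(config.profiles)
    stable = _source_composition(config, SOURCE_PARAMS["pig_stable"])
    background = _source_composition(config, SOURCE_PARAMS["background"])
    suburban = _source_composition(config, SOURCE_PARAMS["suburban_home"])
    farm = FARM_HOME_STABLE_WEIGHT * stable + (1 - FARM_HOME_STABLE_WEIGHT) * background
    # suburban winter tilt flattens the composition (greater winter diversity)
    with np.errstate(divide="ignore"):
        winter_tilt = np.where(suburban > 0, suburban ** (-SUBURBAN_WINTER_FLATTEN), 0.0)
    bases = {"pig_stable": stable, "farm_home": farm, "suburban_home": suburban}
    shifts = {"pig_stable": {}, "farm_home": {},
              "suburban_home": {"winter": winter_tilt}}
    return {
        env: EnvironmentProfile(
            name=env,
            base_composition=bases[env],
            season_shift=shifts[env],
            **PROFILE_PARAMS[env],
        )
        for env in ENVIRONMENTS
    }


def firmicutes_block_mass(config: SyntheticConfig, profile: EnvironmentProfile) -> float:
    start, stop = config.taxonomy_blocks["Firmicutes"]
    return float(profile.base_composition[start:stop].sum())


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------


def _dirichlet_masked(alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet draw allowing structural zeros (alpha == 0 stays 0)."""
    p = np.zeros_like(alpha)
    pos = alpha > 0
    p[pos] = rng.dirichlet(alpha[pos])
    return p


def simulate_sample_composition(
    profile: EnvironmentProfile, season: str | None, rng: np.random.Generator
) -> np.ndarray:
    base = profile.tilted_composition(season)
    if not np.all(np.isfinite(base)):
        raise DataError(f"profile {profile.name!r}: non-finite composition")
    return _dirichlet_masked(profile.concentration * base, rng)


def simulate_sample_counts(
    profile: EnvironmentProfile, season: str | None, depth: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Dirichlet–multinomial count vector at the given depth."""
    if depth < 0:
        raise DataError("depth must be >= 0")
    p = simulate_sample_composition(profile, season, rng)
    if depth == 0:
        return np.zeros(p.size, dtype=np.int64)
    return rng.multinomial(depth, p).astype(np.int64)


def apply_transfer(home_expected, stable_realized, tau: float) -> np.ndarray:
    """Mix a fraction tau of the paired stable's realized composition into
    the home's expected composition: (1 - tau) * home + tau * stable."""
    if not 0.0 <= tau <= 1.0:
        raise ConfigurationError("tau must lie in [0, 1]")
    home = np.asarray(home_expected, dtype=float)
    stable = np.asarray(stable_realized, dtype=float)
    for name, v in (("home_expected", home), ("stable_realized", stable)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise DataError(f"{name} must sum to 1 (got {v.sum():.6f})")
    return (1.0 - tau) * home + tau * stable


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

_FIRMICUTES_FAMILIES = [
    ("Clostridia", "Clostridiales", "Lachnospiraceae"),
    ("Clostridia", "Clostridiales", "Ruminococcaceae"),
    ("Clostridia", "Clostridiales", "Peptostreptococcaceae"),
    ("Clostridia", "Clostridiales", "Clostridiaceae_1"),
    ("Bacilli", "Lactobacillales", "Lactobacillaceae"),
    ("Bacilli", "Lactobacillales", "Streptococcaceae"),
    ("Erysipelotrichia", "Erysipelotrichales", "Erysipelotrichaceae"),
    ("Bacilli", "Bacillales", "Bacillaceae"),
]
_BLOCK_FAMILIES = {
    "Proteobacteria": [
        ("Alphaproteobacteria", "Rhizobiales", "Rhizobiaceae"),
        ("Gammaproteobacteria", "Pseudomonadales", "Moraxellaceae"),
        ("Gammaproteobacteria", "Enterobacteriales", "Enterobacteriaceae"),
        ("Betaproteobacteria", "Burkholderiales", "Comamonadaceae"),
    ],
    "Actinobacteria": [
        ("Actinobacteria", "Corynebacteriales", "Corynebacteriaceae"),
        ("Actinobacteria", "Micrococcales", "Micrococcaceae"),
    ],
    "Bacteroidetes": [
        ("Bacteroidia", "Bacteroidales", "Prevotellaceae"),
        ("Flavobacteriia", "Flavobacteriales", "Flavobacteriaceae"),
    ],
}
#: First OTU of these families gets a named genus of interest.
_NAMED_GENERA = {"Ruminococcaceae": "Ruminiclostridium_5",
                 "Lactobacillaceae": "Lactobacillus",
                 "Prevotellaceae": "Prevotella_9"}
_CONF = (100.0, 97.0, 95.0, 92.0, 90.0, 87.0)


def otu_id(i: int) -> str:
    return f"Otu{i + 1:04d}"


def build_taxonomy(config: SyntheticConfig) -> TaxonomyTable:
    blocks = config.taxonomy_blocks
    lineages: dict[str, tuple[str, ...]] = {}
    named_seen: set[str] = set()
    for name, (start, stop) in sorted(blocks.items(), key=lambda kv: kv[1][0]):
        for j, i in enumerate(range(start, stop)):
            if name == "Nontarget":
                cycle = [
                    ("Archaea", "Euryarchaeota"),
                    ("Eukaryota", "Opisthokonta"),
                    ("unknown", "unknown"),
                    ("Bacteria", "Cyanobacteria", "Chloroplast"),
                    ("Bacteria", "Proteobacteria", "Alphaproteobacteria",
                     "Rickettsiales", "Mitochondrion"),
                ]
                lineages[otu_id(i)] = cycle[j % len(cycle)]
            elif name == "Contaminant":
                genus = ["Ralstonia", "Burkholderia", "Cupriavidus"][j % 3]
                lineages[otu_id(i)] = (
                    "Bacteria", "Proteobacteria", "Betaproteobacteria",
                    "Burkholderiales", "Burkholderiaceae", genus,
                )
            else:
                fams = _FIRMICUTES_FAMILIES if name == "Firmicutes" else _BLOCK_FAMILIES[name]
                cls, order, fam = fams[j % len(fams)]
                if fam in _NAMED_GENERA and fam not in named_seen:
                    genus = _NAMED_GENERA[fam]
                    named_seen.add(fam)
                else:
                    genus = f"{fam}_g{j // len(fams) + 1}"
                lineages[otu_id(i)] = ("Bacteria", name, cls, order, fam, genus)
    confidences = {o: _CONF[: len(lin)] for o, lin in lineages.items()}
    return TaxonomyTable(lineages, confidences)


# ---------------------------------------------------------------------------
# negative controls, qPCR
# ---------------------------------------------------------------------------


def simulate_negative_controls(
    real_counts: np.ndarray, config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Control columns (K x n_controls): planted contaminants + leakage.

    Each control carries Poisson reads at the configured level for every
    contaminant OTU, plus tag-switched reads drawn from the pooled
    real-sample composition at ``tag_switch_rate`` of the mean real depth.
    Guarantees that every planted contaminant's maximum over controls
    strictly exceeds its maximum over real samples, so the downstream
    max-in-blanks rule can recover the planted set exactly.
    """
    if config.n_controls < 1:
        raise ConfigurationError("n_controls must be >= 1")
    k, n_real = real_counts.shape
    pooled = real_counts.sum(axis=1).astype(float)
    pooled_p = pooled / pooled.sum() if pooled.sum() > 0 else np.full(k, 1.0 / k)
    mean_depth = real_counts.sum(axis=0).mean() if n_real else 0.0
    controls = np.zeros((k, config.n_controls), dtype=np.int64)
    for c in range(config.n_controls):
        for idx, level in config.contaminant_otus.items():
            controls[idx, c] += rng.poisson(level)
        if config.tag_switch_rate > 0 and mean_depth > 0:
            n_leak = rng.poisson(config.tag_switch_rate * mean_depth)
            if n_leak:
                controls[:, c] += rng.multinomial(n_leak, pooled_p)
    ctrl_max = controls.max(axis=1)
    real_max = real_counts.max(axis=1) if n_real else np.zeros(k, dtype=np.int64)
    for idx in config.contaminant_otus:
        if not ctrl_max[idx] > real_max[idx]:
            raise ConfigurationError(
                f"contaminant OTU index {idx}: control max {ctrl_max[idx]} does not "
                f"exceed real-sample max {real_max[idx]}; raise its control level"
            )
    return controls


def simulate_qpcr_panel(
    config: SyntheticConfig,
    dataset: "SyntheticDataset",
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Measured 16S copies per m² for a per-group subsample of the study.

    True per-sample values live in ``dataset.truth["log10_copies_per_m2"]``;
    the measurement adds lognormal noise: measured = 10^N(log10 true, sd).
    """
    meta = dataset.metadata.df
    truth = dataset.truth["log10_copies_per_m2"]
    rows = []
    for env in ENVIRONMENTS:
        for season in SEASONS:
            pool = sorted(
                meta.index[
                    (~meta["is_control"])
                    & (meta["environment"] == env)
                    & (meta["season"] == season)
                    & (meta["replicate_of"] == "")
                ]
            )
            if not pool:
                continue
            take = min(config.qpcr_samples_per_group, len(pool))
            chosen = rng.choice(pool, size=take, replace=False)
            for sid in sorted(chosen):
                log10_true = truth[sid]
                log10_meas = rng.normal(log10_true, config.qpcr_measurement_sd)
                rows.append({
                    "sample_id": sid,
                    "environment": env,
                    "season": season,
                    "true_copies_per_m2": 10.0 ** log10_true,
                    "measured_copies_per_m2": 10.0 ** log10_meas,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """Everything one simulated study produces, plus the planted truth."""

    counts: CountTable
    metadata: SampleMetadata
    taxonomy: TaxonomyTable
    qpcr: pd.DataFrame
    truth: dict
    config: SyntheticConfig

    def __post_init__(self) -> None:
        if set(self.counts.sample_ids) != set(self.metadata.sample_ids):
            raise DataError("counts and metadata sample sets differ")


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate counts, metadata, taxonomy, controls, replicates, qPCR and truth."""
    profiles = build_environment_profiles(config)
    taxonomy = build_taxonomy(config)
    rng_depth = child_rng(config.seed, "depth")
    rng_comp = child_rng(config.seed, "composition")
    rng_abund = child_rng(config.seed, "abundance")
    rng_rep = child_rng(config.seed, "replicates")
    rng_ctrl = child_rng(config.seed, "controls")
    rng_qpcr = child_rng(config.seed, "qpcr")
    rng_days = child_rng(config.seed, "days")

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    comps: dict[str, np.ndarray] = {}
    counts_cols: dict[str, np.ndarray] = {}
    log10_abund: dict[str, float] = {}
    stable_realized: dict[tuple[str, str], np.ndarray] = {}
    unpaired_homes: list[str] = []

    def draw_depth() -> int:
        return max(1, int(round(10.0 ** rng_depth.normal(
            config.depth_log10_mean, config.depth_log10_sd))))

    def contaminant_carryover() -> np.ndarray:
        # low-level reagent contamination in every real sample, independent
        # of sequencing depth (it enters from the kit, not the dust)
        extra = np.zeros(config.n_otus, dtype=np.int64)
        if config.contaminant_sample_level > 0:
            for idx in config.contaminant_otus:
                extra[idx] = rng_comp.poisson(config.contaminant_sample_level)
        return extra

    def add_sample(sid, env, season, farm_id, p):
        depth = draw_depth()
        counts_cols[sid] = (
            rng_comp.multinomial(depth, p).astype(np.int64) + contaminant_carryover()
        )
        comps[sid] = p
        sample_ids.append(sid)
        days = int(np.clip(round(10.0 ** rng_days.normal(np.log10(14.0), 0.18)), 7, 73))
        meta_rows.append({
            "sample_id": sid, "environment": env, "season": season,
            "farm_id": farm_id, "replicate_of": "", "is_control": False,
            "collection_days": days,
        })
        log10_abund[sid] = rng_abund.normal(
            profiles[env].log10_abundance(season), profiles[env].log10_abundance_sd
        )

    # stables first: their realized compositions seed the paired homes
    for season in SEASONS:
        n = config.group_sizes.get(("pig_stable", season), 0)
        for i in range(n):
            farm = f"F{i + 1:02d}"
            sid = f"PS{SEASON_CODES[season]}{i + 1:02d}"
            p = simulate_sample_composition(profiles["pig_stable"], season, rng_comp)
            stable_realized[(farm, season)] = p
            add_sample(sid, "pig_stable", season, farm, p)
    for season in SEASONS:
        n = config.group_sizes.get(("farm_home", season), 0)
        profile = profiles["farm_home"]
        for i in range(n):
            farm = f"F{i + 1:02d}"
            sid = f"FH{SEASON_CODES[season]}{i + 1:02d}"
            expected = profile.tilted_composition(season)
            partner = stable_realized.get((farm, season))
            if partner is not None:
                expected = apply_transfer(expected, partner, config.transfer_tau)
            elif config.transfer_tau > 0:
                unpaired_homes.append(sid)
            p = _dirichlet_masked(profile.concentration * expected, rng_comp)
            add_sample(sid, "farm_home", season, farm, p)
    for season in SEASONS:
        n = config.group_sizes.get(("suburban_home", season), 0)
        for i in range(n):
            sid = f"SU{SEASON_CODES[season]}{i + 1:02d}"
            p = simulate_sample_composition(profiles["suburban_home"], season, rng_comp)
            add_sample(sid, "suburban_home", season, "", p)

    n_real = len(sample_ids)

    # technical replicates: fresh multinomial resample of a jittered copy of
    # the sample's realized composition (replicate_noise -> 0 = same composition)
    replicate_map: dict[str, str] = {}
    if config.n_replicate_pairs > 0:
        if config.n_replicate_pairs > n_real:
            raise ConfigurationError("more replicate pairs than samples")
        chosen = sorted(rng_rep.choice(sorted(sample_ids), size=config.n_replicate_pairs,
                                       replace=False))
        for orig in chosen:
            rep = orig + "r"
            p = comps[orig]
            if config.replicate_noise > 0:
                p = _dirichlet_masked(p / config.replicate_noise, rng_rep)
            depth = max(1, int(round(10.0 ** rng_rep.normal(
                config.depth_log10_mean, config.depth_log10_sd))))
            extra = np.zeros(config.n_otus, dtype=np.int64)
            if config.contaminant_sample_level > 0:
                for idx in config.contaminant_otus:
                    extra[idx] = rng_rep.poisson(config.contaminant_sample_level)
            counts_cols[rep] = rng_rep.multinomial(depth, p).astype(np.int64) + extra
            comps[rep] = p
            sample_ids.append(rep)
            orig_row = next(r for r in meta_rows if r["sample_id"] == orig)
            meta_rows.append({**orig_row, "sample_id": rep, "replicate_of": orig})
            replicate_map[rep] = orig

    # negative controls
    control_ids: list[str] = []
    if config.n_controls > 0:
        real_mat = np.column_stack([counts_cols[s] for s in sample_ids])
        controls = simulate_negative_controls(real_mat, config, rng_ctrl)
        for c in range(config.n_controls):
            sid = f"NC{c + 1:02d}"
            control_ids.append(sid)
            counts_cols[sid] = controls[:, c]
            meta_rows.append({
                "sample_id": sid, "environment": "", "season": "",
                "farm_id": "", "replicate_of": "", "is_control": True,
                "collection_days": np.nan,
            })

    all_ids = sample_ids + control_ids
    counts = CountTable(pd.DataFrame(
        {sid: counts_cols[sid] for sid in all_ids},
        index=pd.Index([otu_id(i) for i in range(config.n_otus)], name="otu_id"),
        dtype=np.int64,
    ))
    metadata = SampleMetadata(pd.DataFrame(meta_rows))

    truth = {
        "transfer_tau": config.transfer_tau,
        "contaminant_otus": [otu_id(i) for i in sorted(config.contaminant_otus)],
        "nontarget_otus": [otu_id(i) for i in range(*config.taxonomy_blocks["Nontarget"])],
        "firmicutes_block_mass": {
            env: firmicutes_block_mass(config, profiles[env]) for env in ENVIRONMENTS
        },
        "log10_copies_per_m2": log10_abund,
        "replicate_map": replicate_map,
        "unpaired_homes": unpaired_homes,
        "true_compositions": pd.DataFrame(
            {sid: comps[sid] for sid in sample_ids},
            index=[otu_id(i) for i in range(config.n_otus)],
        ),
    }
    dataset = SyntheticDataset(counts, metadata, taxonomy, pd.DataFrame(), truth, config)
    dataset.qpcr = simulate_qpcr_panel(config, dataset, rng_qpcr)
    return dataset


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write counts/metadata/taxonomy TSVs, the qPCR panel, the truth record
    and a config echo into ``outdir``."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_count_table(dataset.counts, out / "counts.tsv")
    write_metadata(dataset.metadata, out / "metadata.tsv")
    write_taxonomy(dataset.taxonomy, out / "taxonomy.tsv")
    with open(out / "qpcr.tsv", "w", encoding="utf-8") as fh:
        fh.write("# dustair/1 qpcr\n")
        dataset.qpcr.to_csv(fh, sep="\t", index=False)
    truth = {k: v for k, v in dataset.truth.items() if k != "true_compositions"}
    truth["log10_copies_per_m2"] = {
        k: float(v) for k, v in truth["log10_copies_per_m2"].items()
    }
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out / "true_compositions.tsv", "w", encoding="utf-8") as fh:
        fh.write("# dustair/1 true-compositions\n")
        dataset.truth["true_compositions"].to_csv(fh, sep="\t", index_label="otu_id")
    cfg = {
        k: v for k, v in vars(dataset.config).items()
        if k not in ("profiles", "taxonomy_blocks", "contaminant_otus", "group_sizes")
    }
    cfg["group_sizes"] = {f"{e}/{s}": n for (e, s), n in dataset.config.group_sizes.items()}
    cfg["taxonomy_blocks"] = {k: list(v) for k, v in dataset.config.taxonomy_blocks.items()}
    cfg["contaminant_otus"] = {str(k): v for k, v in dataset.config.contaminant_otus.items()}
    with open(out / "config.json", "w", encoding="utf-8") as fh:
        json.dump(cfg, fh, indent=1, sort_keys=True)
        fh.write("\n")
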