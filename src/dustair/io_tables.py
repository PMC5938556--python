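"""Tab-separated table dialects shared by all pipeline stages.

Three files describe a settled-dust amplicon study:

* ``counts.tsv`` — integer OTU-by-sample read matrix (OTU rows, sample
  columns; mothur "shared" files are the transpose, see ``transposed=``).
* ``metadata.tsv`` — one row per sample: environment, season, farm pairing,
  replicate links, control flag, collection time.
* ``taxonomy.tsv`` — mothur ``classify.otu``-style consensus lineages,
  semicolon-delimited with optional per-rank ``(NN)`` confidence suffixes.

All writers emit a leading ``#`` comment line carrying the schema version;
readers skip any number of leading comment lines.  Absent values are encoded
as the empty string.  Files are UTF-8, tab-delimited, unquoted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ParseError

SCHEMA_VERSION = "dustair/1"

ENVIRONMENTS = ("pig_stable", "farm_home", "suburban_home")
SEASONS = ("winter", "summer")
#: Taxonomic ranks stored for each OTU, outermost first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

_METADATA_COLUMNS = (
    "sample_id",
    "environment",
    "season",
    "farm_id",
    "replicate_of",
    "is_control",
    "collection_days",
)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Non-negative integer read counts, OTUs x samples.

    Wraps a :class:`pandas.DataFrame` whose index holds OTU identifiers and
    whose columns hold sample identifiers.  Construction validates the
    invariants (unique ids, integer dtype, counts >= 0).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate OTU ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids: {dups}")
        if df.size and not all(np.issubdtype(t, np.integer) for t in df.dtypes):
            raise DataError("count matrix must be integer-typed")
        if df.size and (df.to_numpy() < 0).any():
            raise DataError("negative counts are not allowed")
        self.df = df.astype(np.int64) if df.size else df

    @property
    def otu_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def n_otus(self) -> int:
        return self.df.shape[0]

    @property
    def n_samples(self) -> int:
        return self.df.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.df.sum(axis=0)

    def otu_totals(self) -> pd.Series:
        return self.df.sum(axis=1)

    def drop_otus(self, otu_ids) -> "CountTable":
        return CountTable(self.df.drop(index=list(otu_ids)))

    def drop_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.df.drop(columns=list(sample_ids)))

    def select_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.df[list(sample_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self.df.equals(other.df)


@dataclass
class SampleMetadata:
    """Per-sample annotations keyed by ``sample_id``.

    Columns: environment, season, farm_id, replicate_of, is_control,
    collection_days.  Controls are exempt from the environment/pairing
    requirements; for real samples ``farm_id`` must be present iff the
    environment is ``pig_stable`` or ``farm_home``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in _METADATA_COLUMNS if c != "sample_id" and c not in df.columns]
        if missing:
            raise DataError(f"metadata missing required columns: {missing}")
        if df.index.name != "sample_id":
            if "sample_id" not in df.columns:
                raise DataError("metadata missing required columns: ['sample_id']")
            df = df.set_index("sample_id")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids in metadata: {dups}")
        for col in ("environment", "season", "farm_id", "replicate_of"):
            df[col] = df[col].fillna("").astype(str)
        df["is_control"] = df["is_control"].map(_parse_bool)
        df["collection_days"] = pd.to_numeric(df["collection_days"], errors="coerce")

        real = df[~df["is_control"]]
        bad_env = sorted(set(real["environment"]) - set(ENVIRONMENTS))
        if bad_env:
            raise DataError(
                f"unknown environment value(s) {bad_env}; allowed: {list(ENVIRONMENTS)}"
            )
        bad_season = sorted(set(real["season"]) - set(SEASONS))
        if bad_season:
            raise DataError(f"unknown season value(s) {bad_season}; allowed: {list(SEASONS)}")
        farm_envs = real["environment"].isin(["pig_stable", "farm_home"])
        no_farm = real.index[farm_envs & (real["farm_id"] == "")].tolist()
        if no_farm:
            raise DataError(f"farm samples missing farm_id: {no_farm}")
        stray_farm = real.index[~farm_envs & (real["farm_id"] != "")].tolist()
        if stray_farm:
            raise DataError(f"non-farm samples carrying farm_id: {stray_farm}")
        for sid, ref in df["replicate_of"].items():
            if ref and ref not in df.index:
                raise DataError(
                    f"replicate_of of sample {sid!r} references absent sample {ref!r}"
                )
        self.df = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def controls(self) -> list[str]:
        return list(self.df.index[self.df["is_control"]])

    def real_samples(self) -> list[str]:
        return list(self.df.index[~self.df["is_control"]])

    def environment_of(self, sample_id: str) -> str:
        return self.df.at[sample_id, "environment"]

    def season_of(self, sample_id: str) -> str:
        return self.df.at[sample_id, "season"]

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.df.loc[list(sample_ids)].copy())

    def samples_where(self, environment=None, season=None, include_replicates=True):
        df = self.df[~self.df["is_control"]]
        if environment is not None:
            df = df[df["environment"] == environment]
        if season is not None:
            df = df[df["season"] == season]
        if not include_replicates:
            df = df[df["replicate_of"] == ""]
        return list(df.index)


@dataclass
class TaxonomyTable:
    """Consensus lineage per OTU, domain -> genus, with optional confidences."""

    lineages: dict[str, tuple[str, ...]]
    confidences: dict[str, tuple[float | None, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for otu, lin in self.lineages.items():
            if len(lin) > len(RANKS):
                raise DataError(f"lineage of {otu!r} has more than {len(RANKS)} ranks")
            conf = self.confidences.get(otu)
            if conf is not None and len(conf) != len(lin):
                raise DataError(f"confidence/lineage length mismatch for {otu!r}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.lineages)

    def rank_label(self, otu_id: str, rank: str) -> str | None:
        """Label of ``otu_id`` at ``rank`` (None when unclassified that deep)."""
        i = RANKS.index(rank)
        lin = self.lineages[otu_id]
        return lin[i] if i < len(lin) else None

    def subset(self, otu_ids) -> "TaxonomyTable":
        ids = list(otu_ids)
        return TaxonomyTable(
            {o: self.lineages[o] for o in ids},
            {o: self.confidences[o] for o in ids if o in self.confidences},
        )


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", ""):
        return False
    raise DataError(f"cannot parse boolean value {v!r}")


# ---------------------------------------------------------------------------
# count table I/O
# ---------------------------------------------------------------------------


def read_count_table(path, transposed: bool = False) -> CountTable:
    """Read a counts TSV (OTU rows x sample columns).

    ``transposed=True`` accepts the mothur "shared"-style orientation
    (sample rows x OTU columns).  Cells must be non-negative integers; a
    fractional or non-numeric cell raises :class:`ParseError` naming it.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, index_col=0)
    df.index = df.index.astype(str)
    parsed = pd.DataFrame(index=df.index, columns=df.columns, dtype=np.int64)
    for col in df.columns:
        for row, raw in df[col].items():
            try:
                value = int(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-integer count {raw!r} at OTU {row!r}, sample {col!r} in {path}"
                ) from None
            parsed.at[row, col] = value
    if transposed:
        parsed = parsed.T
    parsed.index.name = "otu_id"
    return CountTable(parsed.astype(np.int64))


def write_count_table(table: CountTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {SCHEMA_VERSION} counts\n")
        df = table.df.copy()
        df.index.name = "otu_id"
        df.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# metadata I/O
# ---------------------------------------------------------------------------


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"metadata file {path} missing required columns: {missing}")
    df["collection_days"] = df["collection_days"].replace("", np.nan)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    df = metadata.df.copy()
    df = df.reset_index()
    df["is_control"] = df["is_control"].map({True: "true", False: "false"})
    days = df["collection_days"]
    df["collection_days"] = [
        "" if pd.isna(d) else (str(int(d)) if float(d).is_integer() else str(d)) for d in days
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {SCHEMA_VERSION} metadata\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# taxonomy I/O
# ---------------------------------------------------------------------------

_RANK_RE = re.compile(r"^(?P<label>.*?)(?:\((?P<conf>\d+(?:\.\d+)?)\))?$")


def parse_lineage(s: str) -> tuple[tuple[str, ...], tuple[float | None, ...]]:
    """Parse ``"Bacteria(100);Firmicutes(97);"`` into labels and confidences.

    Trailing semicolons are ignored; a rank without a ``(NN)`` suffix gets a
    ``None`` confidence.  Malformed confidences raise :class:`ParseError`.
    """
    labels: list[str] = []
    confs: list[float | None] = []
    for part in s.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        m = _RANK_RE.match(part)
        label = m.group("label").strip()
        conf = m.group("conf")
        if "(" in label or ")" in label:
            raise ParseError(f"malformed confidence in lineage element {part!r}")
        if conf is not None:
            c = float(conf)
            if not 0.0 <= c <= 100.0:
                raise ParseError(f"confidence {c} outside [0, 100] in {part!r}")
            confs.append(c)
        else:
            confs.append(None)
        labels.append(label)
    return tuple(labels), tuple(confs)


def format_lineage(labels, confidences=None) -> str:
    parts = []
    for i, label in enumerate(labels):
        conf = None if confidences is None else confidences[i]
        parts.append(label if conf is None else f"{label}({conf:g})")
    return ";".join(parts) + ";"


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if "otu_id" not in df.columns or "taxonomy" not in df.columns:
        raise DataError(f"taxonomy file {path} must have 'otu_id' and 'taxonomy' columns")
    if df["otu_id"].duplicated().any():
        dups = df["otu_id"][df["otu_id"].duplicated()].unique().tolist()
        raise DataError(f"duplicate OTU ids in taxonomy: {dups}")
    lineages: dict[str, tuple[str, ...]] = {}
    confidences: dict[str, tuple[float | None, ...]] = {}
    for _, row in df.iterrows():
        labels, confs = parse_lineage(row["taxonomy"])
        lineages[row["otu_id"]] = labels
        confidences[row["otu_id"]] = confs
    return TaxonomyTable(lineages, confidences)


def write_taxonomy(taxonomy: TaxonomyTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {SCHEMA_VERSION} taxonomy\n")
        fh.write("otu_id\ttaxonomy\n")
        for otu in taxonomy.otu_ids:
            line = format_lineage(taxonomy.lineages[otu], taxonomy.confidences.get(otu))
            fh.write(f"{otu}\t{line}\n")


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def validate_dataset(
    counts: CountTable, metadata: SampleMetadata, taxonomy: TaxonomyTable
) -> list[str]:
    """Cross-check the three tables; returns a list of violations (empty = ok)."""
    report: list[str] = []
    count_samples = set(counts.sample_ids)
    meta_samples = set(metadata.sample_ids)
    for sid in sorted(count_samples - meta_samples):
        report.append(f"sample {sid!r} present in counts but absent from metadata")
    for sid in sorted(meta_samples - count_samples):
        report.append(f"sample {sid!r} present in metadata but absent from counts")
    tax_otus = set(taxonomy.otu_ids)
    missing_tax = sorted(set(counts.otu_ids) - tax_otus)
    for otu in missing_tax:
        report.append(f"OTU {otu!r} present in counts but absent from taxonomy")

    df = metadata.df[~metadata.df["is_control"]]
    stables = df[df["environment"] == "pig_stable"]
    homes = df[df["environment"] == "farm_home"]
    for season in SEASONS:
        stable_farms = set(stables[stables["season"] == season]["farm_id"])
        home_farms = set(homes[homes["season"] == season]["farm_id"])
        for farm in sorted(stable_farms - home_farms):
            report.append(f"unpaired farm: stable of farm {farm!r} has no {season} farm_home")
        for farm in sorted(home_farms - stable_farms):
            report.append(f"unpaired farm: home of farm {farm!r} has no {season} pig_stable")
    return report
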