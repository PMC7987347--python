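"""Core data model for dyad-structured gut-microbiome surveys.

The comparative design pairs each domesticated species with its wild
progenitor or closest sampled wild relative ("dyad"); samples carry a
domestication status, a domestication category (laboratory, companion,
agricultural), diet/physiology covariates, and — for the longitudinal
experiments — an individual identity, timepoint, and treatment group.

Count tables are stored samples-as-rows throughout. Taxonomy strings use
the 7-rank ``k__;p__;c__;o__;f__;g__;s__`` dialect; empty ranks are allowed.
Missing metadata is encoded as the literal string ``"NA"``: samples with NA
in a factor are excluded from tests on that factor only, never globally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("wilddom")

NA = "NA"

RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

STATUS_LEVELS = frozenset({"wild", "domesticated", NA})
CATEGORY_LEVELS = frozenset({"laboratory", "companion", "agricultural", "primate", "none", NA})

#: Columns a metadata table must provide (others are preserved untouched).
REQUIRED_METADATA_COLUMNS = ("sample_id", "host_species", "dyad_id", "status")

#: Optional columns filled with NA when absent.
OPTIONAL_METADATA_COLUMNS = (
    "category",
    "diet_type",
    "gut_physiology",
    "locale",
    "individual_id",
    "timepoint",
    "treatment_group",
    "microbial_density",
    "population_label",
)


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


def parse_taxonomy(lineage: str) -> dict[str, str]:
    """Split a semicolon-delimited 7-rank lineage string into rank fields.

    Rank prefixes (``g__`` etc.) are stripped; empty or missing ranks map
    to ``""``. Whitespace around separators is tolerated.
    """
    fields = dict.fromkeys(RANK_NAMES, "")
    for chunk in str(lineage).split(";"):
        chunk = chunk.strip()
        for prefix, rank in zip(RANK_PREFIXES, RANK_NAMES):
            if chunk.startswith(prefix):
                fields[rank] = chunk[len(prefix):].strip()
                break
    return fields


@dataclass
class CountTable:
    """Sample x taxon matrix of nonnegative integer read counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Samples as rows, taxa as columns, nonnegative integers.
    taxonomy : pandas.Series, optional
        Per-taxon 7-rank lineage string, indexed by taxon id.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be nonnegative")
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate sample ids in count table")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate taxon ids in count table")
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(self.counts.columns).fillna("")

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def depths(self) -> pd.Series:
        """Total assigned reads per sample."""
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.depths()
        if (totals == 0).any():
            raise ValidationError("zero-sum sample; drop it before normalising")
        return self.counts.div(totals, axis=0)

    def taxonomy_frame(self) -> pd.DataFrame:
        """Taxonomy parsed into one column per rank (empty strings when absent)."""
        if self.taxonomy is None:
            raise ValidationError("count table has no taxonomy annotations")
        rows = {tid: parse_taxonomy(lin) for tid, lin in self.taxonomy.items()}
        return pd.DataFrame.from_dict(rows, orient="index").reindex(self.counts.columns)

    # -- subsetting ------------------------------------------------------
    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        missing = set(sample_ids) - set(self.counts.index)
        if missing:
            raise ValidationError(f"unknown sample ids: {sorted(missing)}")
        return CountTable(self.counts.loc[list(sample_ids)], self.taxonomy)

    def subset_taxa(self, taxon_ids: Sequence[str]) -> "CountTable":
        missing = set(taxon_ids) - set(self.counts.columns)
        if missing:
            raise ValidationError(f"unknown taxon ids: {sorted(missing)}")
        tax = self.taxonomy.loc[list(taxon_ids)] if self.taxonomy is not None else None
        return CountTable(self.counts[list(taxon_ids)], tax)

    def drop_empty_samples(self) -> "CountTable":
        keep = self.depths() > 0
        dropped = [s for s, k in keep.items() if not k]
        if dropped:
            logger.warning("dropping %d zero-sum samples: %s", len(dropped), dropped)
        return CountTable(self.counts.loc[keep], self.taxonomy)

    @staticmethod
    def merge(tables: Iterable["CountTable"]) -> "CountTable":
        """Outer-join tables on their taxon universe, filling absent taxa with 0."""
        tables = list(tables)
        counts = pd.concat([t.counts for t in tables], axis=0).fillna(0).astype(np.int64)
        if counts.index.duplicated().any():
            raise ValidationError("merged tables share sample ids")
        taxonomies = [t.taxonomy for t in tables if t.taxonomy is not None]
        taxonomy = None
        if taxonomies:
            taxonomy = pd.concat(taxonomies)
            taxonomy = taxonomy[~taxonomy.index.duplicated()]
        return CountTable(counts, taxonomy)


@dataclass
class ValidatedDataset:
    """Reconciled bundle of counts, metadata, and optional side tables.

    Produced by :func:`validate_dataset`; all downstream pipeline stages
    take this type so that sample-id consistency is enforced at one choke
    point. Validation is idempotent.
    """

    counts: CountTable
    metadata: pd.DataFrame
    dyads: pd.DataFrame | None = None
    tree: TreeNode | None = None
    pathogens: list[str] | None = None
    host_divergence: object | None = None  # species-level divergence-time DistanceMatrix
    warnings: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.sample_ids

    def require_tree(self) -> TreeNode:
        if self.tree is None:
            raise ValidationError("a phylogeny is required for UniFrac but none was loaded")
        return self.tree

    def samples_where(self, **conditions: object) -> pd.DataFrame:
        """Metadata rows matching equality conditions, NA rows excluded."""
        frame = self.metadata
        for column, value in conditions.items():
            frame = frame[(frame[column] != NA) & (frame[column] == value)]
        return frame


@dataclass(frozen=True)
class RunConfig:
    """Tunable knobs shared across pipeline stages.

    Defaults follow the study conditions: rarefaction depth 17,500 reads for
    the cross-species survey (27,000 / 15,500 / 7,500 for the wild-mouse,
    colonization, and canid experiments), 25,000 bootstrap resamples for
    dissimilarity contrasts, 999 label permutations elsewhere, 2-D NMDS with
    20 restarts, Shannon index in bits.
    """

    rarefaction_depth: int = 17_500
    n_permutations: int = 999
    n_bootstrap: int = 25_000
    random_seed: int = 0
    nmds_dimensions: int = 2
    nmds_starts: int = 20
    nmds_max_iter: int = 300
    nmds_tol: float = 1e-7
    distance_metric: str = "braycurtis"
    shannon_log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.rarefaction_depth <= 0:
            raise ValidationError("rarefaction depth must be positive")
        if self.n_permutations < 99:
            raise ValidationError("use at least 99 permutations")
        if self.nmds_dimensions < 1:
            raise ValidationError("nmds_dimensions must be >= 1")

    def with_depth(self, depth: int) -> "RunConfig":
        return replace(self, rarefaction_depth=depth)


def validate_metadata(frame: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and categorical vocabularies; normalise NAs."""
    frame = frame.copy()
    for col in REQUIRED_METADATA_COLUMNS:
        if col not in frame.columns:
            raise ValidationError(f"metadata is missing required column {col!r}")
    for col in OPTIONAL_METADATA_COLUMNS:
        if col not in frame.columns:
            frame[col] = NA
    frame = frame.fillna(NA)
    frame["sample_id"] = frame["sample_id"].astype(str)
    if frame["sample_id"].duplicated().any():
        dupes = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicated sample ids in metadata: {dupes}")
    bad_status = set(frame["status"].unique()) - STATUS_LEVELS
    if bad_status:
        raise ValidationError(f"status values outside wild/domesticated/NA: {sorted(bad_status)}")
    bad_cat = set(frame["category"].astype(str).unique()) - CATEGORY_LEVELS
    if bad_cat:
        raise ValidationError(f"unknown domestication categories: {sorted(bad_cat)}")
    return frame.set_index("sample_id", drop=False)


def validate_dyads(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    if "dyad_id" not in frame.columns:
        raise ValidationError("dyad table is missing column 'dyad_id'")
    for col in ("time_since_domestication", "time_since_divergence"):
        if col in frame.columns:
            values = pd.to_numeric(frame[col], errors="coerce")
            if (values.dropna() <= 0).any():
                raise ValidationError(f"{col} must be positive")
            frame[col] = values
    both = frame.dropna(subset=["time_since_domestication", "time_since_divergence"])
    if (both["time_since_divergence"] < both["time_since_domestication"]).any():
        raise ValidationError("divergence time must be >= domestication time")
    return frame.set_index("dyad_id", drop=False)


def validate_dataset(
    counts: CountTable,
    metadata: pd.DataFrame,
    dyads: pd.DataFrame | None = None,
    tree: TreeNode | None = None,
    pathogens: list[str] | None = None,
    host_divergence=None,
) -> ValidatedDataset:
    """Reconcile sample ids across inputs and check design invariants.

    Samples present in only one of counts/metadata are dropped with a
    warning; each dyad must map to exactly two host species; tree tips not
    present in the table are pruned (extra table taxa are an error only when
    UniFrac is actually requested).
    """
    if isinstance(counts, ValidatedDataset):  # idempotence
        return counts
    warnings: list[str] = []
    metadata = validate_metadata(metadata)
    counts = counts.drop_empty_samples()

    shared = [s for s in counts.sample_ids if s in metadata.index]
    only_counts = sorted(set(counts.sample_ids) - set(shared))
    only_meta = sorted(set(metadata.index) - set(shared))
    if only_counts:
        warnings.append(f"samples only in counts dropped: {only_counts}")
    if only_meta:
        warnings.append(f"samples only in metadata dropped: {only_meta}")
    if not shared:
        raise ValidationError("no samples shared between counts and metadata")
    counts = counts.subset_samples(shared)
    metadata = metadata.loc[shared]

    for dyad, sub in metadata[metadata["dyad_id"] != NA].groupby("dyad_id"):
        n_species = sub["host_species"].nunique()
        if n_species > 2:
            raise ValidationError(f"dyad {dyad!r} maps to {n_species} host species")
        logger.info("dyad %s: %d samples, %d species", dyad, len(sub), n_species)

    if dyads is not None:
        dyads = validate_dyads(dyads)
        missing = set(metadata.loc[metadata["dyad_id"] != NA, "dyad_id"]) - set(dyads.index)
        if missing:
            warnings.append(f"dyads without divergence-time info: {sorted(missing)}")

    if tree is not None:
        tips = {t.name for t in tree.tips()}
        extra = tips - set(counts.taxon_ids)
        if extra:
            tree = tree.shear(set(counts.taxon_ids) & tips)
            warnings.append(f"pruned {len(extra)} tree tips absent from the table")

    if pathogens is not None:
        pathogens = [p.strip().lower() for p in pathogens if p.strip()]
        if not pathogens:
            raise ValidationError("pathogen list is empty")

    if host_divergence is not None:
        missing_species = set(metadata["host_species"]) - set(host_divergence.ids)
        if missing_species:
            warnings.append(
                f"species without divergence-time entries: {sorted(missing_species)}"
            )

    for message in warnings:
        logger.warning("%s", message)
    return ValidatedDataset(counts, metadata, dyads, tree, pathogens, host_divergence, warnings)
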