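"""Rarefaction, alpha-diversity, and community dissimilarity metrics.

Alpha-diversity (Shannon index, observed richness) is computed on rarefied
tables; beta-diversity (Bray-Curtis, weighted/unweighted UniFrac) on
unrarefied tables. Rarefaction is a single seeded draw without replacement
per sample. Potential-pathogen metrics subset the table to taxa whose genus
(or genus+species) matches a curated pathogen name list, then apply the same
diversity machinery to the subset.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

from .datasets import CountTable, ValidationError

logger = logging.getLogger("wilddom")


# ---------------------------------------------------------------------------
# rarefaction and alpha diversity
# ---------------------------------------------------------------------------

def rarefy(table: CountTable, depth: int, seed: int | np.random.Generator = 0) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (and logged);
    a sample whose total equals ``depth`` is returned unchanged. The draw is
    a multivariate hypergeometric per sample, so retained totals are exact.
    """
    if depth <= 0:
        raise ValidationError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.depths()
    keep = totals[totals >= depth].index.tolist()
    dropped = sorted(set(table.sample_ids) - set(keep))
    if dropped:
        logger.warning("rarefy: dropping %d samples below depth %d: %s", len(dropped), depth, dropped)
    if not keep:
        raise ValidationError(f"all samples are below rarefaction depth {depth}")
    rows = []
    for sid in keep:
        counts = table.counts.loc[sid].to_numpy()
        if counts.sum() == depth:
            rows.append(counts)
        else:
            rows.append(rng.multivariate_hypergeometric(counts, depth))
    rarefied = pd.DataFrame(np.asarray(rows), index=keep, columns=table.counts.columns)
    return CountTable(rarefied, table.taxonomy)


def shannon(counts: np.ndarray, log_base: float = 2.0) -> float:
    """Shannon diversity −Σ pᵢ log(pᵢ) over nonzero proportions (base 2 by default)."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValidationError("negative counts")
    total = counts.sum()
    if total <= 0:
        raise ValidationError("zero-sum count vector")
    p = counts[counts > 0] / total
    return float(-(p * (np.log(p) / np.log(log_base))).sum())


def richness(counts: np.ndarray) -> int:
    """Observed richness: number of taxa with at least one read."""
    counts = np.asarray(counts)
    n = int((counts > 0).sum())
    if n == 0:
        logger.warning("richness of an all-zero vector is 0")
    return n


def alpha_table(table: CountTable, log_base: float = 2.0) -> pd.DataFrame:
    """Per-sample Shannon index and richness, typically on a rarefied table."""
    records = {
        sid: {"shannon": shannon(row.to_numpy(), log_base), "richness": richness(row.to_numpy())}
        for sid, row in table.counts.iterrows()
    }
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table: CountTable, normalize: bool = True) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: 1 − 2 Σ min(Aᵢ,Bᵢ) / (ΣA + ΣB).

    By default samples are converted to relative abundances first, so the
    metric reflects composition rather than library size (sequencing depths
    here vary by close to an order of magnitude, and on raw counts the
    leading ordination axis simply tracks depth). ``normalize=False`` gives
    the raw-count form.
    """
    if len(table.sample_ids) < 2:
        raise ValidationError("need at least two samples for a distance matrix")
    if (table.depths() == 0).any():
        raise ValidationError("zero-sum sample; drop it before computing Bray-Curtis")
    data = table.relative_abundance().to_numpy() if normalize else table.counts.to_numpy()
    return beta_diversity("braycurtis", data, ids=table.sample_ids)


def _check_tree_coverage(table: CountTable, tree: TreeNode) -> None:
    tips = {t.name for t in tree.tips()}
    used = table.counts.columns[(table.counts.to_numpy() > 0).any(axis=0)]
    missing = sorted(set(used) - tips)
    if missing:
        raise ValidationError(f"taxa absent from the tree: {missing}")


def unweighted_unifrac(table: CountTable, tree: TreeNode) -> DistanceMatrix:
    """Presence/absence UniFrac: unshared branch length over union branch length."""
    _check_tree_coverage(table, tree)
    return beta_diversity(
        "unweighted_unifrac",
        table.counts.to_numpy(),
        ids=table.sample_ids,
        taxa=table.taxon_ids,
        tree=tree,
    )


def weighted_unifrac(table: CountTable, tree: TreeNode, normalized: bool = True) -> DistanceMatrix:
    """Abundance-weighted UniFrac, normalized (bounded in [0,1]) by default."""
    _check_tree_coverage(table, tree)
    return beta_diversity(
        "weighted_unifrac",
        table.counts.to_numpy(),
        ids=table.sample_ids,
        taxa=table.taxon_ids,
        tree=tree,
        normalized=normalized,
    )


def distance_matrix(
    table: CountTable,
    metric: str = "braycurtis",
    tree: TreeNode | None = None,
) -> DistanceMatrix:
    """Dispatch on the configured metric name."""
    if metric == "braycurtis":
        return bray_curtis(table)
    if metric == "unweighted_unifrac":
        if tree is None:
            raise ValidationError("UniFrac requested without a tree")
        return unweighted_unifrac(table, tree)
    if metric == "weighted_unifrac":
        if tree is None:
            raise ValidationError("UniFrac requested without a tree")
        return weighted_unifrac(table, tree)
    raise ValidationError(f"unknown distance metric {metric!r}")


# ---------------------------------------------------------------------------
# potential-pathogen subset
# ---------------------------------------------------------------------------

def pathogen_subset(table: CountTable, pathogens: list[str]) -> CountTable:
    """Retain taxa whose genus, or 'genus species', matches a list entry.

    Matching is exact and case-insensitive on the parsed rank fields; a
    single-word entry matches at the genus level, a two-word entry only taxa
    resolved to that species.
    """
    ranks = table.taxonomy_frame()
    genus = ranks["genus"].str.strip().str.lower()
    species = ranks["species"].str.strip().str.lower()
    genus_species = (genus + " " + species).str.strip()
    entries = {e.strip().lower() for e in pathogens if e.strip()}
    single = {e for e in entries if " " not in e}
    double = entries - single
    hit = genus.isin(single) & (genus != "") | genus_species.isin(double)
    kept = list(table.counts.columns[hit.to_numpy()])
    if not kept:
        logger.warning("pathogen subset is empty; downstream pathogen metrics will be 0")
    return table.subset_taxa(kept)


def pathogen_metrics(
    table: CountTable,
    pathogens: list[str],
    rarefied: CountTable | None = None,
) -> pd.DataFrame:
    """Per-sample pathogen richness and relative abundance.

    Richness is counted on the rarefied subset when a rarefied table is
    given (diversity of the subset "with the same methods"); relative
    abundance is pathogen reads over total reads of the full table.
    """
    subset = pathogen_subset(table, pathogens)
    totals = table.depths()
    path_reads = subset.counts.sum(axis=1) if subset.shape[1] else pd.Series(0, index=table.sample_ids)
    abundance = (path_reads / totals).reindex(table.sample_ids).fillna(0.0)

    richness_source = pathogen_subset(rarefied, pathogens) if rarefied is not None else subset
    if richness_source.shape[1]:
        path_rich = (richness_source.counts > 0).sum(axis=1)
    else:
        path_rich = pd.Series(0, index=richness_source.sample_ids)
    out = pd.DataFrame({"pathogen_abundance": abundance})
    out["pathogen_richness"] = path_rich.reindex(out.index)
    out.index.name = "sample_id"
    return out
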