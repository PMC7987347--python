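"""Staged comparative analyses over a validated dataset.

Each stage consumes the shared containers (count table, metadata, distance
matrix, oriented ordination) and returns tidy record frames plus
:class:`~wilddom.stats.TestResult` objects, so drivers can run stages
independently or chain them via :func:`run_cross_species` /
:func:`run_experiment`.

Conventions. Animal-only stages exclude ``category == "primate"`` samples;
human and chimpanzee cohorts enter only the joint-ordination stages.
Displacements ("ordination shifts") are signed axis-1 coordinates minus a
reference mean (dyad mean, all-primate mean, or baseline control mean),
measured after the orientation rule fixed axis 1 to point from wild toward
domesticated; a positive displacement is therefore a shift toward the
domesticated side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from . import stats
from .datasets import NA, CountTable, RunConfig, ValidatedDataset, ValidationError
from .diversity import alpha_table, distance_matrix, pathogen_metrics, rarefy
from .ordination import OrdinationResult, joint_ordination, nmds_from_config, orient
from .simulate import INDUSTRIALIZED_POPULATIONS

logger = logging.getLogger("wilddom")

CONTRAST_CATEGORIES = ("laboratory", "companion", "agricultural")


def _animal_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    return metadata[metadata["category"] != "primate"]


# ---------------------------------------------------------------------------
# dyad shifts
# ---------------------------------------------------------------------------

def dyad_shift_analysis(
    ordination: OrdinationResult,
    metadata: pd.DataFrame,
    axis: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Signed displacement of each animal sample from its dyad mean on axis 1.

    Returns the per-sample shift records and Mann-Whitney contrasts of
    wild vs domesticated displacements: overall, per dyad, and per
    domestication category (Bonferroni-adjusted across categories).
    """
    coords = ordination.axis(axis)
    meta = _animal_metadata(metadata).copy()
    meta = meta[(meta["dyad_id"] != NA) & (meta["status"] != NA)]
    meta = meta[meta.index.isin(coords.index)]

    usable = []
    for dyad, sub in meta.groupby("dyad_id"):
        if sub["status"].nunique() < 2:
            logger.warning("dyad %s has a single status; excluded from shift analysis", dyad)
            continue
        usable.append(dyad)
    meta = meta[meta["dyad_id"].isin(usable)]
    ax = coords.loc[meta.index]
    dyad_mean = ax.groupby(meta["dyad_id"]).transform("mean")
    records = pd.DataFrame(
        {
            "sample_id": meta.index,
            "dyad_id": meta["dyad_id"],
            "status": meta["status"],
            "category": meta["category"],
            "axis": axis + 1,
            "coordinate": ax,
            "displacement": ax - dyad_mean,
            "reference": "dyad_mean",
        }
    )

    dom = records.loc[records["status"] == "domesticated", "displacement"]
    wild = records.loc[records["status"] == "wild", "displacement"]
    if pd.concat([dom, wild]).nunique() <= 1:  # degenerate: all displacements equal
        overall = stats.TestResult("mann_whitney_u", statistic=float("nan"), p_value=1.0)
    else:
        overall = stats.mann_whitney(dom, wild)
    results: dict = {"overall": overall, "by_dyad": {}, "by_category": {}}
    for dyad, sub in records.groupby("dyad_id"):
        d = sub.loc[sub["status"] == "domesticated", "displacement"]
        w = sub.loc[sub["status"] == "wild", "displacement"]
        results["by_dyad"][dyad] = stats.mann_whitney(d, w)
    cat_results = {}
    for cat in CONTRAST_CATEGORIES:
        sub = records[records["category"] == cat]
        if sub.empty:
            continue
        d = sub.loc[sub["status"] == "domesticated", "displacement"]
        w = sub.loc[sub["status"] == "wild", "displacement"]
        if len(d) and len(w):
            cat_results[cat] = stats.mann_whitney(d, w)
    adjusted = stats.bonferroni([r.p_value for r in cat_results.values()]) if cat_results else []
    for (cat, res), p_adj in zip(cat_results.items(), adjusted):
        res.notes["p_bonferroni"] = float(p_adj)
        results["by_category"][cat] = res
    return records, results


# ---------------------------------------------------------------------------
# dissimilarity categories
# ---------------------------------------------------------------------------

def categorize_pairs(dm: DistanceMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """Label every unordered animal sample pair conspecific / dyad / unrelated.

    The three labels partition the C(n, 2) pairs: same host species ->
    conspecific; same dyad, different species -> dyad; otherwise unrelated.
    """
    meta = _animal_metadata(metadata)
    ids = [s for s in dm.ids if s in meta.index]
    species = meta.loc[ids, "host_species"].to_numpy()
    dyad = meta.loc[ids, "dyad_id"].to_numpy()
    individual = meta.loc[ids, "individual_id"].to_numpy()
    sub = dm.filter(ids)
    iu, ju = np.triu_indices(len(ids), k=1)
    same_species = species[iu] == species[ju]
    same_dyad = (dyad[iu] == dyad[ju]) & (dyad[iu] != NA)
    category = np.where(same_species, "conspecific", np.where(same_dyad, "dyad", "unrelated"))
    return pd.DataFrame(
        {
            "sample_a": np.asarray(ids)[iu],
            "sample_b": np.asarray(ids)[ju],
            "ind_a": individual[iu],
            "ind_b": individual[ju],
            "category": category,
            "value": sub.data[iu, ju],
        }
    )


def dissimilarity_categories(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Contrast conspecific / dyad / unrelated pairwise dissimilarities.

    Pairwise contrasts use the individual-stratified bootstrap Mann-Whitney
    (pairs sharing an individual are not independent); the omnibus contrast
    is the stratified-bootstrap Kruskal-Wallis.
    """
    config = config or RunConfig()
    records = categorize_pairs(dm, metadata)
    results: dict = {"category_means": records.groupby("category")["value"].mean().to_dict()}
    present = set(records["category"])
    contrasts = [("dyad", "unrelated"), ("conspecific", "dyad"), ("conspecific", "unrelated")]
    for g1, g2 in contrasts:
        if g1 not in present or g2 not in present:
            logger.warning("category contrast %s vs %s skipped (empty category)", g1, g2)
            continue
        sub = records[records["category"].isin([g1, g2])].rename(columns={"category": "group"})
        results[f"{g1}_vs_{g2}"] = stats.stratified_bootstrap_mwu(
            sub, n_bootstrap=config.n_bootstrap, seed=config.random_seed
        )
    if len(present) == 3:
        omnibus = records.rename(columns={"category": "group"})
        results["kruskal_all"] = stats.stratified_bootstrap_kruskal(
            omnibus, n_bootstrap=config.n_bootstrap, seed=config.random_seed
        )
    return records, results


# ---------------------------------------------------------------------------
# divergence-time analyses
# ---------------------------------------------------------------------------

def species_mean_dissimilarity(dm: DistanceMatrix, metadata: pd.DataFrame) -> DistanceMatrix:
    """Species x species matrix of mean between-species sample dissimilarities."""
    meta = metadata[metadata.index.isin([str(i) for i in dm.ids])]
    species = sorted(meta["host_species"].unique())
    out = np.zeros((len(species), len(species)))
    members = {sp: meta.index[meta["host_species"] == sp].tolist() for sp in species}
    frame = pd.DataFrame(dm.data, index=[str(i) for i in dm.ids], columns=[str(i) for i in dm.ids])
    for i, si in enumerate(species):
        for j in range(i + 1, len(species)):
            block = frame.loc[members[si], members[species[j]]].to_numpy()
            out[i, j] = out[j, i] = float(block.mean())
    return DistanceMatrix(out, ids=species)


def divergence_time_matrix(
    metadata: pd.DataFrame,
    dyads: pd.DataFrame,
    species_ids: list[str],
    deep_time: float = 8.0e7,
) -> DistanceMatrix:
    """Divergence times between species: within-dyad from the dyad table,
    cross-dyad pairs set to a deep (pre-ordinal) split time."""
    sp_dyad = (
        metadata.drop_duplicates("host_species").set_index("host_species")["dyad_id"].to_dict()
    )
    n = len(species_ids)
    out = np.full((n, n), deep_time)
    np.fill_diagonal(out, 0.0)
    for i, si in enumerate(species_ids):
        for j in range(i + 1, n):
            di, dj = sp_dyad.get(si, NA), sp_dyad.get(species_ids[j], NA)
            if di == dj and di != NA and di in dyads.index:
                t = dyads.loc[di, "time_since_divergence"]
                if np.isfinite(t):
                    out[i, j] = out[j, i] = float(t)
    return DistanceMatrix(out, ids=species_ids)


def within_dyad_mean_dissimilarity(records: pd.DataFrame, metadata: pd.DataFrame) -> pd.Series:
    """Mean cross-status dissimilarity per dyad from categorized pair records."""
    dyad_pairs = records[records["category"] == "dyad"].copy()
    sample_dyad = metadata["dyad_id"]
    dyad_pairs["dyad_id"] = sample_dyad.reindex(dyad_pairs["sample_a"]).to_numpy()
    return dyad_pairs.groupby("dyad_id")["value"].mean()


def divergence_analysis(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    dyads: pd.DataFrame,
    shift_records: pd.DataFrame,
    config: RunConfig | None = None,
    include_primates: bool = False,
    host_divergence: DistanceMatrix | None = None,
) -> dict:
    """Relate community dissimilarity and ordination shifts to host divergence.

    (i) Mantel between the species-level mean-dissimilarity matrix and the
    divergence-time matrix; (ii) Spearman of |axis-1 shift| vs dyad
    divergence time; (iii) Spearman of within-dyad mean cross-status
    dissimilarity vs time since domestication and divergence; (iv) mixed-
    model LRT for the status term with divergence time as grouping.
    """
    config = config or RunConfig()
    meta = metadata if include_primates else _animal_metadata(metadata)
    results: dict = {}

    n_dyads = meta.loc[meta["dyad_id"] != NA, "dyad_id"].nunique()
    if n_dyads < 4:
        logger.warning("fewer than 4 dyads; Mantel divergence test skipped")
    else:
        mean_dm = species_mean_dissimilarity(dm, meta)
        if host_divergence is not None and set(mean_dm.ids) <= set(host_divergence.ids):
            div_dm = host_divergence.filter(mean_dm.ids)
        else:
            div_dm = divergence_time_matrix(meta, dyads, list(mean_dm.ids))
        results["mantel_divergence"] = stats.mantel(
            mean_dm, div_dm, correlation="pearson",
            n_permutations=config.n_permutations, seed=config.random_seed,
        )

    div_per_dyad = dyads["time_since_divergence"]
    shifts = shift_records.copy()
    shifts["divergence"] = div_per_dyad.reindex(shifts["dyad_id"]).to_numpy()
    ok = shifts["divergence"].notna()
    results["spearman_shift_vs_divergence"] = stats.spearman(
        shifts.loc[ok, "displacement"].abs(), shifts.loc[ok, "divergence"]
    )

    pair_records = categorize_pairs(dm, meta)
    dyad_mean = within_dyad_mean_dissimilarity(pair_records, meta)
    joined = pd.DataFrame({"dissimilarity": dyad_mean}).join(
        dyads[["time_since_domestication", "time_since_divergence"]]
    )
    for col, label in (
        ("time_since_domestication", "spearman_dyad_dissimilarity_vs_domestication_time"),
        ("time_since_divergence", "spearman_dyad_dissimilarity_vs_divergence_time"),
    ):
        ok = joined[col].notna()
        if ok.sum() >= 3:
            results[label] = stats.spearman(joined.loc[ok, "dissimilarity"], joined.loc[ok, col])

    # status term on the raw axis-1 coordinate, correcting for dyad (random
    # intercept) and divergence time (fixed covariate)
    lmm_data = shifts.loc[shifts["divergence"].notna()].copy()
    lmm_data["log_divergence"] = np.log10(lmm_data["divergence"])
    try:
        results["lmm_status_given_dyad"] = stats.lmm_lrt(
            lmm_data,
            response="coordinate",
            fixed_full=["C(status)", "log_divergence"],
            fixed_null=["log_divergence"],
            group="dyad_id",
        )
    except Exception as exc:  # singular fits on degenerate inputs
        logger.warning("divergence LMM failed: %s", exc)
    return results


# ---------------------------------------------------------------------------
# alpha-diversity / density / pathogen contrasts
# ---------------------------------------------------------------------------

def compute_alpha_records(
    dataset: ValidatedDataset, config: RunConfig | None = None
) -> pd.DataFrame:
    """Per-sample Shannon, richness, density, and pathogen metrics.

    Shannon/richness come from the rarefied table; pathogen relative
    abundance from the unrarefied table; pathogen richness from the
    rarefied pathogen subset.
    """
    config = config or RunConfig()
    rarefied = rarefy(dataset.counts, config.rarefaction_depth, seed=config.random_seed)
    alpha = alpha_table(rarefied, log_base=config.shannon_log_base)
    out = alpha.reindex(dataset.counts.sample_ids)
    if dataset.pathogens:
        pmet = pathogen_metrics(dataset.counts, dataset.pathogens, rarefied=rarefied)
        out = out.join(pmet)
    density = pd.to_numeric(dataset.metadata["microbial_density"], errors="coerce")
    out["density"] = density.reindex(out.index)
    return out


ALPHA_METRICS = ("density", "shannon", "richness", "pathogen_richness", "pathogen_abundance")


def status_contrasts(alpha_records: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Mann-Whitney wild-vs-domesticated contrasts for each alpha metric,
    overall and within each domestication category, Bonferroni-adjusted
    across the metric x category grid."""
    meta = _animal_metadata(metadata)
    rows = []
    scopes = [("overall", meta)] + [
        (cat, meta[meta["category"] == cat]) for cat in CONTRAST_CATEGORIES
    ]
    for metric in ALPHA_METRICS:
        if metric not in alpha_records.columns:
            continue
        values = alpha_records[metric]
        for scope, sub in scopes:
            dom = values.reindex(sub.index[sub["status"] == "domesticated"]).dropna()
            wild = values.reindex(sub.index[sub["status"] == "wild"]).dropna()
            if dom.empty or wild.empty:
                logger.warning("status contrast %s/%s skipped (empty group)", metric, scope)
                continue
            if pd.concat([dom, wild]).nunique() <= 1:
                continue
            res = stats.mann_whitney(dom, wild)
            rows.append(
                {
                    "metric": metric,
                    "scope": scope,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n_domesticated": len(dom),
                    "n_wild": len(wild),
                    "median_domesticated": float(dom.median()),
                    "median_wild": float(wild.median()),
                }
            )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["p_bonferroni"] = stats.bonferroni(frame["p_value"].to_numpy())
    return frame


# ---------------------------------------------------------------------------
# family-level contrasts
# ---------------------------------------------------------------------------

def family_abundances(table: CountTable) -> pd.DataFrame:
    """Per-sample relative abundance aggregated at the family rank.

    Taxa without a family annotation are pooled into ``unassigned`` so the
    per-sample abundances sum to 1.
    """
    ranks = table.taxonomy_frame()
    family = ranks["family"].replace("", "unassigned")
    rel = table.relative_abundance()
    return rel.T.groupby(family.to_numpy()).sum().T


def family_contrasts(
    table: CountTable,
    metadata: pd.DataFrame,
    families: list[str] | None = None,
) -> pd.DataFrame:
    """Mann-Whitney wild-vs-domesticated contrast per family, Bonferroni over
    families; primate population means are reported alongside so gradients
    (chimpanzee -> non-industrialized -> industrialized) can be read off."""
    abundances = family_abundances(table)
    meta = metadata.reindex(abundances.index)
    animal = meta["category"] != "primate"
    if families is None:
        families = [f for f in abundances.columns if f != "unassigned"]
    rows = []
    for fam in families:
        if fam not in abundances.columns:
            logger.warning("family %s absent from the table; zero-abundance contrast", fam)
            values = pd.Series(0.0, index=abundances.index)
        else:
            values = abundances[fam]
        dom = values[animal & (meta["status"] == "domesticated")]
        wild = values[animal & (meta["status"] == "wild")]
        if pd.concat([dom, wild]).nunique() <= 1:
            stat_val, p = float("nan"), 1.0
        else:
            res = stats.mann_whitney(dom, wild)
            stat_val, p = res.statistic, res.p_value
        row = {
            "family": fam,
            "statistic": stat_val,
            "p_value": p,
            "mean_domesticated": float(dom.mean()),
            "mean_wild": float(wild.mean()),
        }
        primates = meta["category"] == "primate"
        if primates.any():
            pops = meta.loc[primates, "population_label"]
            chimp = values[primates & (pops == "chimpanzee")]
            industrial = values[primates & pops.isin(INDUSTRIALIZED_POPULATIONS)]
            nonind = values[primates & (pops != "chimpanzee") & ~pops.isin(INDUSTRIALIZED_POPULATIONS)]
            row.update(
                mean_chimpanzee=float(chimp.mean()),
                mean_nonindustrialized=float(nonind.mean()),
                mean_industrialized=float(industrial.mean()),
            )
        rows.append(row)
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["p_bonferroni"] = stats.bonferroni(frame["p_value"].to_numpy())
    return frame


# ---------------------------------------------------------------------------
# longitudinal experiments
# ---------------------------------------------------------------------------

def _reference_samples(metadata: pd.DataFrame) -> dict[str, list[str]]:
    """Reference sample sets per treatment group: the donor when present,
    otherwise the matching diet control group at baseline."""
    refs: dict[str, list[str]] = {}
    donor = metadata.index[metadata["treatment_group"] == "donor"].tolist()
    groups = [g for g in metadata["treatment_group"].unique() if g not in (NA, "donor")]
    for group in groups:
        if donor:
            refs[group] = donor
            continue
        target_host = "Wild_H" if group.endswith("Wild_D") else "Dom_H"
        control = f"{target_host}/{'Wild_D' if target_host == 'Wild_H' else 'Dom_D'}"
        baseline = metadata.index[
            (metadata["treatment_group"] == control) & (metadata["timepoint"] == 0)
        ].tolist()
        refs[group] = baseline
    return refs


def experiment_analysis(
    ordination: OrdinationResult,
    metadata: pd.DataFrame,
    dm: DistanceMatrix,
    axis: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-individual trajectories along axis 1 and distance-to-reference.

    Displacement is the final minus day-0 axis-1 coordinate per individual
    (individuals missing the day-0 sample are excluded with a warning); each
    treatment group gets a one-sample Wilcoxon of displacements against 0; a
    mixed-model LRT tests the treatment-group term on the axis-1 coordinate;
    distance to the reference (donor or baseline diet control) is reported
    both as the axis-1 gap to the reference mean and as the mean pairwise
    dissimilarity to the reference samples; endpoint contrasts compare
    groups by Mann-Whitney and Kruskal-Wallis.
    """
    ax = ordination.axis(axis)
    meta = metadata[metadata["treatment_group"] != NA]
    meta = meta[meta["treatment_group"] != "donor"]
    refs = _reference_samples(metadata)
    frame = pd.DataFrame(dm.data, index=[str(i) for i in dm.ids], columns=[str(i) for i in dm.ids])

    rows = []
    for ind, sub in meta.groupby("individual_id"):
        sub = sub.sort_values("timepoint")
        times = sub["timepoint"].tolist()
        if 0 not in times:
            logger.warning("individual %s lacks a day-0 sample; excluded", ind)
            continue
        group = sub["treatment_group"].iloc[0]
        ref_ids = refs.get(group, [])
        ref_axis_mean = float(ax.reindex(ref_ids).mean()) if ref_ids else np.nan
        for sid, t in zip(sub.index, times):
            coord = float(ax[sid])
            mean_diss = float(frame.loc[sid, ref_ids].mean()) if ref_ids else np.nan
            rows.append(
                {
                    "individual_id": ind,
                    "treatment_group": group,
                    "timepoint": t,
                    "sample_id": sid,
                    "axis1": coord,
                    "axis1_gap_to_reference": abs(coord - ref_axis_mean),
                    "mean_dissimilarity_to_reference": mean_diss,
                }
            )
    trajectories = pd.DataFrame(rows)

    results: dict = {"wilcoxon_by_group": {}}
    displacements = {}
    for (ind, group), sub in trajectories.groupby(["individual_id", "treatment_group"]):
        sub = sub.sort_values("timepoint")
        displacements[(ind, group)] = sub["axis1"].iloc[-1] - sub["axis1"].iloc[0]
    disp_frame = pd.DataFrame(
        [(g, d) for (_, g), d in displacements.items()], columns=["treatment_group", "displacement"]
    )
    results["displacements"] = disp_frame
    for group, sub in disp_frame.groupby("treatment_group"):
        results["wilcoxon_by_group"][group] = stats.wilcoxon_one_sample(sub["displacement"])

    lmm_data = trajectories.rename(columns={"axis1": "axis1_coord"})
    try:
        results["lmm_treatment"] = stats.lmm_lrt(
            lmm_data,
            response="axis1_coord",
            fixed_full=["timepoint", "C(treatment_group)"],
            fixed_null=["timepoint"],
            group="individual_id",
        )
    except Exception as exc:
        logger.warning("experiment LMM failed: %s", exc)

    final_t = trajectories.groupby("individual_id")["timepoint"].max()
    endpoint = trajectories[
        trajectories["timepoint"] == final_t.reindex(trajectories["individual_id"]).to_numpy()
    ]
    results["endpoint_distance_means"] = (
        endpoint.groupby("treatment_group")["mean_dissimilarity_to_reference"].mean().to_dict()
    )
    groups = sorted(endpoint["treatment_group"].unique())
    by_group = {
        g: endpoint.loc[endpoint["treatment_group"] == g, "mean_dissimilarity_to_reference"].dropna()
        for g in groups
    }
    if len(groups) >= 2:
        pairs_done = {}
        for i, g1 in enumerate(groups):
            for g2 in groups[i + 1:]:
                if len(by_group[g1]) and len(by_group[g2]):
                    pairs_done[f"{g1}_vs_{g2}"] = stats.mann_whitney(by_group[g1], by_group[g2])
        results["endpoint_mwu"] = pairs_done
    if len(groups) >= 3 and all(len(v) for v in by_group.values()):
        results["endpoint_kruskal"] = stats.kruskal_wallis(list(by_group.values()))
    return trajectories, results


# ---------------------------------------------------------------------------
# industrialization comparison
# ---------------------------------------------------------------------------

def industrialization_comparison(
    ordination: OrdinationResult,
    metadata: pd.DataFrame,
    dm: DistanceMatrix,
    config: RunConfig | None = None,
    axis: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Compare the industrialized-human shift with the domestication shift.

    (i) Displacement of every primate sample from the all-primate axis-1
    mean, contrasted per human population against chimpanzees and against
    the non-industrialized pool; (ii) animal-to-industrialized-human
    dissimilarities grouped by animal status, compared with the
    individual-stratified bootstrap; (iii) the same contrast within each
    domestication category.
    """
    config = config or RunConfig()
    ax = ordination.axis(axis)
    primates = metadata[metadata["category"] == "primate"]
    if primates.empty or (primates["population_label"] == NA).all():
        raise ValidationError("industrialization comparison requires labelled primate cohorts")
    primate_axis = ax.reindex(primates.index)
    primate_mean = float(primate_axis.mean())
    records = pd.DataFrame(
        {
            "sample_id": primates.index,
            "population": primates["population_label"],
            "axis": axis + 1,
            "displacement": primate_axis - primate_mean,
            "reference": "primate_mean",
        }
    )

    results: dict = {"by_population_vs_chimp": {}, "by_population_vs_nonindustrialized": {}}
    chimp = records.loc[records["population"] == "chimpanzee", "displacement"]
    industrial_mask = records["population"].isin(INDUSTRIALIZED_POPULATIONS)
    nonind = records.loc[(records["population"] != "chimpanzee") & ~industrial_mask, "displacement"]
    for pop, sub in records[records["population"] != "chimpanzee"].groupby("population"):
        results["by_population_vs_chimp"][pop] = stats.mann_whitney(sub["displacement"], chimp)
        if len(nonind):
            results["by_population_vs_nonindustrialized"][pop] = stats.mann_whitney(
                sub["displacement"], nonind
            )
    results["industrialized_mean_displacement"] = float(
        records.loc[industrial_mask, "displacement"].mean()
    )

    # animal-to-industrialized-human dissimilarities by animal status
    animals = _animal_metadata(metadata)
    animals = animals[animals["status"] != NA]
    humans = primates[primates["population_label"].isin(INDUSTRIALIZED_POPULATIONS)]
    frame = pd.DataFrame(dm.data, index=[str(i) for i in dm.ids], columns=[str(i) for i in dm.ids])
    block = frame.loc[animals.index, humans.index]
    block = block.rename_axis(index="animal", columns="human")
    pairs = block.stack().rename("value").reset_index()
    pairs["ind_a"] = animals["individual_id"].reindex(pairs["animal"]).to_numpy()
    pairs["ind_b"] = humans["individual_id"].reindex(pairs["human"]).to_numpy()
    pairs["group"] = animals["status"].reindex(pairs["animal"]).to_numpy()
    strata = pd.concat(
        [animals["status"], pd.Series("human", index=humans["individual_id"])]
    )
    strata = strata[~strata.index.duplicated()]
    results["animal_to_industrialized"] = stats.stratified_bootstrap_mwu(
        pairs, n_bootstrap=config.n_bootstrap, seed=config.random_seed, individual_strata=strata
    )
    results["animal_to_industrialized_means"] = pairs.groupby("group")["value"].mean().to_dict()
    by_cat = {}
    for cat in CONTRAST_CATEGORIES:
        cat_animals = animals.index[animals["category"] == cat]
        sub = pairs[pairs["animal"].isin(cat_animals)]
        if sub["group"].nunique() == 2:
            by_cat[cat] = stats.stratified_bootstrap_mwu(
                sub, n_bootstrap=config.n_bootstrap, seed=config.random_seed,
                individual_strata=strata,
            )
    results["animal_to_industrialized_by_category"] = by_cat
    return records, results


# ---------------------------------------------------------------------------
# chained drivers
# ---------------------------------------------------------------------------

@dataclass
class CrossSpeciesResults:
    distance: DistanceMatrix
    ordination: OrdinationResult
    permanova: list
    dispersion: stats.TestResult
    shift_records: pd.DataFrame
    shift_tests: dict
    category_records: pd.DataFrame
    category_tests: dict
    divergence: dict
    alpha_records: pd.DataFrame
    status_tests: pd.DataFrame
    family_tests: pd.DataFrame
    industrialization: tuple | None = None
    extras: dict = field(default_factory=dict)


def run_cross_species(dataset: ValidatedDataset, config: RunConfig | None = None) -> CrossSpeciesResults:
    """The full comparative survey pipeline on a validated dataset."""
    config = config or RunConfig()
    metadata = dataset.metadata
    animals = _animal_metadata(metadata)
    has_primates = len(animals) < len(metadata)

    animal_counts = dataset.counts.subset_samples(list(animals.index))
    dm = distance_matrix(animal_counts, metric=config.distance_metric, tree=dataset.tree)
    ordination = orient(nmds_from_config(dm, config), metadata)

    scheme = stats.PermutationScheme(
        type="within_strata",
        strata=animals["dyad_id"],
        n_permutations=config.n_permutations,
        seed=config.random_seed,
    )
    perm = stats.permanova(dm, animals, terms=["dyad_id", "status"], scheme=scheme)
    # between-conspecific variability: distance to own-species centroid,
    # contrasted across domestication status
    disp = stats.dispersion_test(
        dm,
        animals["host_species"],
        contrast_groups=animals["status"],
        n_permutations=config.n_permutations,
        seed=config.random_seed,
    )
    shift_records, shift_tests = dyad_shift_analysis(ordination, metadata)
    category_records, category_tests = dissimilarity_categories(dm, metadata, config)
    divergence = divergence_analysis(
        dm, metadata, dataset.dyads, shift_records, config,
        host_divergence=dataset.host_divergence,
    )
    alpha = compute_alpha_records(dataset, config)
    status_tests = status_contrasts(alpha, metadata)
    family_tests = family_contrasts(dataset.counts, metadata)

    industrial = None
    if has_primates:
        joint_ord, joint_dm = joint_ordination(
            [dataset.counts], metric=config.distance_metric, config=config, tree=dataset.tree
        )
        joint_ord = orient(joint_ord, metadata)
        industrial = industrialization_comparison(joint_ord, metadata, joint_dm, config)
    return CrossSpeciesResults(
        distance=dm,
        ordination=ordination,
        permanova=perm,
        dispersion=disp,
        shift_records=shift_records,
        shift_tests=shift_tests,
        category_records=category_records,
        category_tests=category_tests,
        divergence=divergence,
        alpha_records=alpha,
        status_tests=status_tests,
        family_tests=family_tests,
        industrialization=industrial,
    )


def run_experiment(dataset: ValidatedDataset, config: RunConfig | None = None):
    """Ordination + trajectory analysis for a longitudinal experiment dataset."""
    config = config or RunConfig()
    dm = distance_matrix(dataset.counts, metric=config.distance_metric, tree=dataset.tree)
    ordination = orient(nmds_from_config(dm, config), dataset.metadata)
    return experiment_analysis(ordination, dataset.metadata, dm)
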