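"""Synthetic dyad-structured gut-microbiome datasets with planted effects.

The generator emulates the statistical structure of a cross-species
wild/domesticated survey: nine species dyads sampled at 5-20 individuals
per species, a directional "domestication" shift along a latent axis,
greater within-species dispersion on the wild side, dissimilarity coupled
to dyad divergence time, pathogen taxa enriched in wild samples, sequencing
depths drawn from a lognormal matching 158,611 +/- 109,567 assigned reads
per sample, and optional primate cohorts (chimpanzees, non-industrialized
and industrialized human populations) and longitudinal diet/colonization
experiments.

Counts arise from a log-linear latent model: each sample has a latent point
``z``; taxon loadings ``L`` and intercepts ``b`` are drawn once per dataset;
the expected composition is ``softmax(b + L z)``; reads are a
Dirichlet-multinomial draw with concentration ``theta`` at a lognormal
depth. Every planted parameter is recorded in ``ground_truth`` so each
pipeline estimator can be scored against the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .datasets import NA, CountTable, ValidatedDataset, ValidationError, validate_dataset

DEPTH_MEAN = 158_611.0
DEPTH_SD = 109_567.0

INDUSTRIALIZED_POPULATIONS = ("US", "US_Jha")
NONINDUSTRIALIZED_POPULATIONS = ("Hadza", "Chepang", "Raji", "Raute", "Tharu")

DIET_GROUPS = ("Dom_H/Dom_D", "Dom_H/Wild_D", "Wild_H/Wild_D", "Wild_H/Dom_D")
COLONIZATION_GROUPS = ("Wild_C/Wild_D", "Wild_C/Dom_D", "PBS_C/Wild_D")


@dataclass
class LongitudinalBlock:
    """Design of a reciprocal-diet or colonization experiment."""

    kind: str = "diet"  # {"diet", "colonization"}
    n_per_group: int = 10
    timepoints: tuple = (0, 7, 14, 21, 28)
    sigma_individual: float = 0.4
    sigma_timepoint: float = 0.25
    # total drift fraction toward the target reached at the final timepoint
    drift_wild_to_dom: float = 0.8   # Wild_H/Dom_D converges strongly (mouse asymmetry)
    drift_dom_to_wild: float = 0.3   # Dom_H/Wild_D converges only partially
    donor_jump_fraction: float = 0.7  # colonization gavage
    control_diet_drift: float = 0.25  # PBS control on wild diet


@dataclass
class SyntheticSpec:
    """All planted parameters of a generated dataset (see module docstring)."""

    n_dyads: int = 9
    samples_per_species: int | tuple = (5, 20)
    n_taxa: int = 150
    n_pathogen_taxa: int = 15
    latent_dims: int = 2
    sigma_dyad: float = 5.0
    sigma_wild: float = 2.0
    sigma_dom: float = 1.0
    domestication_shift: float = 2.0
    divergence_coupling: float = 1.0
    minor_axis_fraction: float = 0.35  # dyad-center spread on latent axes > 1
    loading_scale: float = 0.35
    concentration: float = 600.0
    pathogen_enrichment: float = 4.0
    pathogen_rarity: float = 5.0  # log-units subtracted from pathogen intercepts
    depth_mean: float = DEPTH_MEAN
    depth_sd: float = DEPTH_SD
    include_primates: bool = False
    industrialization_shift: float | None = None  # defaults to domestication_shift
    primate_axis1_offset: float = 0.5  # primate cohort center, in sigma_dyad units
    n_per_population: int = 7
    longitudinal: LongitudinalBlock | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathogen_taxa > self.n_taxa:
            raise ValidationError("n_pathogen_taxa exceeds n_taxa")
        for name in ("sigma_dyad", "sigma_wild", "sigma_dom", "concentration", "depth_mean", "depth_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not np.isfinite(self.domestication_shift):
            raise ValidationError("domestication_shift must be finite")


@dataclass
class SyntheticDataset:
    counts: CountTable
    metadata: pd.DataFrame
    dyads: pd.DataFrame
    tree: TreeNode
    pathogens: list[str]
    ground_truth: dict
    spec: SyntheticSpec
    host_divergence: "object | None" = None  # species-level divergence-time DistanceMatrix

    def validate(self) -> ValidatedDataset:
        return validate_dataset(
            self.counts, self.metadata, self.dyads, self.tree, self.pathogens,
            host_divergence=self.host_divergence,
        )


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _random_tree(taxon_ids: list[str], rng: np.random.Generator) -> TreeNode:
    """Random bifurcating tree over the taxa with exponential branch lengths."""
    nodes = [f"{tid}:{rng.exponential(0.1):.6f}" for tid in taxon_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.exponential(0.1):.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    newick = nodes[0]
    newick = newick.rsplit(":", 1)[0] + ";"  # root carries no length
    return TreeNode.read([newick])


def _taxonomy(rng: np.random.Generator, n_taxa: int, pathogen_idx: np.ndarray):
    """Synthetic 7-rank lineages; pathogen taxa get dedicated genus names."""
    n_families = max(6, n_taxa // 12)
    families = rng.integers(0, n_families, size=n_taxa)
    lineages, pathogen_names = [], []
    for i in range(n_taxa):
        if i in pathogen_idx:
            genus = f"Pathogenus{i:03d}"
            pathogen_names.append(genus.lower())
        else:
            genus = f"Genus{i:03d}"
        lineages.append(
            "k__Bacteria;p__Phylum{p};c__Class{p};o__Order{p};f__Family{f:02d};g__{g};s__sp{i:03d}".format(
                p=families[i] % 4, f=families[i], g=genus, i=i
            )
        )
    return lineages, pathogen_names, families


def expected_composition(
    latent: np.ndarray, loadings: np.ndarray, intercepts: np.ndarray
) -> np.ndarray:
    """Softmax(intercepts + loadings . latent) per sample.

    Invariant to any rotation R applied jointly to the latent points and the
    loadings (``z -> R z``, ``L -> L R``), which is why latent axes are only
    identified up to rotation and the pipeline fixes orientation downstream.
    """
    eta = np.asarray(intercepts)[None, :] + np.asarray(latent) @ np.asarray(loadings).T
    eta = eta - eta.max(axis=1, keepdims=True)
    comp = np.exp(eta)
    return comp / comp.sum(axis=1, keepdims=True)


def _compose_counts(
    rng: np.random.Generator,
    latent: np.ndarray,
    loadings: np.ndarray,
    intercepts: np.ndarray,
    wild_mask: np.ndarray,
    pathogen_idx: np.ndarray,
    spec: SyntheticSpec,
) -> np.ndarray:
    """Latent points -> softmax composition -> Dirichlet-multinomial reads."""
    eta = intercepts[None, :] + latent @ loadings.T
    if len(pathogen_idx):
        # potential pathogens are rare taxa, enriched in wild samples; their
        # rarity is what makes rarefied pathogen richness a detection contrast
        eta[:, pathogen_idx] -= spec.pathogen_rarity
        if spec.pathogen_enrichment != 1.0:
            bonus = math.log(spec.pathogen_enrichment)
            eta[np.ix_(wild_mask, pathogen_idx)] += bonus
    eta -= eta.max(axis=1, keepdims=True)
    comp = np.exp(eta)
    comp /= comp.sum(axis=1, keepdims=True)
    mu, sigma = _lognormal_params(spec.depth_mean, spec.depth_sd)
    depths = np.maximum(rng.lognormal(mu, sigma, size=len(latent)).astype(int), 100)
    counts = np.empty((len(latent), comp.shape[1]), dtype=np.int64)
    for i in range(len(latent)):
        p = rng.dirichlet(spec.concentration * comp[i] + 1e-9)
        counts[i] = rng.multinomial(depths[i], p)
    return counts


HOST_ROOT_AGE = 8.0e7  # years; deep pre-ordinal split among host lineages


def _host_history(
    rng: np.random.Generator, n_tips: int, spec: SyntheticSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Host phylogeny over dyad ancestors with Brownian latent evolution.

    A random coalescent over ``n_tips`` host lineages (root at
    ``HOST_ROOT_AGE``) is simulated and lineage positions evolve by Brownian
    motion, scaled so tip positions have the configured dyad spread —
    mostly along latent axis 1, the direction the planted shift acts along,
    so the leading ordination axis carries the domestication contrast the
    way the study design assumes. Hosts that diverged recently therefore
    sit close in latent space, giving dissimilarity a genuine divergence-
    time signal. Returns tip positions (n_tips x latent_dims) and the
    pairwise time-to-MRCA matrix (years).
    """
    d = spec.latent_dims
    scale = np.full(d, spec.sigma_dyad * spec.minor_axis_fraction)
    scale[0] = spec.sigma_dyad
    if n_tips == 1:
        return rng.normal(0.0, 1.0, size=(1, d)) * scale, np.zeros((1, 1))
    ages = np.sort(rng.uniform(0.15 * HOST_ROOT_AGE, HOST_ROOT_AGE, size=n_tips - 1))
    ages[-1] = HOST_ROOT_AGE
    nodes = [{"age": 0.0, "tips": [i], "children": []} for i in range(n_tips)]
    active = list(range(n_tips))
    tmrca = np.zeros((n_tips, n_tips))
    for age in ages:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = nodes[active[i]], nodes[active[j]]
        for ta in a["tips"]:
            for tb in b["tips"]:
                tmrca[ta, tb] = tmrca[tb, ta] = age
        nodes.append({"age": age, "tips": a["tips"] + b["tips"], "children": [active[i], active[j]]})
        active = [x for k, x in enumerate(active) if k not in (i, j)] + [len(nodes) - 1]
    positions = np.zeros((n_tips, d))

    def walk(idx: int, pos: np.ndarray) -> None:
        node = nodes[idx]
        for child in node["children"]:
            dt = node["age"] - nodes[child]["age"]
            step = rng.normal(0.0, 1.0, size=d) * scale * math.sqrt(dt / HOST_ROOT_AGE)
            child_pos = pos + step
            if not nodes[child]["children"]:
                positions[nodes[child]["tips"][0]] = child_pos
            walk(child, child_pos)

    walk(len(nodes) - 1, np.zeros(d))
    return positions, tmrca


def _divergence_times(rng: np.random.Generator, n_dyads: int) -> np.ndarray:
    """Divergence times (years) log-spaced over the survey's range."""
    return np.exp(rng.uniform(math.log(1.0e4), math.log(5.0e6), size=n_dyads))


# ---------------------------------------------------------------------------
# cross-species survey (+ optional primate cohorts)
# ---------------------------------------------------------------------------

def generate(spec: SyntheticSpec, seed: int | None = None) -> SyntheticDataset:
    """Generate the cross-species survey dataset the comparative design assumes."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    d = spec.latent_dims

    pathogen_idx = rng.choice(spec.n_taxa, size=spec.n_pathogen_taxa, replace=False)
    lineages, pathogen_names, families = _taxonomy(rng, spec.n_taxa, pathogen_idx)
    loadings = rng.normal(0.0, spec.loading_scale, size=(spec.n_taxa, d))
    intercepts = rng.normal(0.0, 1.0, size=spec.n_taxa)

    divergence = _divergence_times(rng, spec.n_dyads)
    log_div = np.log10(divergence)
    div_z = (log_div - log_div.mean()) / (log_div.std() if log_div.std() > 0 else 1.0)

    n_tips = spec.n_dyads + (1 if spec.include_primates else 0)
    tip_positions, tmrca = _host_history(rng, n_tips, spec)

    latent_rows, meta_rows = [], []
    dyad_rows = []
    for k in range(spec.n_dyads):
        dyad = f"dyad{k + 1:02d}"
        center = tip_positions[k].copy()
        # separation grows with divergence time on top of the planted shift
        half_sep = (spec.domestication_shift + spec.divergence_coupling * (div_z[k] + 1.5)) / 2.0
        half_sep = max(half_sep, 0.0)
        offsets = {"domesticated": +half_sep, "wild": -half_sep}
        sigmas = {"domesticated": spec.sigma_dom, "wild": spec.sigma_wild}
        category = ("laboratory", "companion", "agricultural")[k % 3]
        if isinstance(spec.samples_per_species, tuple):
            lo, hi = spec.samples_per_species
            n_by_status = {s: int(rng.integers(lo, hi + 1)) for s in ("wild", "domesticated")}
        else:
            n_by_status = {s: int(spec.samples_per_species) for s in ("wild", "domesticated")}
        for status in ("wild", "domesticated"):
            species_center = center.copy()
            species_center[0] += offsets[status]
            for i in range(n_by_status[status]):
                z = species_center + rng.normal(0.0, sigmas[status], size=d)
                sid = f"{dyad}_{status[:4]}_{i + 1:02d}"
                latent_rows.append(z)
                meta_rows.append(
                    dict(
                        sample_id=sid,
                        host_species=f"species_{dyad}_{status[:4]}",
                        dyad_id=dyad,
                        status=status,
                        category=category,
                        diet_type=("omnivore", "herbivore", "carnivore")[k % 3],
                        gut_physiology=("simple", "foregut", "hindgut")[k % 3],
                        locale=f"site{k + 1:02d}",
                        individual_id=sid,
                        timepoint=0,
                        treatment_group=NA,
                        microbial_density=float(rng.lognormal(math.log(1e10), 0.5)),
                        population_label=NA,
                    )
                )
        dom_years = divergence[k] * rng.uniform(0.05, 0.9)
        dyad_rows.append(
            dict(dyad_id=dyad, time_since_domestication=dom_years, time_since_divergence=divergence[k])
        )

    industrial_shift = (
        spec.industrialization_shift
        if spec.industrialization_shift is not None
        else spec.domestication_shift
    )
    if spec.include_primates:
        # anchor the primate cohort right of the animal cloud's center so the
        # industrialized populations, shifted further right, occupy the
        # domesticated edge of the joint space
        primate_center = tip_positions[-1].copy()
        primate_center[0] = spec.primate_axis1_offset * spec.sigma_dyad
        populations = (
            [("chimpanzee", "Pan troglodytes", 0.0)]
            + [(p, "Homo sapiens", 0.0) for p in NONINDUSTRIALIZED_POPULATIONS]
            + [(p, "Homo sapiens", industrial_shift) for p in INDUSTRIALIZED_POPULATIONS]
        )
        for pop, species, shift in populations:
            pop_center = primate_center.copy()
            pop_center[0] += shift
            for i in range(spec.n_per_population):
                z = pop_center + rng.normal(0.0, spec.sigma_dom, size=d)
                sid = f"primate_{pop}_{i + 1:02d}"
                latent_rows.append(z)
                meta_rows.append(
                    dict(
                        sample_id=sid,
                        host_species=species,
                        dyad_id="primate_pair",
                        status=NA,
                        category="primate",
                        diet_type="omnivore",
                        gut_physiology="simple",
                        locale=pop,
                        individual_id=sid,
                        timepoint=0,
                        treatment_group=NA,
                        microbial_density=float(rng.lognormal(math.log(1e10), 0.5)),
                        population_label=pop,
                    )
                )
        dyad_rows.append(
            dict(
                dyad_id="primate_pair",
                time_since_domestication=np.nan,
                time_since_divergence=6.5e6,  # conservative Pan-Homo split
            )
        )

    latent = np.asarray(latent_rows)
    metadata = pd.DataFrame(meta_rows)
    wild_mask = (metadata["status"] == "wild").to_numpy()
    taxon_ids = [f"otu{i + 1:04d}" for i in range(spec.n_taxa)]
    counts = _compose_counts(rng, latent, loadings, intercepts, wild_mask, pathogen_idx, spec)
    table = CountTable(
        pd.DataFrame(counts, index=metadata["sample_id"].tolist(), columns=taxon_ids),
        taxonomy=pd.Series(lineages, index=taxon_ids),
    )
    tree = _random_tree(taxon_ids, rng)
    dyads = pd.DataFrame(dyad_rows).set_index("dyad_id", drop=False)

    # species-level divergence-time matrix (the analysis input a host
    # timetree would provide): within-dyad times from the dyad table,
    # cross-dyad times from the simulated host phylogeny
    from skbio import DistanceMatrix as _DM

    species, species_tip = [], []
    for k in range(spec.n_dyads):
        for status in ("wild", "domesticated"):
            species.append(f"species_dyad{k + 1:02d}_{status[:4]}")
            species_tip.append(k)
    if spec.include_primates:
        species += ["Pan troglodytes", "Homo sapiens"]
        species_tip += [n_tips - 1, n_tips - 1]
    div_matrix = np.zeros((len(species), len(species)))
    within_time = {k: divergence[k] for k in range(spec.n_dyads)}
    if spec.include_primates:
        within_time[n_tips - 1] = 6.5e6
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            ti, tj = species_tip[i], species_tip[j]
            t = within_time[ti] if ti == tj else tmrca[ti, tj]
            div_matrix[i, j] = div_matrix[j, i] = t
    host_divergence = _DM(div_matrix, ids=species)

    family_axis1 = (
        pd.DataFrame({"family": [f"Family{f:02d}" for f in families], "load": loadings[:, 0]})
        .groupby("family")["load"]
        .mean()
        .to_dict()
    )
    ground_truth = {
        "latent": latent,
        "loadings": loadings,
        "intercepts": intercepts,
        "domestication_shift": spec.domestication_shift,
        "industrialization_shift": industrial_shift if spec.include_primates else None,
        "sigma_wild": spec.sigma_wild,
        "sigma_dom": spec.sigma_dom,
        "pathogen_taxa": [taxon_ids[i] for i in pathogen_idx],
        "divergence_times": dict(zip([r["dyad_id"] for r in dyad_rows],
                                     [r["time_since_divergence"] for r in dyad_rows])),
        "family_axis1_loading": family_axis1,
        "spec": asdict(spec),
    }
    return SyntheticDataset(table, metadata.set_index("sample_id", drop=False),
                            dyads, tree, pathogen_names, ground_truth, spec,
                            host_divergence=host_divergence)


# ---------------------------------------------------------------------------
# longitudinal experiments
# ---------------------------------------------------------------------------

def generate_longitudinal(spec: SyntheticSpec, seed: int | None = None) -> SyntheticDataset:
    """Generate a reciprocal-diet or colonization experiment dataset.

    Individuals start at their species center plus an individual intercept;
    reciprocal-diet individuals drift linearly toward the other species'
    center, controls hold position, and colonization is an instantaneous
    jump of ``donor_jump_fraction`` toward the donor's point.
    """
    block = spec.longitudinal or LongitudinalBlock()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    d = spec.latent_dims

    pathogen_idx = rng.choice(spec.n_taxa, size=spec.n_pathogen_taxa, replace=False)
    lineages, pathogen_names, _ = _taxonomy(rng, spec.n_taxa, pathogen_idx)
    loadings = rng.normal(0.0, spec.loading_scale, size=(spec.n_taxa, d))
    intercepts = rng.normal(0.0, 1.0, size=spec.n_taxa)

    # a single dyad: keep it at the latent origin so compositions stay in
    # the well-mixed regime of the softmax map
    center = np.zeros(d)
    dom_center, wild_center = center.copy(), center.copy()
    dom_center[0] += spec.domestication_shift / 2.0
    wild_center[0] -= spec.domestication_shift / 2.0
    centers = {"domesticated": dom_center, "wild": wild_center}

    timepoints = tuple(block.timepoints)
    t_final = max(timepoints)
    groups = DIET_GROUPS if block.kind == "diet" else COLONIZATION_GROUPS
    donor_point = wild_center + rng.normal(0.0, spec.sigma_wild, size=d)

    latent_rows, meta_rows = [], []
    truth_drift: dict[str, float] = {}
    for group in groups:
        if block.kind == "diet":
            host = "domesticated" if group.startswith("Dom_H") else "wild"
            target = centers["wild" if group.endswith("Wild_D") else "domesticated"]
            if group == "Wild_H/Dom_D":
                total_drift = block.drift_wild_to_dom
            elif group == "Dom_H/Wild_D":
                total_drift = block.drift_dom_to_wild
            else:
                total_drift = 0.0
        else:
            host = "domesticated"  # colonization recipients are laboratory mice
            target = donor_point
            total_drift = block.donor_jump_fraction if group.startswith("Wild_C") else block.control_diet_drift
        truth_drift[group] = total_drift
        for i in range(block.n_per_group):
            ind = f"{group.replace('/', '_')}_m{i + 1:02d}"
            start = centers[host] + rng.normal(0.0, block.sigma_individual, size=d)
            for t in timepoints:
                if block.kind == "colonization" and group.startswith("Wild_C"):
                    frac = 0.0 if t == 0 else total_drift  # gavage acts at once
                else:
                    frac = total_drift * (t / t_final if t_final else 0.0)
                z = start + frac * (target - start) + rng.normal(0.0, block.sigma_timepoint, size=d)
                sid = f"{ind}_d{t:02d}"
                latent_rows.append(z)
                meta_rows.append(
                    dict(
                        sample_id=sid,
                        host_species=f"experiment_{host}",
                        dyad_id="experiment_dyad",
                        status=host,
                        category="laboratory",
                        diet_type="wild" if group.endswith("Wild_D") else "domesticate",
                        gut_physiology="simple",
                        locale="facility",
                        individual_id=ind,
                        timepoint=int(t),
                        treatment_group=group,
                        microbial_density=float(rng.lognormal(math.log(1e10), 0.5)),
                        population_label=NA,
                    )
                )
    if block.kind == "colonization":  # the wild donor community itself
        latent_rows.append(donor_point)
        meta_rows.append(
            dict(
                sample_id="donor_wild_01", host_species="experiment_wild",
                dyad_id="experiment_dyad", status="wild", category="laboratory",
                diet_type="wild", gut_physiology="simple", locale="facility",
                individual_id="donor_wild_01", timepoint=0, treatment_group="donor",
                microbial_density=float(rng.lognormal(math.log(1e10), 0.5)),
                population_label=NA,
            )
        )

    latent = np.asarray(latent_rows)
    metadata = pd.DataFrame(meta_rows)
    wild_mask = (metadata["status"] == "wild").to_numpy()
    taxon_ids = [f"otu{i + 1:04d}" for i in range(spec.n_taxa)]
    counts = _compose_counts(rng, latent, loadings, intercepts, wild_mask, pathogen_idx, spec)
    table = CountTable(
        pd.DataFrame(counts, index=metadata["sample_id"].tolist(), columns=taxon_ids),
        taxonomy=pd.Series(lineages, index=taxon_ids),
    )
    tree = _random_tree(taxon_ids, rng)
    dyads = pd.DataFrame(
        [dict(dyad_id="experiment_dyad", time_since_domestication=1.0e4, time_since_divergence=5.0e5)]
    ).set_index("dyad_id", drop=False)
    ground_truth = {
        "latent": latent,
        "drift_fractions": truth_drift,
        "donor_point": donor_point,
        "centers": {k: v for k, v in centers.items()},
        "domestication_shift": spec.domestication_shift,
        "kind": block.kind,
        "spec": asdict(spec),
    }
    return SyntheticDataset(table, metadata.set_index("sample_id", drop=False),
                            dyads, tree, pathogen_names, ground_truth, spec)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def score_recovery(dataset: SyntheticDataset, results: dict) -> dict:
    """Score pipeline estimates against the planted ground truth.

    ``results`` may carry any of: ``shift_mean`` (mean domesticated-minus-
    wild displacement), ``dispersion_means`` ({group: mean distance to
    centroid}), ``category_means`` ({conspecific/dyad/unrelated: mean
    dissimilarity}). Missing stages yield a partial report with a warning.
    """
    truth = dataset.ground_truth
    report: dict = {"scored": [], "missing": []}
    if "shift_mean" in results:
        planted = truth.get("domestication_shift", 0.0)
        est = results["shift_mean"]
        report["shift_sign_agrees"] = bool(planted == 0 or np.sign(est) == np.sign(planted))
        report["shift_estimate"] = float(est)
        report["scored"].append("shift")
    else:
        report["missing"].append("shift")
    if "dispersion_means" in results:
        means = results["dispersion_means"]
        ratio_true = truth.get("sigma_wild", 1.0) / truth.get("sigma_dom", 1.0)
        ratio_est = means.get("wild", np.nan) / means.get("domesticated", np.nan)
        report["dispersion_ratio_true"] = float(ratio_true)
        report["dispersion_ratio_estimate"] = float(ratio_est)
        report["dispersion_order_agrees"] = bool(
            (ratio_true - 1.0) * (ratio_est - 1.0) >= 0.0
        )
        report["scored"].append("dispersion")
    else:
        report["missing"].append("dispersion")
    if "category_means" in results:
        cm = results["category_means"]
        report["category_order_recovered"] = bool(
            cm["conspecific"] < cm["dyad"] < cm["unrelated"]
        )
        report["scored"].append("categories")
    else:
        report["missing"].append("categories")
    if report["missing"]:
        import logging

        logging.getLogger("wilddom").warning(
            "score_recovery: stages missing from results: %s", report["missing"]
        )
    return report


# ---------------------------------------------------------------------------
# serialisation for the CLI
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    from . import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_count_table(dataset.counts, out / "counts.tsv", layout="otu")
    io.write_metadata(dataset.metadata.reset_index(drop=True), out / "metadata.tsv")
    io.write_dyad_table(dataset.dyads.reset_index(drop=True), out / "dyads.tsv")
    io.write_tree(dataset.tree, out / "tree.nwk")
    io.write_pathogen_list(dataset.pathogens, out / "pathogens.txt")
    if dataset.host_divergence is not None:
        io.write_distance_matrix(dataset.host_divergence, out / "host_divergence.tsv")
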