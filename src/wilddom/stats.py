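"""Permutational and rank-based inference for community dissimilarities.

The comparative design has two non-standard inferential needs that ordinary
library routines do not cover:

* **Restricted-permutation PERMANOVA.** Domestication status is nested
  within the species dyad, so status labels are only exchangeable *within*
  a dyad. The sequential (Type I) distance-based partitioning is computed
  from the Gower-centered dissimilarity matrix and the null distribution is
  built by permuting samples within dyad strata.

* **Stratified bootstrap for pairwise dissimilarities.** Dissimilarity
  values that share an individual are not independent. Following the
  study's resampling scheme (25,000 resamples stratified by individual
  identity), the resampling unit is the individual: individuals are drawn
  with replacement within their stratum and the Mann-Whitney U statistic is
  recomputed on the dissimilarity pairs induced by each resample.

Rank tests (Mann-Whitney, one-sample Wilcoxon, Kruskal-Wallis, Spearman)
wrap scipy.stats; the mixed-model likelihood-ratio test wraps statsmodels
MixedLM fit by maximum likelihood. All permutation p-values satisfy
p >= 1/(n_permutations + 1).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata
from skbio import DistanceMatrix

from .datasets import ValidationError

logger = logging.getLogger("wilddom")


@dataclass
class TestResult:
    """Uniform return type of every inferential procedure."""

    method: str
    statistic: float
    p_value: float
    effect_size: float | None = None
    df: float | None = None
    n: int | tuple | None = None
    n_permutations: int | None = None
    n_bootstrap: int | None = None
    seed: int | None = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "effect_size": self.effect_size,
            "df": self.df,
            "n": self.n,
            "n_permutations": self.n_permutations,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
        }
        out.update(self.notes)
        return out


@dataclass(frozen=True)
class PermutationScheme:
    """Free or within-strata sample permutations."""

    type: str = "free"  # {"free", "within_strata"}
    strata: pd.Series | None = None  # sample -> stratum
    n_permutations: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.type not in {"free", "within_strata"}:
            raise ValidationError(f"unknown permutation scheme {self.type!r}")
        if self.type == "within_strata" and self.strata is None:
            raise ValidationError("within_strata scheme requires a strata map")


def _strata_indices(sample_ids: list[str], scheme: PermutationScheme) -> list[np.ndarray]:
    if scheme.type == "free":
        return [np.arange(len(sample_ids))]
    strata = scheme.strata.reindex(sample_ids)
    if strata.isna().any():
        missing = [s for s, v in strata.items() if pd.isna(v)]
        raise ValidationError(f"strata map does not cover samples: {missing}")
    blocks = []
    for _, idx in pd.Series(np.arange(len(sample_ids)), index=sample_ids).groupby(strata):
        block = idx.to_numpy()
        if len(block) == 1:
            logger.warning("stratum with a single sample contributes no permutations")
        blocks.append(block)
    return blocks


def _draw_permutation(rng: np.random.Generator, n: int, blocks: list[np.ndarray]) -> np.ndarray:
    perm = np.arange(n)
    for block in blocks:
        perm[block] = rng.permutation(block)
    return perm


def _enumerate_permutations(n: int, blocks: list[np.ndarray]) -> list[np.ndarray]:
    """All distinct permutations respecting strata (exhaustive null)."""
    per_block = [list(itertools.permutations(block)) for block in blocks]
    perms = []
    for combo in itertools.product(*per_block):
        perm = np.arange(n)
        for block, arrangement in zip(blocks, combo):
            perm[block] = arrangement
        perms.append(perm)
    return perms


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _gower_center(dm: DistanceMatrix) -> np.ndarray:
    a = -0.5 * dm.data.astype(float) ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()

def _hat_matrix(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def permanova(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: list[str],
    scheme: PermutationScheme | None = None,
    exhaustive: bool = False,
) -> list[TestResult]:
    """Sequential (Type I) distance-based multivariate ANOVA.

    Terms are fitted in the given order; each term's sum of squares is the
    increment in explained SS of the Gower-centered matrix, R^2 = SS/SS_total,
    and pseudo-F uses the residual mean square of the full model. The null
    distribution permutes samples freely or within strata. A final pseudo-
    result labelled ``Residual`` carries the residual R^2 so R^2 sums to 1.
    """
    scheme = scheme or PermutationScheme()
    ids = [str(i) for i in dm.ids]
    meta = metadata.reindex(ids)
    n = len(ids)
    g = _gower_center(dm)
    ss_total = float(np.trace(g))

    hats = [np.full((n, n), 1.0 / n)]  # intercept-only hat matrix
    x = np.ones((n, 1))
    ranks = [1]
    for term in terms:
        levels = meta[term].astype(str)
        if levels.nunique() < 2:
            raise ValidationError(f"term {term!r} is constant among included samples")
        dummies = pd.get_dummies(levels, drop_first=False).to_numpy(dtype=float)
        x = np.hstack([x, dummies])
        hats.append(_hat_matrix(x))
        ranks.append(int(np.linalg.matrix_rank(x)))
    df_terms = [ranks[i + 1] - ranks[i] for i in range(len(terms))]
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValidationError("model saturates the samples; no residual df")

    contrasts = [hats[i + 1] - hats[i] for i in range(len(terms))]
    residual_proj = np.eye(n) - hats[-1]

    def term_stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float((c * gmat).sum()) for c in contrasts])
        ss_res = float((residual_proj * gmat).sum())
        return ss, ss_res

    ss_obs, ss_res_obs = term_stats(g)
    ms_res = ss_res_obs / df_res
    f_obs = (ss_obs / np.array(df_terms)) / ms_res

    blocks = _strata_indices(ids, scheme)
    # ties with the observed F (e.g. permutations preserving the grouping)
    # must count as exceedances despite float summation jitter
    tol = 1e-8 * np.maximum(1.0, np.abs(f_obs))
    if exhaustive:
        perms = _enumerate_permutations(n, blocks)
        n_perm = len(perms) - 1
        exceed = np.zeros(len(terms))
        for perm in perms:
            gp = g[np.ix_(perm, perm)]
            ss_p, ss_res_p = term_stats(gp)
            f_p = (ss_p / np.array(df_terms)) / (ss_res_p / df_res)
            exceed += f_p >= f_obs - tol
        p_values = exceed / len(perms)
    else:
        rng = np.random.default_rng(scheme.seed)
        n_perm = scheme.n_permutations
        exceed = np.ones(len(terms))  # the observed ordering counts
        for _ in range(n_perm):
            perm = _draw_permutation(rng, n, blocks)
            gp = g[np.ix_(perm, perm)]
            ss_p, ss_res_p = term_stats(gp)
            f_p = (ss_p / np.array(df_terms)) / (ss_res_p / df_res)
            exceed += f_p >= f_obs - tol
        p_values = exceed / (n_perm + 1)

    results = []
    for i, term in enumerate(terms):
        results.append(
            TestResult(
                method="permanova",
                statistic=float(f_obs[i]),
                effect_size=float(ss_obs[i] / ss_total),
                p_value=float(p_values[i]),
                df=df_terms[i],
                n=n,
                n_permutations=n_perm,
                seed=scheme.seed,
                notes={"term": term, "ss": float(ss_obs[i]), "scheme": scheme.type},
            )
        )
    results.append(
        TestResult(
            method="permanova",
            statistic=float("nan"),
            effect_size=float(ss_res_obs / ss_total),
            p_value=float("nan"),
            df=df_res,
            n=n,
            notes={"term": "Residual", "ss": float(ss_res_obs), "ss_total": ss_total},
        )
    )
    return results


# ---------------------------------------------------------------------------
# multivariate dispersion (betadisper-style)
# ---------------------------------------------------------------------------

def _pcoa_embedding(dm: DistanceMatrix) -> np.ndarray:
    """Positive-eigenvalue PCoA coordinates of all samples."""
    g = _gower_center(dm)
    eigvals, eigvecs = np.linalg.eigh(g)
    keep = eigvals > 1e-9
    return eigvecs[:, keep] * np.sqrt(eigvals[keep])


def _centroid_distances(coords: np.ndarray, codes: np.ndarray, k: int) -> np.ndarray:
    out = np.empty(len(codes))
    for level in range(k):
        mask = codes == level
        centroid = coords[mask].mean(axis=0)
        out[mask] = np.linalg.norm(coords[mask] - centroid, axis=1)
    return out


def distances_to_centroid(dm: DistanceMatrix, groups: pd.Series) -> pd.Series:
    """Per-sample distance to its group centroid in positive-axis PCoA space."""
    ids = [str(i) for i in dm.ids]
    labels = groups.reindex(ids)
    codes = pd.Categorical(labels).codes.astype(np.int64)
    coords = _pcoa_embedding(dm)
    out = _centroid_distances(coords, codes, codes.max() + 1)
    return pd.Series(out, index=ids, name="dist_to_centroid")


def dispersion_test(
    dm: DistanceMatrix,
    groups: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
    contrast_groups: pd.Series | None = None,
) -> TestResult:
    """Permutation F-test for homogeneity of multivariate dispersions.

    Distances to group centroids are computed once in the PCoA embedding
    (positive eigenvalue axes); the one-way F on those distances is compared
    with its distribution under permutation of the group labels.

    When ``contrast_groups`` is given, centroids are those of ``groups``
    (e.g. host species) but the F contrasts ``contrast_groups`` (e.g.
    domestication status), so between-conspecific variability can be
    compared across a coarser factor.
    """
    ids = [str(i) for i in dm.ids]
    centroid_labels = groups.reindex(ids).astype(str)
    counts = centroid_labels.value_counts()
    if len(counts) < 2:
        raise ValidationError("dispersion test needs at least two groups")
    if (counts < 2).any():
        raise ValidationError("every group needs at least two samples")
    coords = _pcoa_embedding(dm)
    centroid_codes = pd.Categorical(centroid_labels).codes.astype(np.int64)
    n_centroid_groups = centroid_codes.max() + 1
    dists = _centroid_distances(coords, centroid_codes, n_centroid_groups)

    if contrast_groups is not None:
        labels = contrast_groups.reindex(ids).astype(str)
        counts = labels.value_counts()
        if len(counts) < 2 or (counts < 2).any():
            raise ValidationError("contrast groups need >= 2 groups of >= 2 samples")
    else:
        labels = centroid_labels
    codes = pd.Categorical(labels).codes.astype(np.int64)
    k = codes.max() + 1

    def one_way_f(values: np.ndarray, assignment: np.ndarray) -> float:
        grand = values.mean()
        ss_between = ss_within = 0.0
        for level in range(k):
            grp = values[assignment == level]
            ss_between += len(grp) * (grp.mean() - grand) ** 2
            ss_within += ((grp - grp.mean()) ** 2).sum()
        df1, df2 = k - 1, len(values) - k
        if ss_within == 0:
            return np.inf
        return (ss_between / df1) / (ss_within / df2)

    f_obs = one_way_f(dists, codes)
    rng = np.random.default_rng(seed)
    exceed = 1
    for _ in range(n_permutations):
        perm = rng.permutation(len(ids))
        if contrast_groups is None:
            # relabel samples and re-estimate centroids under the permuted
            # grouping, so centroid-estimation noise enters the null
            perm_codes = codes[perm]
            perm_dists = _centroid_distances(coords, perm_codes, k)
            f_perm = one_way_f(perm_dists, perm_codes)
        else:
            # centroid structure (e.g. host species) is a fixed nuisance;
            # only the contrast labels are exchangeable
            f_perm = one_way_f(dists, codes[perm])
        exceed += f_perm >= f_obs
    p = exceed / (n_permutations + 1)
    return TestResult(
        method="dispersion_permutation_f",
        statistic=float(f_obs),
        effect_size=float(f_obs),
        p_value=float(p),
        df=(k - 1, len(ids) - k),
        n=len(ids),
        n_permutations=n_permutations,
        seed=seed,
        notes={"group_mean_dispersion": {str(level): float(dists[codes == i].mean())
                                         for i, level in enumerate(pd.Categorical(labels).categories)}},
    )


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    correlation: str = "pearson",
    n_permutations: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> TestResult:
    """Mantel correlation between two distance matrices over matching ids."""
    if list(d1.ids) != list(d2.ids):
        if set(d1.ids) != set(d2.ids):
            raise ValidationError("mantel: distance matrices cover different ids")
        d2 = d2.filter(d1.ids)
    n = len(d1.ids)
    iu = np.triu_indices(n, k=1)
    x = d1.data[iu]
    m2 = d2.data.astype(float)

    if correlation == "spearman":
        def corr(v1, v2):
            return float(sps.spearmanr(v1, v2).statistic)
    elif correlation == "pearson":
        def corr(v1, v2):
            return float(np.corrcoef(v1, v2)[0, 1])
    else:
        raise ValidationError(f"unknown correlation {correlation!r}")

    r_obs = corr(x, m2[iu])
    if exhaustive:
        perms = list(itertools.permutations(range(n)))
        exceed = sum(
            abs(corr(x, m2[np.ix_(p, p)][iu])) >= abs(r_obs) - 1e-12 for p in perms
        )
        n_perm = len(perms) - 1
        p_value = exceed / len(perms)
    else:
        rng = np.random.default_rng(seed)
        exceed = 1
        for _ in range(n_permutations):
            p = rng.permutation(n)
            exceed += abs(corr(x, m2[np.ix_(p, p)][iu])) >= abs(r_obs)
        n_perm = n_permutations
        p_value = exceed / (n_permutations + 1)
    return TestResult(
        method=f"mantel_{correlation}",
        statistic=r_obs,
        effect_size=r_obs,
        p_value=float(p_value),
        n=n,
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rank tests (scipy wrappers)
# ---------------------------------------------------------------------------

def mann_whitney(x, y, alternative: str = "two-sided") -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("mann_whitney requires non-empty samples")
    if np.ptp(np.concatenate([x, y])) == 0:  # every value identical
        return TestResult(
            method="mann_whitney_u",
            statistic=len(x) * len(y) / 2,
            p_value=1.0,
            n=(len(x), len(y)),
            notes={"alternative": alternative, "degenerate": True},
        )
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 12 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return TestResult(
        method="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(len(x), len(y)),
        notes={"alternative": alternative, "approximation": method},
    )


def wilcoxon_one_sample(x, mu0: float = 0.0, alternative: str = "two-sided") -> TestResult:
    x = np.asarray(x, dtype=float) - mu0
    nonzero = x[x != 0]
    if len(nonzero) == 0:
        logger.warning("all values equal mu0; Wilcoxon p set to 1")
        return TestResult(method="wilcoxon_signed_rank", statistic=0.0, p_value=1.0, n=0)
    ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if (len(nonzero) <= 15 and not ties) else "approx"
    res = sps.wilcoxon(nonzero, alternative=alternative, method=method)
    return TestResult(
        method="wilcoxon_signed_rank",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(nonzero),
        notes={"alternative": alternative, "approximation": method},
    )


def _partitions(indices: list[int], sizes: list[int]):
    """Distinct assignments of indices into ordered groups of given sizes."""
    if len(sizes) == 1:
        yield (tuple(indices),)
        return
    for combo in itertools.combinations(indices, sizes[0]):
        rest = [i for i in indices if i not in combo]
        for tail in _partitions(rest, sizes[1:]):
            yield (combo,) + tail


def kruskal_wallis(groups: list, exact: bool = False) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square reference.

    ``exact=True`` replaces the asymptotic p with full enumeration of all
    distinct assignments of the pooled values to the group sizes (tie-free
    pooled n <= 10 recommended).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValidationError("kruskal_wallis: empty group")
    if np.ptp(np.concatenate(groups)) == 0:
        return TestResult(
            method="kruskal_wallis", statistic=0.0, p_value=1.0,
            df=len(groups) - 1, n=tuple(len(g) for g in groups),
            notes={"degenerate": True},
        )
    stat, p = sps.kruskal(*groups)
    notes = {}
    if exact:
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        exceed = total = 0
        for assignment in _partitions(list(range(len(pooled))), sizes):
            h, _ = sps.kruskal(*[pooled[list(idx)] for idx in assignment])
            exceed += h >= stat - 1e-10
            total += 1
        p = exceed / total
        notes["p_exact_enumeration"] = True
    return TestResult(
        method="kruskal_wallis",
        statistic=float(stat),
        p_value=float(p),
        df=len(groups) - 1,
        n=tuple(len(g) for g in groups),
        notes=notes,
    )


def spearman(x, y) -> TestResult:
    res = sps.spearmanr(x, y)
    return TestResult(
        method="spearman",
        statistic=float(res.statistic),
        effect_size=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(np.asarray(x)),
    )


# ---------------------------------------------------------------------------
# stratified bootstrap over individuals
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x over y via midranks (tie-aware)."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2)


class _PairDesign:
    """Pairs of individuals with values and groups, coded for fast resampling."""

    def __init__(self, pairs: pd.DataFrame, individual_strata: pd.Series | None):
        required = {"value", "ind_a", "ind_b", "group"}
        if not required <= set(pairs.columns):
            raise ValidationError(f"pairs frame needs columns {sorted(required)}")
        pairs = pairs.reset_index(drop=True)
        individuals = pd.Index(pd.unique(pd.concat([pairs["ind_a"], pairs["ind_b"]])))
        self.values = pairs["value"].to_numpy(dtype=float)
        self.a_codes = individuals.get_indexer(pairs["ind_a"])
        self.b_codes = individuals.get_indexer(pairs["ind_b"])
        if (self.a_codes == self.b_codes).any():
            raise ValidationError("a pair maps both sides to the same individual")
        self.group_levels = sorted(pairs["group"].unique())
        self.group_codes = pd.Categorical(
            pairs["group"], categories=self.group_levels
        ).codes.astype(np.int64)
        self.n_individuals = len(individuals)

        if individual_strata is not None:
            strata = individual_strata.reindex(individuals)
            orphan = strata[strata.isna()].index.tolist()
            if orphan:
                raise ValidationError(f"individuals without a stratum: {orphan}")
        else:
            # default stratum: the set of comparison groups an individual's pairs span
            membership: dict[object, set] = {i: set() for i in individuals}
            for a, b, grp in zip(pairs["ind_a"], pairs["ind_b"], pairs["group"]):
                membership[a].add(grp)
                membership[b].add(grp)
            strata = pd.Series(
                {i: "|".join(sorted(map(str, g))) for i, g in membership.items()}
            ).reindex(individuals)
        self.strata_blocks = [
            individuals.get_indexer(sub.index) for _, sub in strata.groupby(strata)
        ]
        # pairs-per-individual; where every individual of a stratum appears in
        # exactly one pair the pairs themselves are the independent units, and
        # resampling individuals would only inflate the replicate variance —
        # such strata are bootstrapped at the pair level instead
        appearances = np.bincount(self.a_codes, minlength=self.n_individuals)
        appearances += np.bincount(self.b_codes, minlength=self.n_individuals)
        self.block_pair_rows: list[np.ndarray | None] = []
        for block in self.strata_blocks:
            if appearances[block].max() <= 1:
                members = set(block.tolist())
                rows = np.where(
                    [a in members or b in members for a, b in zip(self.a_codes, self.b_codes)]
                )[0]
                self.block_pair_rows.append(rows)
            else:
                self.block_pair_rows.append(None)

    def resample_multiplicity(self, rng: np.random.Generator) -> np.ndarray:
        """Pair multiplicities induced by resampling units within strata.

        The unit is the individual (pair multiplicity = product of the two
        endpoint counts); in strata whose individuals each appear in a single
        pair, the unit degenerates to the pair and pairs are drawn directly.
        """
        counts = np.zeros(self.n_individuals, dtype=np.int64)
        mult = np.zeros(len(self.values), dtype=np.int64)
        product_strata = False
        for block, pair_rows in zip(self.strata_blocks, self.block_pair_rows):
            if pair_rows is not None:
                if len(pair_rows):
                    draw = rng.choice(pair_rows, size=len(pair_rows), replace=True)
                    mult += np.bincount(draw, minlength=len(self.values))
            else:
                product_strata = True
                # n-1 draws: the standard cluster-bootstrap correction for
                # the (n-1)/n variance shrinkage of the naive n-of-n draw
                m = max(len(block) - 1, 1)
                draw = rng.choice(block, size=m, replace=True)
                counts += np.bincount(draw, minlength=self.n_individuals)
        if product_strata:
            product = counts[self.a_codes] * counts[self.b_codes]
            # only pairs whose both endpoints live in individual-resampled strata
            pair_level = np.zeros(len(self.values), dtype=bool)
            for pair_rows in self.block_pair_rows:
                if pair_rows is not None and len(pair_rows):
                    pair_level[pair_rows] = True
            mult += np.where(pair_level, 0, product)
        return mult


def stratified_bootstrap_mwu(
    pairs: pd.DataFrame,
    n_bootstrap: int = 25_000,
    seed: int = 0,
    individual_strata: pd.Series | None = None,
) -> TestResult:
    """Dependence-robust Mann-Whitney contrast of two groups of pairwise values.

    ``pairs`` has one row per unordered sample pair with columns ``value``
    (the dissimilarity), ``ind_a``/``ind_b`` (the two individuals behind the
    pair) and ``group`` (which of the two comparison groups the pair belongs
    to). Individuals — the exchangeable units — are resampled with
    replacement within their stratum; each replicate recomputes U on the
    induced pair multiset. Two-sided p: twice the smaller tail fraction of
    replicates whose centered statistic U - n1 n2 / 2 falls on either side
    of zero, floored at 1/(B+1). A percentile interval of the centered U is
    reported in ``notes`` alongside.
    """
    design = _PairDesign(pairs, individual_strata)
    group_levels = design.group_levels
    if len(group_levels) != 2:
        raise ValidationError(f"need exactly two pair groups, got {group_levels}")
    values = design.values
    is_g1 = design.group_codes == 0
    x_obs, y_obs = values[is_g1], values[~is_g1]
    u_obs = _u_statistic(x_obs, y_obs)
    center_obs = len(x_obs) * len(y_obs) / 2

    rng = np.random.default_rng(seed)
    centered = np.empty(n_bootstrap)
    attempts = 0
    b = 0
    max_attempts = 10 * n_bootstrap
    while b < n_bootstrap:
        attempts += 1
        if attempts > max_attempts:
            raise ValidationError("too many degenerate bootstrap replicates")
        mult = design.resample_multiplicity(rng)
        n1 = int(mult[is_g1].sum())
        n2 = int(mult[~is_g1].sum())
        if n1 == 0 or n2 == 0:
            continue
        rep_values = np.repeat(values, mult)
        rep_g1 = np.repeat(is_g1, mult)
        u_b = _u_statistic(rep_values[rep_g1], rep_values[~rep_g1])
        centered[b] = u_b - n1 * n2 / 2
        b += 1

    lower = float(np.mean(centered <= 0))
    upper = float(np.mean(centered >= 0))
    p = min(1.0, max(2 * min(lower, upper), 1.0 / (n_bootstrap + 1)))
    ci = np.percentile(centered, [2.5, 97.5])
    return TestResult(
        method="stratified_bootstrap_mwu",
        statistic=u_obs,
        effect_size=float(u_obs - center_obs),
        p_value=p,
        n=(len(x_obs), len(y_obs)),
        n_bootstrap=n_bootstrap,
        seed=seed,
        notes={
            "groups": group_levels,
            "centered_u_ci": [float(ci[0]), float(ci[1])],
            "redrawn_replicates": attempts - n_bootstrap,
        },
    )


def stratified_bootstrap_kruskal(
    pairs: pd.DataFrame,
    n_bootstrap: int = 25_000,
    seed: int = 0,
    individual_strata: pd.Series | None = None,
) -> TestResult:
    """Individual-stratified bootstrap of the Kruskal-Wallis H across >=3 pair groups.

    One-sided crossing p: the fraction of replicates whose H falls at or
    below the median of the chi-square(k-1) null reference, floored at
    1/(B+1). This is a heuristic omnibus analogue of the two-group bootstrap.
    """
    design = _PairDesign(pairs, individual_strata)
    group_levels = design.group_levels
    k = len(group_levels)
    if k < 3:
        raise ValidationError("use stratified_bootstrap_mwu for two groups")
    values = design.values
    group_codes = design.group_codes

    h_obs, _ = sps.kruskal(*[values[group_codes == i] for i in range(k)])
    null_median = sps.chi2.median(df=k - 1)

    rng = np.random.default_rng(seed)
    h_boot = np.empty(n_bootstrap)
    attempts = b = 0
    while b < n_bootstrap:
        attempts += 1
        if attempts > 10 * n_bootstrap:
            raise ValidationError("too many degenerate bootstrap replicates")
        mult = design.resample_multiplicity(rng)
        rep_values = np.repeat(values, mult)
        rep_codes = np.repeat(group_codes, mult)
        if len(np.unique(rep_codes)) < k or np.ptp(rep_values) == 0:
            continue
        h_boot[b], _ = sps.kruskal(*[rep_values[rep_codes == i] for i in range(k)])
        b += 1
    p = max(float(np.mean(h_boot <= null_median)), 1.0 / (n_bootstrap + 1))
    return TestResult(
        method="stratified_bootstrap_kruskal",
        statistic=float(h_obs),
        p_value=min(1.0, p),
        df=k - 1,
        n=tuple(int((group_codes == i).sum()) for i in range(k)),
        n_bootstrap=n_bootstrap,
        seed=seed,
        notes={"groups": group_levels},
    )


# ---------------------------------------------------------------------------
# mixed-model likelihood-ratio test
# ---------------------------------------------------------------------------

def lmm_lrt(
    data: pd.DataFrame,
    response: str,
    fixed_full: list[str],
    fixed_null: list[str],
    group: str,
) -> TestResult:
    """Likelihood-ratio test between nested mixed models with a random intercept.

    Both models are fit by maximum likelihood (not REML, since the fixed
    effects differ); the LRT statistic is referred to chi-square with df =
    difference in fixed-effect parameter count.
    """
    import statsmodels.formula.api as smf

    def fit(terms: list[str]):
        rhs = " + ".join(terms) if terms else "1"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(f"{response} ~ {rhs}", data, groups=data[group])
            # lbfgs occasionally diverges on boundary fits; fall back
            for method in ("lbfgs", "bfgs", "powell", "nm"):
                try:
                    result = model.fit(reml=False, method=method)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if np.isfinite(result.llf):
                    return result
            raise ValidationError("mixed-model fit failed with every optimizer")

    full = fit(fixed_full)
    null = fit(fixed_null)
    stat = 2.0 * (full.llf - null.llf)
    df = int(full.df_modelwc - null.df_modelwc)
    if df <= 0:
        raise ValidationError("full model must add parameters over the null")
    stat = max(stat, 0.0)
    p = float(sps.chi2.sf(stat, df))
    flagged = bool(getattr(full, "converged", True) is False)
    if flagged:
        logger.warning("lmm_lrt: full model did not converge cleanly")
    return TestResult(
        method="lmm_likelihood_ratio",
        statistic=float(stat),
        p_value=p,
        df=df,
        n=len(data),
        notes={"fixed_full": fixed_full, "fixed_null": fixed_null, "flagged": flagged},
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p) elementwise."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values outside [0, 1]")
    m = m if m is not None else p.size
    return np.minimum(1.0, m * p)
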