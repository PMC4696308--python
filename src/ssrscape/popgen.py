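"""Haplotypic population genetics for category-labelled microsatellite loci.

Individuals are haploid multilocus genotypes (one integer allele size per
locus); each multilocus genotype is treated as a haplotype.  Genetic
distance between two individuals is the number of loci at which their
alleles differ, which for AMOVA purposes is used directly as the squared
distance (it is the sum over loci of per-locus 0/1 distances).

The hierarchical AMOVA partitions total variance into three strata:
among species (sigma_a^2), among populations within species (sigma_b^2),
and among genotypes within populations (sigma_c^2), with the fixation
indices

    Phi_CT = sigma_a^2 / sigma_total^2
    Phi_SC = sigma_b^2 / (sigma_b^2 + sigma_c^2)
    Phi_ST = (sigma_a^2 + sigma_b^2) / sigma_total^2

Significance is assessed by permutation: individuals among all
populations for Phi_ST, individuals among populations within species for
Phi_SC, and whole populations among species for Phi_CT.  Gene flow is
derived from per-locus Fst through the island-model relation
Fst = 1 / (4 Nm + 1).
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenotypeMatrix",
    "AmovaResult",
    "PCoAResult",
    "allele_stats",
    "allele_summary",
    "pairwise_distances",
    "amova",
    "fst_to_2nm",
    "pcoa",
    "per_locus_stats",
    "category_variance_test",
    "letter_groups",
]

LOCUS_CATEGORIES = ("OUT", "UP", "IN", "DOWN")


@dataclasses.dataclass
class GenotypeMatrix:
    """Haploid individuals x loci allele-size table with hierarchy labels.

    ``alleles`` holds integer allele sizes (bp) with NaN for missing data;
    its index is the individual id.  ``population`` and ``species`` map
    individual id to labels; ``locus_category`` maps locus id to one of
    OUT / UP / IN / DOWN (upstream-distal, upstream-proximal, exonic,
    downstream-proximal loci).
    """

    alleles: pd.DataFrame
    population: pd.Series
    species: pd.Series
    locus_category: pd.Series

    def __post_init__(self) -> None:
        self.alleles = self.alleles.astype(float)
        self.population = self.population.reindex(self.alleles.index)
        self.species = self.species.reindex(self.alleles.index)
        self.locus_category = self.locus_category.reindex(self.alleles.columns)
        if self.population.isna().any() or self.species.isna().any():
            raise ValueError("every individual needs a population and species label")
        pop_species = self.species.groupby(self.population).nunique()
        if (pop_species > 1).any():
            bad = pop_species[pop_species > 1].index.tolist()
            raise ValueError(f"populations spanning several species: {bad}")
        if self.population.nunique() < 2:
            raise ValueError("need at least two populations")

    @property
    def individuals(self) -> pd.Index:
        return self.alleles.index

    @property
    def loci(self) -> pd.Index:
        return self.alleles.columns

    def loci_in_category(self, category: str) -> list[str]:
        if category not in LOCUS_CATEGORIES:
            raise ValueError(
                f"unknown locus category {category!r}; valid: {LOCUS_CATEGORIES}")
        return [l for l in self.loci if self.locus_category[l] == category]

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.alleles[list(loci)], self.population,
                              self.species, self.locus_category.loc[list(loci)])

    # ---- TSV round trip ------------------------------------------------
    @classmethod
    def from_tsv(cls, genotype_path: str | Path, locus_meta_path: str | Path
                 ) -> "GenotypeMatrix":
        """Read the genotype dialect: individual_id, population, species,
        then one column per locus; blank cells are missing alleles.
        Locus metadata TSV must contain locus_id and category columns."""
        geno = pd.read_csv(genotype_path, sep="\t", dtype={"individual_id": str})
        geno = geno.set_index("individual_id")
        population = geno.pop("population")
        species = geno.pop("species")
        meta = pd.read_csv(locus_meta_path, sep="\t", dtype={"locus_id": str})
        category = meta.set_index("locus_id")["category"]
        return cls(geno, population, species, category)

    def to_tsv(self, genotype_path: str | Path, locus_meta_path: str | Path) -> None:
        out = self.alleles.copy()
        out.insert(0, "species", self.species)
        out.insert(0, "population", self.population)
        out.index.name = "individual_id"
        with open(genotype_path, "w") as fh:
            fh.write(out.to_csv(sep="\t", na_rep=""))
        meta = pd.DataFrame({"locus_id": self.loci,
                             "category": self.locus_category.values})
        meta.to_csv(locus_meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# allelic diversity


def allele_stats(g: GenotypeMatrix, grouping: str = "population") -> pd.DataFrame:
    """Per-locus, per-group allele counts.

    Returns a table indexed by (locus, group) with Na (number of distinct
    alleles), Ne (effective number of alleles, ``1 / sum p_i^2``), and the
    species-level private and shared allele counts for the group's species.
    Missing alleles are excluded from frequencies; a group with no scored
    individual at a locus gets NaN, not zero.
    """
    if grouping not in ("population", "species"):
        raise ValueError("grouping must be 'population' or 'species'")
    labels = g.population if grouping == "population" else g.species
    # species-level allele sets for private/shared classification
    species_alleles: dict[str, dict[str, set]] = {}
    for sp in g.species.unique():
        members = g.alleles.loc[g.species == sp]
        species_alleles[sp] = {
            locus: set(members[locus].dropna().tolist()) for locus in g.loci}
    all_species = list(species_alleles)
    rows = []
    for group in labels.unique():
        members = g.alleles.loc[labels == group]
        group_species = (group if grouping == "species"
                         else g.species[labels == group].iloc[0])
        for locus in g.loci:
            vals = members[locus].dropna()
            if len(vals) == 0:
                rows.append({"locus": locus, "group": group, "species": group_species,
                             "n": 0, "na": np.nan, "ne": np.nan,
                             "private": np.nan, "shared": np.nan})
                continue
            freqs = vals.value_counts(normalize=True).to_numpy()
            own = species_alleles[group_species][locus]
            others = set().union(*(species_alleles[sp][locus]
                                   for sp in all_species if sp != group_species))
            rows.append({
                "locus": locus, "group": group, "species": group_species,
                "n": len(vals),
                "na": float(len(freqs)),
                "ne": float(1.0 / np.sum(freqs**2)),
                "private": float(len(own - others)),
                "shared": float(len(own & others)),
            })
    return pd.DataFrame(rows).set_index(["locus", "group"])


def allele_summary(g: GenotypeMatrix) -> pd.DataFrame:
    """Allelic diversity summary per locus category and species.

    For each (category, species) cell: the mean and standard error across
    loci of Na and Ne (Na and Ne first averaged over the species'
    populations per locus) and of the species-level private and shared
    allele counts.
    """
    per_pop = allele_stats(g, grouping="population").reset_index()
    per_pop["category"] = per_pop["locus"].map(g.locus_category)
    by_locus = (per_pop.groupby(["category", "species", "locus"])
                [["na", "ne", "private", "shared"]].mean())
    agg = by_locus.groupby(["category", "species"]).agg(["mean", "sem"])
    agg.columns = [f"{stat}_{how}" for stat, how in agg.columns]
    return agg


# ---------------------------------------------------------------------------
# distances


def pairwise_distances(g: GenotypeMatrix, loci: Sequence[str] | None = None
                       ) -> pd.DataFrame:
    """Number of loci at which two individuals carry different alleles.

    Loci missing in either individual of a pair are skipped (pairwise
    deletion).  A pair with no co-scored locus is an error.
    """
    sub = g.alleles[list(loci)] if loci is not None else g.alleles
    a = sub.to_numpy(dtype=float)
    present = ~np.isnan(a)
    diff = (a[:, None, :] != a[None, :, :])
    both = present[:, None, :] & present[None, :, :]
    shared = both.sum(axis=2)
    if np.any(shared == 0):
        i, j = np.argwhere(shared == 0)[0]
        raise ValueError(
            f"individuals {sub.index[i]!r} and {sub.index[j]!r} share no scored locus")
    d = (diff & both).sum(axis=2)
    np.fill_diagonal(d, 0)
    return pd.DataFrame(d, index=sub.index, columns=sub.index)


# ---------------------------------------------------------------------------
# AMOVA


@dataclasses.dataclass
class AmovaResult:
    """Hierarchical AMOVA decomposition.

    ``table`` has one row per stratum (plus Total) with d.f., sum of
    squares, variance component and percentage of total variance.
    Phi-statistics are NaN when total variance is zero (all individuals
    identical), and reported as-is (possibly negative) otherwise.
    """

    table: pd.DataFrame
    phi_st: float
    phi_sc: float
    phi_ct: float
    p_values: dict[str, float]
    n_perm: int

    @property
    def variance_components(self) -> pd.Series:
        return self.table["variance"].drop("Total")

    @property
    def percentages(self) -> pd.Series:
        return self.table["pct"].drop("Total")


def _codes(labels: Sequence) -> np.ndarray:
    _, codes = np.unique(np.asarray(labels), return_inverse=True)
    return codes


def _group_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Sum over groups of (within-group pairwise squared distances) / size."""
    ss = 0.0
    for k in range(n_groups):
        idx = np.flatnonzero(codes == k)
        if idx.size:
            ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def _three_level(d2: np.ndarray, pop_codes: np.ndarray, grp_codes: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float, float]:
    """d.f., SS, variance components and Phi statistics for the
    species/population/genotype design; also used with permuted labels."""
    n = d2.shape[0]
    pops = np.unique(pop_codes)
    # species of each population (constant within population by contract)
    pop_grp = np.array([grp_codes[pop_codes == p][0] for p in pops])
    groups = np.unique(pop_grp)
    n_pop, n_grp = pops.size, groups.size

    ss_total = d2.sum() / (2.0 * n)
    ss_wp = _group_ss(d2, pop_codes, pop_codes.max() + 1)
    ss_wg = _group_ss(d2, grp_codes, grp_codes.max() + 1)
    ss_ag = ss_total - ss_wg          # among species
    ss_ap = ss_wg - ss_wp             # among populations within species

    df = np.array([n_grp - 1, n_pop - n_grp, n - n_pop], dtype=float)
    ss = np.array([ss_ag, ss_ap, ss_wp])

    pop_sizes = np.array([(pop_codes == p).sum() for p in pops], dtype=float)
    grp_sizes = np.array([(grp_codes == gidx).sum() for gidx in groups], dtype=float)
    sum_np2_over_ng = sum(
        (pop_sizes[pop_grp == gval] ** 2).sum() / grp_sizes[k]
        for k, gval in enumerate(groups))
    # unbalanced-design coefficients
    n_coef = ((n - sum_np2_over_ng) / df[1]) if df[1] > 0 else np.nan
    n1_coef = ((sum_np2_over_ng - (pop_sizes**2).sum() / n) / df[0]) if df[0] > 0 else np.nan
    n2_coef = ((n - (grp_sizes**2).sum() / n) / df[0]) if df[0] > 0 else np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        ms = np.where(df > 0, ss / df, np.nan)
    sigma_c = ms[2]
    sigma_b = (ms[1] - sigma_c) / n_coef if df[1] > 0 else 0.0
    sigma_a = (ms[0] - sigma_c - n1_coef * sigma_b) / n2_coef
    var = np.array([sigma_a, sigma_b, sigma_c])
    total = var.sum()
    if total == 0 or not np.isfinite(total):
        phi_ct = phi_sc = phi_st = math.nan
    else:
        phi_ct = sigma_a / total
        denom_sc = sigma_b + sigma_c
        phi_sc = sigma_b / denom_sc if denom_sc != 0 else math.nan
        phi_st = (sigma_a + sigma_b) / total
    return df, ss, var, phi_ct, phi_sc, phi_st


def _two_level(d2: np.ndarray, pop_codes: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    n = d2.shape[0]
    n_pop = np.unique(pop_codes).size
    ss_total = d2.sum() / (2.0 * n)
    ss_wp = _group_ss(d2, pop_codes, pop_codes.max() + 1)
    ss_ap = ss_total - ss_wp
    df = np.array([n_pop - 1, n - n_pop], dtype=float)
    ss = np.array([ss_ap, ss_wp])
    pop_sizes = np.bincount(pop_codes).astype(float)
    pop_sizes = pop_sizes[pop_sizes > 0]
    n_coef = (n - (pop_sizes**2).sum() / n) / df[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ms = np.where(df > 0, ss / df, np.nan)
    sigma_w = ms[1]
    sigma_a = (ms[0] - sigma_w) / n_coef
    var = np.array([sigma_a, sigma_w])
    total = var.sum()
    phi_st = var[0] / total if total != 0 and np.isfinite(total) else math.nan
    return df, ss, var, phi_st


def amova(g: GenotypeMatrix, loci: Sequence[str] | None = None,
          n_perm: int = 0, seed: int | None = None,
          levels: int = 3, truncate_negative: bool = False) -> AmovaResult:
    """Hierarchical analysis of molecular variance on haplotype distances.

    Parameters
    ----------
    g
        Genotype matrix; species define groups, populations subdivide them.
    loci
        Optional locus subset (e.g. one positional category).
    n_perm
        Number of permutations for the Phi significance tests (0 skips
        them).  p-values use the ``(count + 1) / (n_perm + 1)`` estimator.
    seed
        Seed for the permutation RNG; required when ``n_perm > 0``.
    levels
        3 for species/population/genotype, 2 for population/genotype
        (species ignored).
    truncate_negative
        Clamp negative variance components to zero before percentages and
        Phi statistics (off by default: negative estimates are reported
        as-is, following common AMOVA practice).
    """
    if n_perm > 0 and seed is None:
        raise ValueError("seed is required when permutations are requested")
    d2 = pairwise_distances(g, loci).to_numpy(dtype=float)
    n = d2.shape[0]
    pop_codes = _codes(g.population)
    grp_codes = _codes(g.species)
    if levels == 3 and np.unique(grp_codes).size < 2:
        raise ValueError("three-level design needs at least two species")

    rng = np.random.default_rng(seed)
    p_values: dict[str, float] = {}

    if levels == 3:
        df, ss, var, phi_ct, phi_sc, phi_st = _three_level(d2, pop_codes, grp_codes)
        strata = ["Among species", "Among populations within species",
                  "Among genotypes within populations"]
    elif levels == 2:
        df, ss, var, phi_st = _two_level(d2, pop_codes)
        phi_ct = phi_sc = math.nan
        strata = ["Among populations", "Among genotypes within populations"]
    else:
        raise ValueError("levels must be 2 or 3")

    if truncate_negative:
        var = np.maximum(var, 0.0)
        total = var.sum()
        if levels == 3:
            phi_ct = var[0] / total if total else math.nan
            phi_sc = var[1] / (var[1] + var[2]) if (var[1] + var[2]) else math.nan
            phi_st = (var[0] + var[1]) / total if total else math.nan
        else:
            phi_st = var[0] / var.sum() if var.sum() else math.nan

    if n_perm > 0 and np.isfinite(phi_st):
        if levels == 2:
            obs = phi_st
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(n)
                stat = _two_level(d2, pop_codes[perm])[3]
                if np.isfinite(stat) and stat >= obs - 1e-12:
                    count += 1
            p_values["phi_st"] = (count + 1) / (n_perm + 1)
        else:
            counts = {"phi_st": 0, "phi_sc": 0, "phi_ct": 0}
            pops = np.unique(pop_codes)
            pop_grp = np.array([grp_codes[pop_codes == p][0] for p in pops])
            for _ in range(n_perm):
                # Phi_ST: individuals among all populations
                perm = rng.permutation(n)
                stat = _three_level(d2, pop_codes[perm], grp_codes[perm])[5]
                if np.isfinite(stat) and stat >= phi_st - 1e-12:
                    counts["phi_st"] += 1
                # Phi_SC: individuals among populations within species
                permuted = np.arange(n)
                for gval in np.unique(grp_codes):
                    idx = np.flatnonzero(grp_codes == gval)
                    permuted[idx] = idx[rng.permutation(idx.size)]
                stat = _three_level(d2, pop_codes[permuted], grp_codes)[4]
                if np.isfinite(stat) and stat >= phi_sc - 1e-12:
                    counts["phi_sc"] += 1
                # Phi_CT: whole populations among species
                shuffled = pop_grp[rng.permutation(pop_grp.size)]
                new_grp = shuffled[np.searchsorted(pops, pop_codes)]
                stat = _three_level(d2, pop_codes, new_grp)[3]
                if np.isfinite(stat) and stat >= phi_ct - 1e-12:
                    counts["phi_ct"] += 1
            for key, cnt in counts.items():
                p_values[key] = (cnt + 1) / (n_perm + 1)

    total_var = var.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * var / total_var if total_var != 0 else np.full_like(var, np.nan)
    table = pd.DataFrame({
        "df": np.append(df, df.sum()),
        "ss": np.append(ss, ss.sum()),
        "variance": np.append(var, total_var),
        "pct": np.append(pct, np.nansum(pct) if total_var != 0 else np.nan),
    }, index=strata + ["Total"])
    return AmovaResult(table=table, phi_st=phi_st, phi_sc=phi_sc,
                       phi_ct=phi_ct, p_values=p_values, n_perm=n_perm)


# ---------------------------------------------------------------------------
# gene flow


def fst_to_2nm(fst: float) -> float:
    """Island-model gene flow 2Nm from Fst via Fst = 1 / (4 Nm + 1)."""
    if not np.isfinite(fst):
        raise ValueError("Fst must be finite")
    if fst <= 0:
        raise ValueError("Fst <= 0 implies unbounded gene flow; undefined")
    if fst > 1:
        raise ValueError("Fst cannot exceed 1")
    return (1.0 / fst - 1.0) / 2.0


# ---------------------------------------------------------------------------
# per-locus statistics


def per_locus_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus differentiation table.

    For each locus: the two-level Phi_ST across all populations (species
    grouping ignored) used as the per-locus Fst; gene flow 2Nm from that
    Fst; and the three-level variance percentages (among species, among
    populations within species, among genotypes within populations).
    Individuals missing at a locus are dropped for that locus.
    """
    rows = []
    for locus in g.loci:
        scored = g.alleles[locus].notna()
        keep = g.alleles.index[scored]
        sub = GenotypeMatrix(g.alleles.loc[keep, [locus]], g.population.loc[keep],
                             g.species.loc[keep], g.locus_category.loc[[locus]])
        two = amova(sub, levels=2)
        three = amova(sub, levels=3)
        fst = two.phi_st
        if np.isfinite(fst) and 0 < fst <= 1:
            nm2 = fst_to_2nm(fst)
        else:
            nm2 = np.nan
        pct = three.percentages
        rows.append({
            "locus": locus,
            "category": g.locus_category[locus],
            "fst": fst,
            "gene_flow_2nm": nm2,
            "pct_among_species": pct.iloc[0],
            "pct_among_populations": pct.iloc[1],
            "pct_within_populations": pct.iloc[2],
        })
    return pd.DataFrame(rows).set_index("locus")


# ---------------------------------------------------------------------------
# PCoA


@dataclasses.dataclass
class PCoAResult:
    coordinates: pd.DataFrame        # individuals x axes
    eigenvalues: np.ndarray          # positive eigenvalues, descending
    proportion_explained: np.ndarray


def pcoa(d: pd.DataFrame | np.ndarray, n_axes: int = 2,
         ids: Sequence[str] | None = None) -> PCoAResult:
    """Principal coordinates analysis of a distance matrix.

    The element-wise squared distances are Gower-centered
    (``B = -1/2 J D2 J`` with ``J = I - 11'/n``) and eigendecomposed;
    coordinates are eigenvectors scaled by the square root of their
    eigenvalue.  Axes with negative eigenvalues (non-Euclidean distances)
    are dropped with a warning; proportions explained are relative to the
    sum of positive eigenvalues.
    """
    if isinstance(d, pd.DataFrame):
        ids = list(d.index)
        mat = d.to_numpy(dtype=float)
    else:
        mat = np.asarray(d, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(mat.shape[0])]
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(mat), 0):
        raise ValueError("distance matrix must have a zero diagonal")
    n = mat.shape[0]
    d2 = mat**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-8 * max(abs(eigvals[0]), 1.0), 1e-12)
    positive = eigvals > tol
    if np.any(eigvals < -tol):
        warnings.warn("negative eigenvalues dropped (non-Euclidean distances)")
    eigvals_pos = eigvals[positive]
    vecs = eigvecs[:, positive]
    if n_axes > eigvals_pos.size:
        warnings.warn(f"only {eigvals_pos.size} positive axes available; truncated")
        n_axes = eigvals_pos.size
    coords = vecs[:, :n_axes] * np.sqrt(eigvals_pos[:n_axes])
    prop = eigvals_pos / eigvals_pos.sum() if eigvals_pos.size else eigvals_pos
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=pd.Index(ids, name="individual_id"),
                                 columns=[f"axis{i+1}" for i in range(n_axes)]),
        eigenvalues=eigvals_pos,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# variance comparison across locus categories


def category_variance_test(values_by_category: Mapping[str, Sequence[float]]
                           ) -> pd.DataFrame:
    """Pairwise two-sample variance-ratio F-tests between locus categories.

    For each pair of categories the statistic is the ratio of sample
    variances, larger over smaller, with a two-tailed p-value from the F
    distribution and Benjamini-Hochberg adjustment across pairs.
    """
    cats = {k: np.asarray(v, dtype=float) for k, v in values_by_category.items()}
    for name, vals in cats.items():
        if vals.size < 2:
            raise ValueError(f"category {name!r} needs at least two loci")
    rows = []
    for a, b in itertools.combinations(sorted(cats), 2):
        va, vb = np.var(cats[a], ddof=1), np.var(cats[b], ddof=1)
        if va == 0 and vb == 0:
            rows.append({"category_1": a, "category_2": b, "f": np.nan,
                         "df1": cats[a].size - 1, "df2": cats[b].size - 1,
                         "p_value": np.nan})
            continue
        if va >= vb:
            f, df1, df2 = va / vb if vb > 0 else np.inf, cats[a].size - 1, cats[b].size - 1
        else:
            f, df1, df2 = vb / va if va > 0 else np.inf, cats[b].size - 1, cats[a].size - 1
        p = min(1.0, 2.0 * float(stats.f.sf(f, df1, df2)))
        rows.append({"category_1": a, "category_2": b, "f": float(f),
                     "df1": df1, "df2": df2, "p_value": p})
    table = pd.DataFrame(rows)
    defined = table["p_value"].notna()
    table["p_adj"] = np.nan
    if defined.any():
        table.loc[defined, "p_adj"] = multipletests(
            table.loc[defined, "p_value"], method="fdr_bh")[1]
    return table


def letter_groups(categories: Sequence[str], pairwise: pd.DataFrame,
                  alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display from the pairwise variance-test table.

    Categories sharing a letter are not significantly different at the
    adjusted ``alpha``.  Letters come from the maximal cliques of the
    non-significance graph, assigned in category order.
    """
    cats = list(categories)
    nonsig = {frozenset((a, b)) for a, b in itertools.combinations(cats, 2)}
    for _, row in pairwise.iterrows():
        pair = frozenset((row["category_1"], row["category_2"]))
        if pd.notna(row["p_adj"]) and row["p_adj"] < alpha:
            nonsig.discard(pair)
    # maximal cliques by brute force (few categories)
    cliques = []
    for r in range(len(cats), 0, -1):
        for combo in itertools.combinations(cats, r):
            if all(frozenset(p) in nonsig for p in itertools.combinations(combo, 2)):
                if not any(set(combo) <= set(c) for c in cliques):
                    cliques.append(combo)
    letters = {c: "" for c in cats}
    for i, clique in enumerate(sorted(cliques, key=lambda c: [cats.index(x) for x in c])):
        symbol = chr(ord("a") + i)
        for c in clique:
            letters[c] += symbol
    return letters
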