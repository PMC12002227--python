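"""Phenotype-subgroup burden, clinical comparisons, and protein-region tests.

Covers: gene x phenotype meta-analysis with joint-local FDR over the whole
grid; two-sided Fisher 2x2 comparisons and Wilcoxon rank-sum tests for
clinical feature tables; a Monte-Carlo permutation test of non-random
gene-category / phenotype-category association; and enrichment of a variant
class (e.g. cysteine-altering missense) within protein regions such as EGF
domains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .case_control import fet_burden, fet_randp_vec
from .dnm import poisson_burden, poisson_randp
from .meta import BivariateMixtureFDR, fishers_method, jl_fdr, p_to_z, P_FLOOR
from .records import DAMAGING_CLASSES, InputError

__all__ = [
    "ProteinRegion",
    "feature_2x2",
    "rank_sum",
    "phenotype_permutation_test",
    "region_class_enrichment",
    "cysteine_altering",
    "subgroup_meta",
]


@dataclass
class ProteinRegion:
    """A protein region in 1-based inclusive residue coordinates."""

    gene: str
    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(f"region {self.name}: start > end")

    def contains(self, residue: int) -> bool:
        return self.start <= residue <= self.end


def feature_2x2(a: int, b: int, c: int, d: int) -> tuple[float, tuple[float, float]]:
    """Two-sided Fisher exact test on ``[[a, b], [c, d]]``.

    Uses the point-probability rule (sum over tables with fixed margins whose
    probability does not exceed the observed table's).  Returns the p-value
    and the two row proportions ``(a/(a+b), c/(c+d))``.
    """
    if min(a, b, c, d) < 0:
        raise InputError("cell counts must be non-negative")
    if a + b + c + d == 0:
        raise InputError("all-zero table")
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    prop1 = a / (a + b) if a + b else np.nan
    prop2 = c / (c + d) if c + d else np.nan
    return p, (prop1, prop2)


def rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact-distribution computation when both groups have at most 10 values
    and there are no ties; normal approximation with tie correction
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def phenotype_permutation_test(
    gene_labels, phenotype_labels, n_perm: int = 10_000, seed: int | None = None
) -> float:
    """Monte-Carlo test that phenotypes are non-randomly distributed over genes.

    The statistic is the Pearson chi-square of the gene-category x
    phenotype-category contingency table; phenotype labels are permuted
    across probands.  ``p = (1 + #{permuted >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise InputError("n_perm must be >= 100")
    gene_labels = np.asarray(gene_labels)
    phenotype_labels = np.asarray(phenotype_labels)
    if gene_labels.size != phenotype_labels.size:
        raise InputError("label vectors must be the same length")
    g_cats, g_idx = np.unique(gene_labels, return_inverse=True)
    p_cats, p_idx = np.unique(phenotype_labels, return_inverse=True)
    if g_cats.size < 2 or p_cats.size < 2:
        raise InputError("need at least two categories on each axis")

    def chi2_stat(pi: np.ndarray) -> float:
        table = np.zeros((g_cats.size, p_cats.size))
        np.add.at(table, (g_idx, pi), 1)
        row = table.sum(1, keepdims=True)
        col = table.sum(0, keepdims=True)
        expected = row @ col / table.sum()
        mask = expected > 0
        return float(((table - expected)[mask] ** 2 / expected[mask]).sum())

    observed = chi2_stat(p_idx)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if chi2_stat(rng.permutation(p_idx)) >= observed:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def cysteine_altering(aa_ref: str | None, aa_alt: str | None) -> bool:
    """True when a missense change introduces or removes exactly one cysteine."""
    if aa_ref is None or aa_alt is None:
        return False
    return (aa_ref == "C") != (aa_alt == "C")


_PREDICATES = {"cysteine-altering": cysteine_altering}


def region_class_enrichment(
    case_variants: pd.DataFrame,
    ctrl_variants: pd.DataFrame,
    regions: list[ProteinRegion],
    case_an: int,
    ctrl_an: int,
    predicate: str = "cysteine-altering",
) -> pd.DataFrame:
    """Per-region enrichment of predicate-positive alleles in cases vs controls.

    Variants without a protein position are skipped (counted in the
    ``n_skipped`` attribute of the returned frame).  A union row pools all
    regions.  Returns one row per region with predicate-positive case/control
    allele counts, the case/control frequency ratio, and the one-tailed
    Fisher p-value against the chromosome denominators.
    """
    try:
        pred = _PREDICATES[predicate]
    except KeyError:
        raise InputError(f"unknown predicate {predicate!r}") from None

    def _count(df: pd.DataFrame, region: ProteinRegion | None) -> tuple[int, int]:
        hits = skipped = 0
        for r in df.itertuples():
            ppos = getattr(r, "protein_pos", None)
            if ppos is None or (isinstance(ppos, float) and np.isnan(ppos)):
                skipped += 1
                continue
            in_region = (
                any(reg.contains(int(ppos)) for reg in regions)
                if region is None
                else region.contains(int(ppos))
            )
            if in_region and pred(getattr(r, "aa_ref", None), getattr(r, "aa_alt", None)):
                hits += 1
        return hits, skipped

    rows = []
    total_skipped = 0
    for region in list(regions) + [None]:
        case_hits, sk1 = _count(case_variants, region)
        ctrl_hits, sk2 = _count(ctrl_variants, region)
        total_skipped = sk1 + sk2  # same records skipped for every region
        enrichment, p = fet_burden(case_hits, case_an, ctrl_hits, ctrl_an)
        rows.append(
            {
                "region": region.name if region else "union",
                "case_hits": case_hits,
                "ctrl_hits": ctrl_hits,
                "fold": enrichment,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_skipped"] = total_skipped
    return out


def subgroup_meta(
    counts: pd.DataFrame,
    mutability: pd.DataFrame,
    controls: pd.DataFrame,
    genes: list[str],
    n_trios_by_phenotype: dict[str, int],
    case_an_by_phenotype: dict[str, int],
    fclass: str = "damaging",
    level: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene x phenotype meta-analysis with JL-FDR over the whole grid.

    ``counts`` carries per gene x fclass x cardiac_subtype rows (``n_dnm``,
    ``case_ac``); subgroup DNM burden uses the subgroup's trio count against
    the same per-gene mutability, the case-control test uses the subgroup's
    chromosome denominator against the full control table.  Subgroups with
    zero probands are skipped with a warning column.
    """
    classes = list(DAMAGING_CLASSES) if fclass == "damaging" else [fclass]
    mu = mutability.set_index("gene")
    ctrl = controls[controls["fclass"].isin(classes)].groupby("gene")[["ctrl_ac"]].sum()
    ctrl_an = controls[controls["fclass"].isin(classes)].groupby("gene")["ctrl_an"].max()
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        mu_g = float(sum(mu.loc[gene, f"mu_{c}"] for c in classes))
        for pheno, n_trios in n_trios_by_phenotype.items():
            if n_trios <= 0 or case_an_by_phenotype.get(pheno, 0) <= 0:
                continue
            sel = counts[
                (counts["gene"] == gene)
                & counts["fclass"].isin(classes)
                & (counts.get("cardiac_subtype") == pheno)
            ]
            n_dnm = int(sel["n_dnm"].sum())
            case_ac = int(sel["case_ac"].sum())
            case_an = case_an_by_phenotype[pheno]
            p_dnm = poisson_burden(n_dnm, n_trios, mu_g).p
            c_ac = int(ctrl.loc[gene, "ctrl_ac"]) if gene in ctrl.index else 0
            c_an = int(ctrl_an.loc[gene]) if gene in ctrl_an.index else 1
            _, p_cc = fet_burden(case_ac, case_an, c_ac, c_an)
            # randomized transforms for the mixture (discrete tests, see pipeline)
            z_dnm = float(poisson_randp(n_dnm, n_trios * mu_g, rng))
            z_cc = float(fet_randp_vec(case_ac, case_an, c_ac, c_an, rng))
            rows.append(
                {
                    "gene": gene,
                    "phenotype": pheno,
                    "n_dnm": n_dnm,
                    "case_ac": case_ac,
                    "p_dnm": p_dnm,
                    "p_cc": p_cc,
                    "p_fisher": fishers_method(max(p_dnm, P_FLOOR), max(p_cc, P_FLOOR)),
                    "z_dnm": p_to_z(min(max(z_dnm, P_FLOOR), 1.0)),
                    "z_cc": p_to_z(min(max(z_cc, P_FLOOR), 1.0)),
                }
            )
    grid = pd.DataFrame(rows)
    if len(grid) < 10:
        grid["local_fdr"] = np.nan
        grid["jl_fdr"] = np.nan
        grid["significant"] = False
        return grid
    fit = BivariateMixtureFDR().fit(grid[["z_dnm", "z_cc"]].to_numpy())
    ranked = jl_fdr(grid, fit, level=level)
    return ranked
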