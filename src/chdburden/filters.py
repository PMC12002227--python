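"""Functional classification, rarity filtering, coverage harmonization, counting.

The case and control cohorts were sequenced on different platforms, so burden
comparisons are restricted to genomic territory targeted by all platforms and
allele denominators are scaled by the per-gene callable fraction of that shared
territory.  Variant positions are 1-based; intervals are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import (
    DAMAGING_CLASSES,
    FUNCTIONAL_CLASSES,
    CONSEQUENCES,
    FilterThresholds,
    InputError,
)

__all__ = [
    "classify_variant",
    "classify_frame",
    "filter_very_rare",
    "harmonize_territory",
    "aggregate_counts",
    "CoverageTable",
]

_LOF_CONSEQUENCES = {"stopgain", "frameshift", "canonical-splice"}


def classify_variant(consequence: str, metasvm: str | None = None) -> str:
    """Collapse a raw consequence (+ metapredictor call) to a functional class.

    Truncating consequences (stopgain, frameshift, canonical splice) are LOF;
    missense splits into D-mis / T-mis on the metapredictor verdict, with a
    missing verdict treated as tolerated; inframe indels and anything else
    fall into ``other``.
    """
    if consequence in _LOF_CONSEQUENCES:
        return "LOF"
    if consequence == "missense":
        return "D-mis" if metasvm == "D" else "T-mis"
    if consequence == "synonymous":
        return "synonymous"
    if consequence in ("inframe-indel", "other"):
        return "other"
    raise InputError(f"unknown consequence {consequence!r}")


def classify_frame(variants: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the variant table with an ``fclass`` column added."""
    svm = variants["metasvm"] if "metasvm" in variants.columns else None
    fclass = [
        classify_variant(c, None if svm is None or pd.isna(m) else m)
        for c, m in zip(variants["consequence"], svm if svm is not None else [None] * len(variants))
    ]
    out = variants.copy()
    out["fclass"] = fclass
    return out


def filter_very_rare(
    variants: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> pd.DataFrame:
    """Keep only very rare variants; order is preserved.

    A record is retained when its allele frequency is at most ``max_pop_maf``
    in both the BRAVO and ESP databases and its within-cohort frequency
    (``cohort_ac / cohort_an``) is at most ``max_cohort_maf``.  Missing
    population frequencies mean the allele is absent from the database and are
    treated as 0.
    """
    thresholds = thresholds or FilterThresholds()
    if len(variants) == 0:
        return variants.copy()
    an = variants["cohort_an"].to_numpy(dtype=float)
    if np.any(an <= 0):
        raise InputError("cohort_an must be positive for all records")
    bravo = variants["maf_bravo"].fillna(0.0).to_numpy(dtype=float)
    esp = variants["maf_esp"].fillna(0.0).to_numpy(dtype=float)
    cohort = variants["cohort_ac"].to_numpy(dtype=float) / an
    keep = (
        (bravo <= thresholds.max_pop_maf)
        & (esp <= thresholds.max_pop_maf)
        & (cohort <= thresholds.max_cohort_maf)
    )
    return variants.loc[keep].copy()


@dataclass
class CoverageTable:
    """Shared capture territory and per-gene callable fractions."""

    shared_intervals: pd.DataFrame  # chrom, start, end, gene (0-based half-open)
    fractions: pd.DataFrame  # gene, callable_fraction_cases, callable_fraction_controls


def _check_intervals(intervals: pd.DataFrame, label: str) -> pd.DataFrame:
    bad = intervals["end"] <= intervals["start"]
    if bad.any():
        row = intervals.loc[bad].iloc[0]
        raise InputError(
            f"malformed {label} interval {row['chrom']}:{row['start']}-{row['end']} (end <= start)"
        )
    return intervals.sort_values(["gene", "chrom", "start"]).reset_index(drop=True)


def _intersect_gene(case_iv: np.ndarray, ctrl_iv: np.ndarray) -> list[tuple[int, int]]:
    # sorted-merge intersection of two interval lists (0-based half-open)
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(case_iv) and j < len(ctrl_iv):
        a0, a1 = case_iv[i]
        b0, b1 = ctrl_iv[j]
        lo, hi = max(a0, b0), min(a1, b1)
        if lo < hi:
            out.append((lo, hi))
        if a1 <= b1:
            i += 1
        else:
            j += 1
    return out


def harmonize_territory(
    case_intervals: pd.DataFrame,
    control_intervals: pd.DataFrame,
    variants: pd.DataFrame,
) -> tuple[CoverageTable, pd.DataFrame]:
    """Restrict to territory targeted on both arms.

    Interval tables carry ``chrom, start, end, gene``.  The shared territory is
    the per-gene intersection; variants outside it are dropped; per-gene
    callable fractions are the shared span divided by each arm's own span.
    """
    case_intervals = _check_intervals(case_intervals, "case")
    control_intervals = _check_intervals(control_intervals, "control")

    shared_rows = []
    frac_rows = []
    genes = sorted(set(case_intervals["gene"]) | set(control_intervals["gene"]))
    for gene in genes:
        cs = case_intervals[case_intervals["gene"] == gene]
        ct = control_intervals[control_intervals["gene"] == gene]
        for chrom in sorted(set(cs["chrom"]) | set(ct["chrom"])):
            a = cs[cs["chrom"] == chrom][["start", "end"]].to_numpy()
            b = ct[ct["chrom"] == chrom][["start", "end"]].to_numpy()
            for lo, hi in _intersect_gene(a, b):
                shared_rows.append({"chrom": chrom, "start": lo, "end": hi, "gene": gene})
        case_span = int((cs["end"] - cs["start"]).sum())
        ctrl_span = int((ct["end"] - ct["start"]).sum())
        shared_span = sum(
            r["end"] - r["start"] for r in shared_rows if r["gene"] == gene
        )
        frac_rows.append(
            {
                "gene": gene,
                "callable_fraction_cases": shared_span / case_span if case_span else 0.0,
                "callable_fraction_controls": shared_span / ctrl_span if ctrl_span else 0.0,
            }
        )
    shared = pd.DataFrame(shared_rows, columns=["chrom", "start", "end", "gene"])
    fractions = pd.DataFrame(
        frac_rows, columns=["gene", "callable_fraction_cases", "callable_fraction_controls"]
    )

    if len(variants):
        keep = np.zeros(len(variants), dtype=bool)
        by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for r in shared.itertuples():
            by_key.setdefault((r.gene, r.chrom), []).append((r.start, r.end))
        pos0 = variants["pos"].to_numpy(dtype=int) - 1  # 1-based -> 0-based
        for idx, (gene, chrom, p0) in enumerate(
            zip(variants["gene"], variants["chrom"], pos0)
        ):
            keep[idx] = any(lo <= p0 < hi for lo, hi in by_key.get((gene, chrom), ()))
        retained = variants.loc[keep].copy()
    else:
        retained = variants.copy()
    return CoverageTable(shared_intervals=shared, fractions=fractions), retained


def aggregate_counts(
    variants: pd.DataFrame,
    panel_genes: list[str] | pd.Index,
    phenotypes: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tally filtered, classified records per gene x functional class.

    Returns ``(counts, rejects)``.  ``counts`` has one row per gene x class
    (x cardiac subtype when ``phenotypes`` is given) with columns ``n_dnm``,
    ``case_ac`` (distinct proband alleles: de novo + transmitted + unphased),
    ``T``, ``U`` (transmitted / untransmitted parental alleles) and
    ``n_unphased``.  Duplicate rows for the same allele in the same individual
    collapse to one.  Records whose gene is not on the panel are skipped and
    reported in ``rejects``.
    """
    panel = set(panel_genes)
    if "fclass" not in variants.columns:
        variants = classify_frame(variants)

    in_panel = variants["gene"].isin(panel)
    rejects = variants.loc[~in_panel].copy()
    rejects["reason"] = "gene_not_in_panel"
    v = variants.loc[in_panel]
    # one allele per (site, individual)
    v = v.drop_duplicates(subset=["chrom", "pos", "ref", "alt", "sample_id"])

    keys = ["gene", "fclass"]
    if phenotypes is not None:
        pheno = phenotypes.set_index("proband_id")["cardiac_subtype"]
        v = v.copy()
        v["cardiac_subtype"] = v["sample_id"].map(pheno)
        keys.append("cardiac_subtype")

    def _tally(group: pd.DataFrame) -> pd.Series:
        origin = group["origin"]
        return pd.Series(
            {
                "n_dnm": int((origin == "de_novo").sum()),
                "case_ac": int(origin.isin(["de_novo", "transmitted", "unphased"]).sum()),
                "T": int((origin == "transmitted").sum()),
                "U": int((origin == "untransmitted_parental").sum()),
                "n_unphased": int((origin == "unphased").sum()),
            }
        )

    if len(v):
        counts = v.groupby(keys, sort=True).apply(_tally, include_groups=False).reset_index()
    else:
        cols = keys + ["n_dnm", "case_ac", "T", "U", "n_unphased"]
        counts = pd.DataFrame(columns=cols)
    for c in ("n_dnm", "case_ac", "T", "U", "n_unphased"):
        counts[c] = counts[c].astype(int) if len(counts) else counts.get(c, pd.Series(dtype=int))
    return counts, rejects


def complete_counts(
    counts: pd.DataFrame, panel_genes: list[str], classes: tuple[str, ...] = FUNCTIONAL_CLASSES
) -> pd.DataFrame:
    """Expand a counts table to the full gene x class grid with zero fill."""
    full = pd.MultiIndex.from_product([panel_genes, list(classes)], names=["gene", "fclass"])
    out = (
        counts.set_index(["gene", "fclass"])
        .reindex(full, fill_value=0)
        .reset_index()
    )
    count_cols = [c for c in ("n_dnm", "case_ac", "T", "U", "n_unphased") if c in out.columns]
    out[count_cols] = out[count_cols].astype(float).fillna(0.0).astype(int)
    return out
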