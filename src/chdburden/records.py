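"""Core record types and table schemas.

Variant observations travel through the pipeline as pandas DataFrames with the
column schema declared in :data:`VARIANT_COLUMNS`; :class:`VariantRecord` is the
validated single-row view used when constructing or inspecting individual calls.
Positions are 1-based (VCF convention); genomic intervals elsewhere in the
package are 0-based half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable

import pandas as pd

#: Functional classes after collapsing raw consequences.
FUNCTIONAL_CLASSES = ("synonymous", "T-mis", "D-mis", "LOF", "other")

#: Damaging classes pooled in the headline burden analyses.
DAMAGING_CLASSES = ("D-mis", "LOF")

#: Raw consequence vocabulary accepted by the classifier.
CONSEQUENCES = (
    "synonymous",
    "missense",
    "stopgain",
    "frameshift",
    "canonical-splice",
    "inframe-indel",
    "other",
)

ORIGINS = ("de_novo", "transmitted", "untransmitted_parental", "unphased")

#: Declared variant-table schema (TSV header order).
VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "metasvm",
    "maf_bravo",
    "maf_esp",
    "maf_gnomad",
    "cohort_ac",
    "cohort_an",
    "origin",
    "sample_id",
    "family_id",
    "protein_pos",
    "aa_ref",
    "aa_alt",
]


class InputError(ValueError):
    """Raised on malformed user input (bad table, bad parameter)."""


@dataclass
class VariantRecord:
    """One annotated variant observation in one individual."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    metasvm: str | None = None
    maf_bravo: float = 0.0
    maf_esp: float = 0.0
    maf_gnomad: float = 0.0
    cohort_ac: int = 1
    cohort_an: int = 1
    origin: str = "unphased"
    sample_id: str = ""
    family_id: str = ""
    protein_pos: int | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"pos must be >= 1, got {self.pos}")
        for name in ("maf_bravo", "maf_esp", "maf_gnomad"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} out of [0, 1]: {v}")
        if self.cohort_ac > self.cohort_an:
            raise InputError(
                f"cohort_ac ({self.cohort_ac}) exceeds cohort_an ({self.cohort_an})"
            )
        if self.origin not in ORIGINS:
            raise InputError(f"unknown origin {self.origin!r}")
        if "," in self.alt:
            raise InputError("multi-allelic rows must be pre-split (one alt per row)")


def variants_to_frame(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Stack records into the canonical variant DataFrame."""
    rows = [{f.name: getattr(r, f.name) for f in fields(VariantRecord)} for r in records]
    if not rows:
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def frame_to_variants(df: pd.DataFrame) -> list[VariantRecord]:
    """Materialize (and validate) each row of a variant DataFrame."""
    out = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in VARIANT_COLUMNS if c in row.index}
        for opt in ("metasvm", "protein_pos", "aa_ref", "aa_alt"):
            if opt in kwargs and pd.isna(kwargs[opt]):
                kwargs[opt] = None
        if kwargs.get("protein_pos") is not None:
            kwargs["protein_pos"] = int(kwargs["protein_pos"])
        kwargs["pos"] = int(kwargs["pos"])
        kwargs["cohort_ac"] = int(kwargs["cohort_ac"])
        kwargs["cohort_an"] = int(kwargs["cohort_an"])
        out.append(VariantRecord(**kwargs))
    return out


@dataclass
class FilterThresholds:
    """Rarity thresholds for the very-rare variant filter.

    ``max_pop_maf`` bounds the allele frequency in each population database
    (BRAVO and ESP); ``max_cohort_maf`` bounds the within-cohort frequency
    computed from cohort allele counts.
    """

    max_pop_maf: float = 1e-5
    max_cohort_maf: float = 1.3e-4

    def __post_init__(self) -> None:
        for name in ("max_pop_maf", "max_cohort_maf"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InputError(f"{name} must be in (0, 1), got {v}")
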