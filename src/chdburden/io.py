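"""Readers and writers for the pipeline's file formats.

TSV tables with declared headers, 6-column PED pedigrees, BED intervals,
optional VCF input for variants, YAML run configuration.  Every writer's
output is re-readable by the matching reader.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import VARIANT_COLUMNS, InputError

__all__ = [
    "read_variants",
    "read_pedigree",
    "read_bed",
    "read_table",
    "write_table",
    "write_pedigree",
    "RunConfig",
    "load_config",
]

_NUMERIC = {
    "pos": int,
    "maf_bravo": float,
    "maf_esp": float,
    "maf_gnomad": float,
    "cohort_ac": int,
    "cohort_an": int,
}


def read_variants(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read an annotated variant table (TSV, or VCF with INFO annotations).

    Enforces the declared schema, one alt allele per row, and
    ``cohort_ac <= cohort_an`` per row; errors carry 1-based line numbers.
    """
    if dialect == "vcf":
        return _read_variants_vcf(path)
    if dialect != "tsv":
        raise InputError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}")
    for col, typ in _NUMERIC.items():
        try:
            df[col] = df[col].astype(float if typ is float else int)
        except ValueError as exc:
            raise InputError(f"{path}: unparsable {col}: {exc}") from None
    df["protein_pos"] = pd.to_numeric(df["protein_pos"], errors="coerce")
    bad_alt = df["alt"].str.contains(",")
    if bad_alt.any():
        line = int(np.flatnonzero(bad_alt)[0]) + 2  # header is line 1
        raise InputError(f"{path}: multi-allelic row at line {line}; pre-split alts")
    bad_ac = df["cohort_ac"] > df["cohort_an"]
    if bad_ac.any():
        line = int(np.flatnonzero(bad_ac)[0]) + 2
        raise InputError(f"{path}: cohort_ac > cohort_an at line {line}")
    return df[VARIANT_COLUMNS + [c for c in df.columns if c not in VARIANT_COLUMNS]]


_VCF_INFO_KEYS = {
    "gene": "GENE",
    "consequence": "CSQ",
    "metasvm": "METASVM",
    "maf_bravo": "MAF_BRAVO",
    "maf_esp": "MAF_ESP",
    "maf_gnomad": "MAF_GNOMAD",
    "cohort_ac": "COHORT_AC",
    "cohort_an": "COHORT_AN",
    "origin": "ORIGIN",
    "sample_id": "SAMPLE",
    "family_id": "FAMILY",
    "protein_pos": "PPOS",
    "aa_ref": "AAREF",
    "aa_alt": "AAALT",
}


def _read_variants_vcf(path: str | Path) -> pd.DataFrame:
    from cyvcf2 import VCF  # optional input path; heavy import kept lazy

    rows = []
    for v in VCF(str(path)):
        if len(v.ALT) != 1:
            raise InputError(f"{path}: multi-allelic record at {v.CHROM}:{v.POS}; pre-split")
        row: dict = {
            "chrom": v.CHROM,
            "pos": v.POS,
            "ref": v.REF,
            "alt": v.ALT[0],
        }
        for col, key in _VCF_INFO_KEYS.items():
            val = v.INFO.get(key)
            row[col] = val
        rows.append(row)
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    for col in ("maf_bravo", "maf_esp", "maf_gnomad"):
        df[col] = pd.to_numeric(df[col]).fillna(0.0)
    for col in ("cohort_ac", "cohort_an"):
        df[col] = pd.to_numeric(df[col]).astype(int)
    df["protein_pos"] = pd.to_numeric(df["protein_pos"], errors="coerce")
    return df


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Read a 6-column PED file and classify families.

    Returns the table with an added ``role`` column and, in ``attrs``,
    ``n_trios`` / ``n_singletons``.  A child whose listed parent has no row of
    its own is a structural error; a child with exactly one listed parent is
    downgraded to singleton (``attrs['warnings']``).
    """
    ped = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["family_id", "individual_id", "father_id", "mother_id", "sex", "affected"],
        dtype=str,
    )
    ids = set(ped["individual_id"])
    warnings: list[str] = []
    role = []
    n_trios = n_singletons = 0
    for r in ped.itertuples():
        fa, mo = r.father_id, r.mother_id
        if fa not in ("0", "") and fa not in ids:
            raise InputError(f"{path}: {r.individual_id} references absent father {fa}")
        if mo not in ("0", "") and mo not in ids:
            raise InputError(f"{path}: {r.individual_id} references absent mother {mo}")
        has_fa = fa not in ("0", "")
        has_mo = mo not in ("0", "")
        if has_fa and has_mo:
            role.append("trio_proband")
            n_trios += 1
        elif has_fa or has_mo:
            role.append("singleton_proband")
            n_singletons += 1
            warnings.append(f"{r.individual_id}: one parent listed, treated as singleton")
        elif r.affected == "2":
            role.append("singleton_proband")
            n_singletons += 1
        else:
            role.append("parent")
    out = ped.copy()
    out["role"] = role
    out.attrs["n_trios"] = n_trios
    out.attrs["n_singletons"] = n_singletons
    out.attrs["warnings"] = warnings
    return out


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED4 intervals (chrom, start, end, gene), 0-based half-open."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene"],
        dtype={"chrom": str, "start": int, "end": int, "gene": str}, comment="#",
    )
    if (df["end"] <= df["start"]).any():
        raise InputError(f"{path}: interval with end <= start")
    return df


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_pedigree(ped: pd.DataFrame, path: str | Path) -> None:
    cols = ["family_id", "individual_id", "father_id", "mother_id", "sex", "affected"]
    ped[cols].to_csv(path, sep="\t", index=False, header=False, lineterminator="\n")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (paths, thresholds, seeds)."""

    variants: str = ""
    pedigree: str = ""
    phenotypes: str = ""
    mutability: str = ""
    controls: str = ""
    coverage: str = ""
    outdir: str = "chdburden_out"
    max_pop_maf: float = 1e-5
    max_cohort_maf: float = 1.3e-4
    fdr_level: float = 0.05
    bonferroni_n: int = 248
    genome_wide_p: float = 2.6e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise InputError("fdr_level must be in (0, 1)")
        if self.genome_wide_p <= 0 or self.genome_wide_p >= 1:
            raise InputError("genome_wide_p must be in (0, 1)")

    def validate_paths(self) -> None:
        for name in ("variants", "pedigree", "phenotypes", "mutability", "controls"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise InputError(f"config path {name} does not exist: {p}")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
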