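"""Transmission disequilibrium test for very rare variants in trios.

Each parental heterozygous allele is one informative transmission: it either
reaches the proband (T) or does not (U).  Under Mendelian null transmission
T ~ Binomial(T+U, 1/2); the test statistic is chi-square (T-U)^2/(T+U) with 1
df and no continuity correction.  The genotypic risk ratio is estimated as
T/U under a multiplicative model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import DAMAGING_CLASSES, InputError

__all__ = ["TdtResult", "tdt_test", "geneset_tdt"]


@dataclass
class TdtResult:
    unit: str
    fclass: str
    T: int
    U: int
    chi2: float
    p: float
    transmitted_fraction: float
    grr: float
    attributable_fraction: float | None = None


def tdt_test(T: int, U: int, unit: str = "", fclass: str = "") -> TdtResult:
    """Chi-square TDT on transmitted vs untransmitted parental allele counts."""
    if T < 0 or U < 0:
        raise InputError("counts must be non-negative")
    n = T + U
    if n == 0:
        raise InputError("no informative transmissions (T + U = 0)")
    chi2 = (T - U) ** 2 / n
    return TdtResult(
        unit=unit,
        fclass=fclass,
        T=int(T),
        U=int(U),
        chi2=float(chi2),
        p=float(stats.chi2.sf(chi2, 1)),
        transmitted_fraction=T / n,
        grr=(T / U) if U > 0 else np.inf,
    )


def geneset_tdt(
    counts: pd.DataFrame,
    genes: list[str],
    fclass: str,
    n_trios: int,
) -> TdtResult:
    """TDT pooled over a gene set, plus the transmission attributable fraction.

    T and U are summed over the set; the attributable fraction is the excess
    of transmissions over the Mendelian expectation (T+U)/2, per trio.
    ``fclass`` may be one functional class or ``"damaging"``.
    """
    genes = list(genes)
    if not genes:
        raise InputError("empty gene set")
    classes = list(DAMAGING_CLASSES) if fclass == "damaging" else [fclass]
    sel = counts[counts["gene"].isin(genes) & counts["fclass"].isin(classes)]
    T = int(sel["T"].sum())
    U = int(sel["U"].sum())
    res = tdt_test(T, U, unit="geneset", fclass=fclass)
    res.attributable_fraction = max(0.0, T - (T + U) / 2.0) / n_trios
    return res
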