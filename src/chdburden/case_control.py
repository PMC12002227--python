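"""Case-control burden of very rare alleles via one-tailed Fisher's exact test.

Cases are CHD proband alleles (transmitted + unphased after filtering);
controls are gnomAD-style per-gene, per-class allele counts with chromosome
denominators scaled by the callable fraction of the harmonized territory.
The one-tailed direction is fixed to case enrichment: depletion can never be
significant.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .records import InputError

__all__ = [
    "fet_burden",
    "fet_burden_vec",
    "coverage_adjust",
    "attributable_fraction_cc",
]


def _check(case_ac: int, case_an: int, ctrl_ac: int, ctrl_an: int) -> None:
    if case_an <= 0 or ctrl_an <= 0:
        raise InputError("chromosome counts must be positive")
    if case_ac > case_an or ctrl_ac > ctrl_an:
        raise InputError("allele count exceeds chromosome count")
    if min(case_ac, ctrl_ac) < 0:
        raise InputError("counts must be non-negative")


def fet_burden(case_ac: int, case_an: int, ctrl_ac: int, ctrl_an: int) -> tuple[float, float]:
    """One-tailed Fisher's exact test for allele enrichment in cases.

    The 2x2 table is ``[[case_ac, case_an - case_ac], [ctrl_ac, ctrl_an -
    ctrl_ac]]``; the p-value is the hypergeometric upper tail in the case
    enrichment direction.  Returns ``(enrichment, p)`` where enrichment is the
    case/control frequency ratio (``inf`` when only cases carry alleles,
    ``nan`` when neither arm does).
    """
    _check(case_ac, case_an, ctrl_ac, ctrl_an)
    total_ac = case_ac + ctrl_ac
    total_an = case_an + ctrl_an
    # P(X >= case_ac), X ~ Hypergeom(total_an, total_ac, case_an)
    p = float(stats.hypergeom.sf(case_ac - 1, total_an, total_ac, case_an))
    case_f = case_ac / case_an
    ctrl_f = ctrl_ac / ctrl_an
    if ctrl_ac == 0:
        enrichment = np.inf if case_ac > 0 else np.nan
    else:
        enrichment = case_f / ctrl_f
    return enrichment, min(p, 1.0)


def fet_burden_vec(case_ac, case_an, ctrl_ac, ctrl_an) -> np.ndarray:
    """Vectorized upper-tail p-values for arrays of 2x2 tables."""
    case_ac = np.asarray(case_ac)
    p = stats.hypergeom.sf(
        case_ac - 1,
        np.asarray(case_an) + np.asarray(ctrl_an),
        case_ac + np.asarray(ctrl_ac),
        np.asarray(case_an),
    )
    return np.minimum(p, 1.0)


def fet_midp_vec(case_ac, case_an, ctrl_ac, ctrl_an) -> np.ndarray:
    """Mid-p upper tail of the hypergeometric: ``P(X > a) + 0.5 P(X = a)``.

    Used for z-score transforms, where the standard tail's point mass at 1
    (zero-count genes) would distort the evidence mixture.
    """
    a = np.asarray(case_ac)
    M = np.asarray(case_an) + np.asarray(ctrl_an)
    K = a + np.asarray(ctrl_ac)
    n = np.asarray(case_an)
    return stats.hypergeom.sf(a, M, K, n) + 0.5 * stats.hypergeom.pmf(a, M, K, n)


def fet_randp_vec(case_ac, case_an, ctrl_ac, ctrl_an, rng: np.random.Generator) -> np.ndarray:
    """Randomized upper-tail hypergeometric transform (exactly uniform null).

    ``P(X > a) + U * P(X = a)`` with U ~ Uniform(0, 1); see the de novo
    counterpart for why the discrete tests need this before a z-transform.
    """
    a = np.asarray(case_ac)
    M = np.asarray(case_an) + np.asarray(ctrl_an)
    K = a + np.asarray(ctrl_ac)
    n = np.asarray(case_an)
    u = rng.uniform(size=np.broadcast(a, M).shape)
    return stats.hypergeom.sf(a, M, K, n) + u * stats.hypergeom.pmf(a, M, K, n)


def coverage_adjust(an_raw: int, callable_fraction: float) -> int:
    """Effective chromosome count after per-gene coverage adjustment.

    Rounds half up; never returns less than 1.
    """
    if not 0 < callable_fraction <= 1:
        raise InputError(f"callable fraction must be in (0, 1], got {callable_fraction}")
    if an_raw < 1:
        raise InputError("an_raw must be >= 1")
    return max(1, int(np.floor(an_raw * callable_fraction + 0.5)))


def attributable_fraction_cc(
    case_ac: int, case_an: int, ctrl_ac: int, ctrl_an: int
) -> float:
    """Excess case allele frequency over controls, per diploid proband.

    The per-chromosome frequency difference is doubled to express carriers per
    proband, and floored at zero.
    """
    _check(case_ac, case_an, ctrl_ac, ctrl_an)
    return max(0.0, (case_ac / case_an - ctrl_ac / ctrl_an)) * 2.0
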