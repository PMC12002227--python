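"""De novo mutation burden against per-gene mutability expectation.

The null model: the DNM count of class ``c`` in gene ``g`` across ``n`` trios
is Poisson with mean ``n * mu_gc``, where ``mu_gc`` is the per-live-birth
probability of one de novo variant of that class in that gene.  Enrichment is
observed/expected; the test is the upper Poisson tail including the observed
count.  The module also provides QQ/lambda_1000 inflation statistics, the
expected number of multi-hit genes, the attributable fraction of probands, and
a Monte-Carlo maximum-likelihood estimate of the number of risk genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .records import DAMAGING_CLASSES, InputError

__all__ = [
    "BurdenResult",
    "poisson_burden",
    "geneset_burden",
    "attributable_fraction_dnm",
    "lambda_1000",
    "qq_summary",
    "expected_multihit_genes",
    "risk_gene_mle",
    "RiskGeneEstimate",
    "damaging_mu",
]

#: Median of the 1-df chi-square distribution, the null median of the
#: inflation statistic.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class BurdenResult:
    unit: str
    fclass: str
    observed: int
    expected: float
    enrichment: float
    p: float
    attributable_fraction: float


def poisson_burden(
    observed: int, n_trios: int, mu: float, unit: str = "", fclass: str = ""
) -> BurdenResult:
    """Upper-tail Poisson test of an observed DNM count against mutability.

    ``p = P(Poisson(n_trios * mu) >= observed)``, including the observed count.
    """
    if mu <= 0:
        raise InputError(f"mutability must be positive, got {mu}")
    if n_trios < 1:
        raise InputError("n_trios must be >= 1")
    if observed < 0:
        raise InputError("observed count must be non-negative")
    expected = n_trios * mu
    p = float(stats.poisson.sf(observed - 1, expected)) if observed > 0 else 1.0
    return BurdenResult(
        unit=unit,
        fclass=fclass,
        observed=int(observed),
        expected=expected,
        enrichment=observed / expected,
        p=p,
        attributable_fraction=attributable_fraction_dnm(observed, expected, n_trios),
    )


def poisson_midp(observed, expected) -> np.ndarray:
    """Mid-p upper tail: ``P(X > obs) + 0.5 P(X = obs)``.

    For discrete counts the standard upper tail has a point mass at 1 (all
    zero-count genes), which distorts z-score transforms; the mid-p variant
    is approximately uniform under the null and is used when feeding the
    evidence mixture.  Reported p-values stay the conservative full tail.
    """
    observed = np.asarray(observed)
    expected = np.asarray(expected, dtype=float)
    return stats.poisson.sf(observed, expected) + 0.5 * stats.poisson.pmf(observed, expected)


def poisson_randp(observed, expected, rng: np.random.Generator) -> np.ndarray:
    """Randomized upper-tail transform: ``P(X > obs) + U * P(X = obs)``.

    The randomized probability-integral transform of the discrete count is
    exactly Uniform(0, 1) under the null, unlike the full tail (point mass
    at 1 for zero-count genes) or the deterministic mid-p.  Used to build
    the z-scores feeding the evidence mixture; reported p-values stay the
    conservative full tail.
    """
    observed = np.asarray(observed)
    expected = np.asarray(expected, dtype=float)
    u = rng.uniform(size=np.broadcast(observed, expected).shape)
    return stats.poisson.sf(observed, expected) + u * stats.poisson.pmf(observed, expected)


def damaging_mu(mutability: pd.DataFrame) -> pd.Series:
    """Per-gene damaging mutability (D-mis + LOF), indexed by gene."""
    m = mutability.set_index("gene") if "gene" in mutability.columns else mutability
    return m["mu_D-mis"] + m["mu_LOF"]


def _class_mu(mutability: pd.DataFrame, fclass: str) -> pd.Series:
    m = mutability.set_index("gene") if "gene" in mutability.columns else mutability
    if fclass == "damaging":
        return m["mu_D-mis"] + m["mu_LOF"]
    col = f"mu_{fclass}"
    if col not in m.columns:
        raise InputError(f"mutability table lacks column {col}")
    return m[col]


def geneset_burden(
    counts: pd.DataFrame,
    mutability: pd.DataFrame,
    genes: list[str],
    fclass: str,
    n_trios: int,
) -> BurdenResult:
    """Pooled burden over a gene set: O and E are summed, then tested.

    ``fclass`` may be a single functional class or ``"damaging"`` (D-mis + LOF
    pooled).
    """
    genes = list(genes)
    if not genes:
        raise InputError("empty gene set")
    mu = _class_mu(mutability, fclass)
    missing = [g for g in genes if g not in mu.index]
    if missing:
        raise InputError(f"genes absent from mutability table: {missing[:5]}")
    classes = list(DAMAGING_CLASSES) if fclass == "damaging" else [fclass]
    sel = counts[counts["gene"].isin(genes) & counts["fclass"].isin(classes)]
    observed = int(sel["n_dnm"].sum())
    mu_total = float(mu.loc[genes].sum())
    return poisson_burden(observed, n_trios, mu_total, unit="+".join(genes[:3]) + ("..." if len(genes) > 3 else ""), fclass=fclass)


def attributable_fraction_dnm(observed: float, expected: float, n_probands: int) -> float:
    """Excess observed DNMs over expectation, per proband, floored at zero."""
    if n_probands < 1:
        raise InputError("n_probands must be >= 1")
    return max(0.0, (observed - expected) / n_probands)


def lambda_1000(pvals, n_samples: int) -> float:
    """Genomic inflation factor rescaled to a cohort of 1,000 samples.

    lambda is the median 1-df chi-square statistic implied by the p-values
    divided by the null median 0.4549; the per-1000 rescaling is
    ``1 + (lambda - 1) * 1000 / n_samples``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise InputError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise InputError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    lam = float(np.median(chi) / CHI2_1DF_MEDIAN)
    return 1.0 + (lam - 1.0) * (1000.0 / n_samples)


def qq_summary(pvals, n_samples: int) -> pd.DataFrame:
    """Sorted observed p-values vs uniform expectation, for QQ plotting."""
    p = np.sort(np.asarray(pvals, dtype=float))
    n = p.size
    if n == 0:
        raise InputError("empty p-value list")
    expected = (np.arange(1, n + 1) - 0.5) / n
    df = pd.DataFrame({"observed_p": p, "expected_p": expected})
    df.attrs["lambda_1000"] = lambda_1000(p, n_samples)
    return df


def expected_multihit_genes(
    mutability: pd.DataFrame,
    n_trios: int,
    min_hits: int = 2,
    n_sim: int = 0,
    seed: int | None = None,
) -> float | tuple[float, float, float]:
    """Expected number of genes with >= ``min_hits`` damaging DNMs.

    Closed form: sum over genes of the upper Poisson tail at ``min_hits``.
    With ``n_sim`` > 0 a Monte-Carlo cross-check is run and the return value
    is ``(closed_form, sim_mean, sim_sd)``.
    """
    if min_hits < 1:
        raise InputError("min_hits must be >= 1")
    lam = damaging_mu(mutability).to_numpy(dtype=float) * n_trios
    closed = float(stats.poisson.sf(min_hits - 1, lam).sum())
    if n_sim <= 0:
        return closed
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam, size=(n_sim, lam.size))
    hits = (counts >= min_hits).sum(axis=1)
    return closed, float(hits.mean()), float(hits.std(ddof=1))


@dataclass
class RiskGeneEstimate:
    r_hat: float
    ci_low: float
    ci_high: float
    loglik_curve: pd.DataFrame  # columns: R, loglik
    degenerate: bool = False


def _multihit_pair(counts: np.ndarray) -> np.ndarray:
    """(n_sim, 2) array: genes with >=1 and >=2 damaging DNMs per simulation."""
    return np.stack([(counts >= 1).sum(axis=1), (counts >= 2).sum(axis=1)], axis=1)


def risk_gene_mle(
    observed_per_gene,
    mutability: pd.DataFrame,
    n_trios: int,
    enrichment_grid=(5.0, 10.0, 20.0),
    r_grid=tuple(range(0, 121, 10)),
    n_sim: int = 200,
    seed: int | None = None,
    uniform_sampling: bool = False,
) -> RiskGeneEstimate:
    """Monte-Carlo MLE of the number of risk genes on the panel.

    For each candidate count ``R``, cohorts are simulated ``n_sim`` times:
    ``R`` risk genes are drawn (by default proportionally to damaging
    mutability), damaging DNM counts are Poisson with the risk genes' means
    multiplied by an enrichment factor, and the summary statistic is the pair
    (number of genes with >= 1 hit, number with >= 2 hits).  The empirical
    likelihood of the observed pair uses the simulated joint frequency table
    with add-one smoothing; the enrichment factor is profiled out (maximized)
    per ``R``.  The 95% CI collects grid points within 1.92 log-likelihood
    units of the maximum.
    """
    obs = np.asarray(observed_per_gene, dtype=int)
    lam0 = damaging_mu(mutability).to_numpy(dtype=float) * n_trios
    if obs.size != lam0.size:
        raise InputError("observed_per_gene and mutability must cover the same genes")
    r_grid = [int(r) for r in r_grid]
    enrichment_grid = [float(e) for e in enrichment_grid]
    if not r_grid or not enrichment_grid:
        raise InputError("grids must be non-empty")
    if n_sim < 100:
        raise InputError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    n_genes = lam0.size
    weights = lam0 / lam0.sum() if not uniform_sampling else np.full(n_genes, 1.0 / n_genes)
    obs_pair = (int((obs >= 1).sum()), int((obs >= 2).sum()))

    rows = []
    for R in r_grid:
        best = -np.inf
        for e in enrichment_grid if R > 0 else enrichment_grid[:1]:
            lam = np.tile(lam0, (n_sim, 1))
            if R > 0:
                for i in range(n_sim):
                    risk = rng.choice(n_genes, size=min(R, n_genes), replace=False, p=weights)
                    lam[i, risk] *= e
            counts = rng.poisson(lam)
            pairs = _multihit_pair(counts)
            uniq, freq = np.unique(pairs, axis=0, return_counts=True)
            table = {tuple(u): f for u, f in zip(uniq, freq)}
            n_bins = len(table) + 1  # support seen, plus one slot for the unseen
            lik = (table.get(obs_pair, 0) + 1) / (n_sim + n_bins)
            best = max(best, float(np.log(lik)))
        rows.append({"R": R, "loglik": best})
    curve = pd.DataFrame(rows)
    imax = int(curve["loglik"].idxmax())
    r_hat = float(curve.loc[imax, "R"])
    inside = curve[curve["loglik"] >= curve["loglik"].max() - 1.92]
    degenerate = len(r_grid) == 1
    return RiskGeneEstimate(
        r_hat=r_hat,
        ci_low=float(inside["R"].min()),
        ci_high=float(inside["R"].max()),
        loglik_curve=curve,
        degenerate=degenerate,
    )
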