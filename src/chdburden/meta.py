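"""Meta-analysis of DNM and case-control evidence, and joint-local FDR.

Per gene, the two one-sided p-values (Poisson DNM tail, case-control Fisher
tail) are combined by Fisher's method for a headline meta p-value, and mapped
to a pair of standard-normal deviates ``z = (z_dnm, z_cc)``.  Across genes the
z-pairs are modeled as a two-component mixture: a fixed standard bivariate
normal null (both inputs are one-sided p-values, uniform under the null) and a
free alternative component with non-negative mean, fitted by EM.  The local
FDR of a gene is the posterior null probability at its z-pair; the joint-local
FDR (JL-FDR) of a rejection set is the running mean of local FDRs in rank
order, thresholded at 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import InputError

__all__ = [
    "fishers_method",
    "p_to_z",
    "BivariateMixtureFDR",
    "fit_mixture_em",
    "jl_fdr",
    "bh_fdr",
    "predicted_risk_genes",
    "P_FLOOR",
    "Z_CAP",
]

#: p-values are floored here before log / inverse-normal transforms.
P_FLOOR = 1e-300
#: z-scores are clipped to +-Z_CAP.
Z_CAP = 8.0


def fishers_method(p1: float, p2: float) -> float:
    """Combine two independent p-values: chi-square(4 df) tail of -2*sum(log p)."""
    if p1 <= 0 or p2 <= 0 or p1 > 1 or p2 > 1:
        raise InputError("p-values must lie in (0, 1]; floor extreme values first")
    x = -2.0 * (np.log(p1) + np.log(p2))
    return float(stats.chi2.sf(x, 4))


def p_to_z(p: float, cap: float = Z_CAP) -> float:
    """One-sided p-value to standard-normal deviate, clipped to [-cap, cap]."""
    if p <= 0 or p > 1:
        raise InputError("p must lie in (0, 1]")
    return float(np.clip(stats.norm.isf(p), -cap, cap))


def _log_bvn_pdf(z: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    return stats.multivariate_normal(mean=mean, cov=cov, allow_singular=False).logpdf(z)


class BivariateMixtureFDR:
    """Two-component bivariate normal mixture for joint-local FDR.

    The null component is fixed at the standard bivariate normal with zero
    correlation; the alternative component has a free weight ``1 - pi0``, a
    mean constrained non-negative componentwise (evidence points toward
    enrichment in both coordinates) and a free positive-definite covariance.

    When the sample contains no real signal the two components become
    indistinguishable and the likelihood is flat in ``pi0``; a weak Beta
    prior on ``pi0`` (strength ``pi0_prior`` pseudo-counts, default 10% of
    the sample) makes the fit null-dominant in that regime, the usual
    empirical-Bayes convention.  The EM maximizes the penalized
    log-likelihood with a generalized-EM safeguard: an M-step that would
    lower the objective (possible when the mean clips at zero) is rejected
    and the fit stops at the previous parameters, so ``loglik_trace_`` is
    always non-decreasing.

    After the EM, a BIC comparison against the null-only model decides
    whether the alternative component is supported at all (the same
    model-selection step mixture packages apply when choosing the number of
    components).  When it is not, the fit collapses to ``pi0_ = 1``
    (``null_model_`` True) and no gene can be declared significant —
    without this gate the free alternative component fits the extreme tail
    of a pure-null sample and manufactures false discoveries.

    Parameters
    ----------
    tol : float
        Stop when the objective gain drops below this.
    max_iter : int
        Iteration cap; exceeding it leaves ``converged_`` False.
    pi0_prior : float or None
        Pseudo-count strength of the Beta prior on ``pi0``; ``None`` means
        ``0.1 * n``.
    pi0_init, mu_fallback : EM initialization knobs. The alternative mean is
        initialized at the mean of pairs with both z > 1, falling back to
        ``mu_fallback`` when no such pairs exist.

    Attributes (after ``fit``)
    --------------------------
    pi0_ : float — null weight.
    mu1_ : (2,) array — alternative mean.
    sigma1_ : (2, 2) array — alternative covariance.
    loglik_trace_ : list of per-iteration log-likelihoods (non-decreasing).
    converged_ : bool
    n_iter_ : int
    """

    def __init__(
        self,
        tol: float = 1e-6,
        max_iter: int = 1000,
        pi0_init: float = 0.9,
        pi0_prior: float | None = None,
        mu_fallback: tuple[float, float] = (2.0, 2.0),
        ridge: float = 1e-6,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.pi0_init = pi0_init
        self.pi0_prior = pi0_prior
        self.mu_fallback = mu_fallback
        self.ridge = ridge

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "tol": self.tol,
            "max_iter": self.max_iter,
            "pi0_init": self.pi0_init,
            "pi0_prior": self.pi0_prior,
            "mu_fallback": self.mu_fallback,
            "ridge": self.ridge,
        }

    def set_params(self, **params) -> "BivariateMixtureFDR":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # ---------------------------------------------------------------------
    @staticmethod
    def _validate(z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if z.ndim != 2 or z.shape[1] != 2:
            raise InputError("z must be an (n, 2) array of z-score pairs")
        if z.shape[0] < 10:
            raise InputError("need at least 10 z-score pairs")
        if not np.all(np.isfinite(z)):
            raise InputError("z contains non-finite values")
        return z

    def _loglik(self, z, pi0, mu1, sigma1, prior: float) -> tuple[float, np.ndarray]:
        log0 = np.log(pi0 + 1e-320) + np.atleast_1d(_log_bvn_pdf(z, np.zeros(2), np.eye(2)))
        log1 = np.log(1 - pi0 + 1e-320) + np.atleast_1d(_log_bvn_pdf(z, mu1, sigma1))
        m = np.maximum(log0, log1)
        tot = m + np.log(np.exp(log0 - m) + np.exp(log1 - m))
        resp0 = np.exp(log0 - tot)
        return float(tot.sum() + prior * np.log(pi0 + 1e-320)), resp0

    def fit(self, z, y=None) -> "BivariateMixtureFDR":
        z = self._validate(z)
        prior = 0.1 * len(z) if self.pi0_prior is None else float(self.pi0_prior)
        pi0 = float(self.pi0_init)
        high = z[(z[:, 0] > 1) & (z[:, 1] > 1)]
        mu1 = high.mean(axis=0) if len(high) else np.asarray(self.mu_fallback, float)
        mu1 = np.maximum(mu1, 0.0)
        sigma1 = np.eye(2)

        trace: list[float] = []
        ll, resp0 = self._loglik(z, pi0, mu1, sigma1, prior)
        trace.append(ll)
        converged = False
        it = 0
        n = len(z)
        for it in range(1, self.max_iter + 1):
            w1 = 1.0 - resp0
            w1sum = w1.sum()
            if w1sum < 1e-12:
                converged = True
                break
            new_pi0 = float(np.clip((resp0.sum() + prior) / (n + prior), 0.0, 1.0))
            new_mu1 = np.maximum((w1[:, None] * z).sum(axis=0) / w1sum, 0.0)
            d = z - new_mu1
            new_sigma1 = (w1[:, None, None] * (d[:, :, None] * d[:, None, :])).sum(axis=0) / w1sum
            new_sigma1 += self.ridge * np.eye(2)
            new_ll, new_resp0 = self._loglik(z, new_pi0, new_mu1, new_sigma1, prior)
            if new_ll < trace[-1] - 1e-10:
                # clipped M-step would lower the likelihood: keep previous params
                converged = True
                break
            pi0, mu1, sigma1, resp0 = new_pi0, new_mu1, new_sigma1, new_resp0
            trace.append(new_ll)
            if new_ll - trace[-2] < self.tol:
                converged = True
                break

        self.pi0_raw_ = pi0
        self.mu1_ = mu1
        self.sigma1_ = sigma1
        self.loglik_trace_ = trace
        self.converged_ = converged
        self.n_iter_ = it

        # BIC gate: is the alternative component supported at all?
        ll_mix, _ = self._loglik(z, pi0, mu1, sigma1, 0.0)
        ll_null, _ = self._loglik(z, 1.0 - 1e-12, mu1, sigma1, 0.0)
        n_extra_params = 6  # weight, 2 mean, 3 covariance entries
        self.lrt_ = 2.0 * (ll_mix - ll_null)
        self.null_model_ = self.lrt_ <= n_extra_params * np.log(len(z))
        self.pi0_ = 1.0 if self.null_model_ else pi0
        return self

    def local_fdr(self, z) -> np.ndarray:
        """Posterior null probability at each z-pair."""
        z = np.asarray(z, dtype=float)
        _, resp0 = self._loglik(z, self.pi0_, self.mu1_, self.sigma1_, 0.0)
        return resp0

    def transform(self, z) -> np.ndarray:
        return self.local_fdr(z)

    def fit_transform(self, z, y=None) -> np.ndarray:
        return self.fit(z).transform(z)


def fit_mixture_em(
    z, tol: float = 1e-6, max_iter: int = 500, seed: int | None = None
) -> BivariateMixtureFDR:
    """Fit the two-component mixture; returns the fitted estimator.

    The fit is deterministic given the data (initialization is data-driven);
    ``seed`` is accepted for interface symmetry with the stochastic stages.
    """
    return BivariateMixtureFDR(tol=tol, max_iter=max_iter).fit(z)


def jl_fdr(
    z: pd.DataFrame, fit: BivariateMixtureFDR, level: float = 0.05
) -> pd.DataFrame:
    """Joint-local FDR over genes.

    ``z`` carries columns ``gene, z_dnm, z_cc``.  Genes are ranked by local
    FDR ascending; the JL-FDR at rank k is the mean local FDR of the top-k set
    (step-up averaging), which is non-decreasing in rank by construction.
    """
    if not getattr(fit, "converged_", False):
        raise InputError("mixture fit did not converge; pass converged fit or refit")
    lf = fit.local_fdr(z[["z_dnm", "z_cc"]].to_numpy())
    out = z.copy()
    out["local_fdr"] = lf
    out = out.sort_values("local_fdr", kind="mergesort").reset_index(drop=True)
    out["jl_fdr"] = out["local_fdr"].expanding().mean()
    # running mean of a sorted sequence is already non-decreasing
    out["significant"] = out["jl_fdr"] <= level
    return out


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise InputError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def predicted_risk_genes(fit: BivariateMixtureFDR, n_genes: int) -> int:
    """Number of panel genes predicted to ultimately prove significant."""
    return int(round((1.0 - fit.pi0_) * n_genes))
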