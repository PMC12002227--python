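"""Synthetic trio/singleton CHD cohorts with known ground truth.

The generator emulates the statistical structure of a targeted-panel rare
variant study: per-gene, per-class de novo mutation counts are Poisson under
class-specific mutabilities with fold-enrichment at designated risk genes;
parents carry very rare damaging alleles that are transmitted to probands
with probability 1/2 (non-risk genes) or an elevated transmission probability
(risk genes); controls carry the same alleles at the matching population
frequency with per-gene coverage masks; and proband cardiac/EC/NDD phenotype
labels are correlated with the causal-gene category.  Every simulated site is
unique unless site reuse is switched on, so the post-filter rarity thresholds
are satisfied by construction.

All randomness flows from a single NumPy generator keyed by the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import DAMAGING_CLASSES, FUNCTIONAL_CLASSES, InputError

__all__ = [
    "CohortConfig",
    "SimulatedCohort",
    "sample_mutabilities",
    "simulate_cohort",
    "CARDIAC_SUBTYPES",
]

#: Cardiac subtype labels with rough baseline frequencies in the cohort.
CARDIAC_SUBTYPES = ("CTD", "TOF", "LVO", "HLHS", "ASD", "AVC", "LAT", "other")
_SUBTYPE_BASELINE = np.array([0.15, 0.12, 0.18, 0.10, 0.15, 0.08, 0.07, 0.15])

#: Target mean total per-gene mutation probability per live birth.  Panel
#: genes are large, mutation-prone loci; 1e-4 per birth across all classes is
#: representative of such genes.
MEAN_TOTAL_MU = 1e-4

_CLASS_SHARE = {"synonymous": 0.30, "T-mis": 0.40, "D-mis": 0.20, "LOF": 0.10}

_AA = list("ARNDCEQGHILKMFPSTWYV")


@dataclass
class CohortConfig:
    """Study-condition parameters for one simulated cohort.

    Defaults mirror the real study's scale: 3,887 trios, 7,668 singleton
    probands, 133,743 diploid controls, 248 panel genes.  The damaging-class
    DNM enrichment default of 10x sits between the reported LOF (14.3x) and
    D-mis (6.1x) panel-wide enrichments; the transmission probability default
    of 0.78 matches the observed LOF transmitted fraction.
    """

    n_trios: int = 3887
    n_singletons: int = 7668
    n_controls: int = 133743
    n_genes: int = 248
    risk_gene_fraction: float = 0.25
    dnm_enrichment: float = 10.0
    transmission_prob: float = 0.78
    carrier_freq: float = 5e-4
    coverage_fraction_range: tuple[float, float] = (0.9, 1.0)
    phenotype_concordance: float = 0.8
    site_reuse_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise InputError("n_genes must be >= 1")
        for name in ("risk_gene_fraction", "carrier_freq", "phenotype_concordance", "site_reuse_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {v}")
        if not 0.5 <= self.transmission_prob < 1.0:
            raise InputError("transmission_prob must be in [0.5, 1)")
        if self.dnm_enrichment < 1.0:
            raise InputError("dnm_enrichment must be >= 1")
        lo, hi = self.coverage_fraction_range
        if not (0.0 < lo <= hi <= 1.0):
            raise InputError("coverage_fraction_range must satisfy 0 < lo <= hi <= 1")


@dataclass
class SimulatedCohort:
    variants: pd.DataFrame
    pedigree: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: pd.DataFrame
    controls: pd.DataFrame
    coverage: pd.DataFrame
    mutability: pd.DataFrame
    config: CohortConfig


def sample_mutabilities(n_genes: int, seed: int, mean_total_mu: float = MEAN_TOTAL_MU) -> pd.DataFrame:
    """Draw a per-gene, per-class mutability table.

    Total per-gene mutability is log-normal with mean ``mean_total_mu``;
    class shares are Dirichlet around typical coding-consequence proportions,
    so synonymous + missense mass exceeds LOF mass on average.  Deterministic
    for a fixed seed.
    """
    if n_genes < 1:
        raise InputError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = 0.7
    # E[lognormal(m, s)] = exp(m + s^2/2)
    m = np.log(mean_total_mu) - sigma**2 / 2.0
    total = rng.lognormal(mean=m, sigma=sigma, size=n_genes)
    alpha = 40.0 * np.array([_CLASS_SHARE[c] for c in ("synonymous", "T-mis", "D-mis", "LOF")])
    shares = rng.dirichlet(alpha, size=n_genes)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    df = pd.DataFrame({"gene": genes})
    for j, c in enumerate(("synonymous", "T-mis", "D-mis", "LOF")):
        df[f"mu_{c}"] = total * shares[:, j]
    df["pli"] = rng.beta(0.4, 0.4, size=n_genes)
    # synthetic gene loci: one interval per gene (0-based half-open)
    df["chrom"] = [f"chr{(i % 22) + 1}" for i in range(n_genes)]
    df["start"] = (np.arange(n_genes) + 1) * 1_000_000
    df["end"] = df["start"] + 10_000
    return df


def _lof_consequence(rng: np.random.Generator) -> str:
    return rng.choice(["stopgain", "frameshift", "canonical-splice"])


class _SiteFactory:
    """Hands out variant sites within a gene locus, optionally reusing them."""

    def __init__(self, rng: np.random.Generator, reuse_prob: float):
        self.rng = rng
        self.reuse = reuse_prob
        self.used: dict[tuple[str, str], list[dict]] = {}
        self.offset: dict[str, int] = {}

    def site(self, gene: str, fclass: str, chrom: str, start: int) -> dict:
        key = (gene, fclass)
        prev = self.used.setdefault(key, [])
        if prev and self.rng.random() < self.reuse:
            return dict(prev[self.rng.integers(len(prev))])
        off = self.offset.get(gene, 0) + 1
        self.offset[gene] = off
        pos = start + off  # 1-based position inside the locus
        if fclass == "synonymous":
            cons, svm = "synonymous", None
        elif fclass == "T-mis":
            cons, svm = "missense", "T"
        elif fclass == "D-mis":
            cons, svm = "missense", "D"
        else:
            cons, svm = _lof_consequence(self.rng), None
        rec = {
            "chrom": chrom,
            "pos": int(pos),
            "ref": str(self.rng.choice(list("ACGT"))),
            "alt": str(self.rng.choice(list("ACGT"))),
            "consequence": cons,
            "metasvm": svm,
        }
        if cons == "missense":
            rec["protein_pos"] = int(off)
            rec["aa_ref"] = str(self.rng.choice(_AA))
            rec["aa_alt"] = str(self.rng.choice(_AA))
        else:
            rec["protein_pos"] = None
            rec["aa_ref"] = None
            rec["aa_alt"] = None
        prev.append(rec)
        return dict(rec)


def _make_pedigree(cfg: CohortConfig) -> pd.DataFrame:
    rows = []
    for i in range(cfg.n_trios):
        fam = f"F{i + 1:05d}"
        pro, fa, mo = f"{fam}-P", f"{fam}-F", f"{fam}-M"
        rows.append((fam, fa, "0", "0", 1, 1))
        rows.append((fam, mo, "0", "0", 2, 1))
        rows.append((fam, pro, fa, mo, 1, 2))
    for i in range(cfg.n_singletons):
        fam = f"S{i + 1:05d}"
        rows.append((fam, f"{fam}-P", "0", "0", 1, 2))
    return pd.DataFrame(
        rows, columns=["family_id", "individual_id", "father_id", "mother_id", "sex", "affected"]
    )


def simulate_cohort(config: CohortConfig, mutability: pd.DataFrame) -> SimulatedCohort:
    """Simulate one cohort plus matched controls under the configured truth."""
    cfg = config
    if len(mutability) != cfg.n_genes:
        raise InputError(
            f"mutability covers {len(mutability)} genes but config declares {cfg.n_genes}"
        )
    rng = np.random.default_rng(cfg.seed)
    genes = mutability["gene"].tolist()
    mu = {c: mutability[f"mu_{c}"].to_numpy(float) for c in ("synonymous", "T-mis", "D-mis", "LOF")}
    mu_dam = mu["D-mis"] + mu["LOF"]
    chrom = mutability["chrom"].tolist()
    start = mutability["start"].to_numpy(int)

    # ---- ground truth -----------------------------------------------------
    n_risk = int(round(cfg.risk_gene_fraction * cfg.n_genes))
    risk_idx = rng.choice(cfg.n_genes, size=n_risk, replace=False) if n_risk else np.array([], int)
    is_risk = np.zeros(cfg.n_genes, dtype=bool)
    is_risk[risk_idx] = True
    linked_subtype = np.array(["-"] * cfg.n_genes, dtype=object)
    linked_subtype[risk_idx] = rng.choice(CARDIAC_SUBTYPES[:-1], size=n_risk)
    ndd_assoc = np.zeros(cfg.n_genes, dtype=bool)
    ndd_assoc[risk_idx] = rng.random(n_risk) < 0.5

    # per-gene coverage masks
    lo, hi = cfg.coverage_fraction_range
    cov_cases = rng.uniform(lo, hi, size=cfg.n_genes)
    cov_controls = rng.uniform(lo, hi, size=cfg.n_genes)

    # per-gene, per-class parental heterozygote probability: scales with the
    # class mutability, averaging carrier_freq per gene over damaging classes
    mean_dam = float(mu_dam.mean())
    h = {c: np.minimum(cfg.carrier_freq * mu[c] / mean_dam, 0.05) for c in mu}

    n_probands = cfg.n_trios + cfg.n_singletons
    cohort_an_full = 2 * n_probands

    truth = pd.DataFrame(
        {
            "gene": genes,
            "is_risk": is_risk,
            "enrichment_D-mis": np.where(is_risk, cfg.dnm_enrichment, 1.0),
            "enrichment_LOF": np.where(is_risk, cfg.dnm_enrichment, 1.0),
            "transmission_prob": np.where(is_risk, cfg.transmission_prob, 0.5),
            "linked_subtype": linked_subtype,
            "ndd_assoc": ndd_assoc,
            "carrier_h_damaging": cfg.carrier_freq * mu_dam / mean_dam,
        }
    )

    pedigree = _make_pedigree(cfg)
    trio_fams = [f"F{i + 1:05d}" for i in range(cfg.n_trios)]
    singleton_ids = [f"S{i + 1:05d}-P" for i in range(cfg.n_singletons)]

    factory = _SiteFactory(rng, cfg.site_reuse_prob)
    rows: list[dict] = []

    def emit(g: int, fclass: str, origin: str, sample_id: str, family_id: str) -> None:
        rec = factory.site(genes[g], fclass, chrom[g], int(start[g]))
        rec.update(
            gene=genes[g],
            maf_bravo=0.0,
            maf_esp=0.0,
            maf_gnomad=0.0,
            cohort_ac=1,
            cohort_an=cohort_an_full,
            origin=origin,
            sample_id=sample_id,
            family_id=family_id,
            fclass=fclass,
        )
        rows.append(rec)

    for g in range(cfg.n_genes):
        for fclass in ("synonymous", "T-mis", "D-mis", "LOF"):
            enrich = (
                cfg.dnm_enrichment
                if is_risk[g] and fclass in DAMAGING_CLASSES
                else 1.0
            )
            tau = cfg.transmission_prob if is_risk[g] and fclass in DAMAGING_CLASSES else 0.5

            # de novo mutations in trio probands
            k_dnm = rng.poisson(cfg.n_trios * mu[fclass][g] * enrich)
            for fam_i in rng.integers(cfg.n_trios, size=k_dnm):
                fam = trio_fams[fam_i]
                emit(g, fclass, "de_novo", f"{fam}-P", fam)

            # parental heterozygous alleles in trios
            n_par = rng.binomial(2 * cfg.n_trios, h[fclass][g])
            if n_par:
                slots = rng.choice(2 * cfg.n_trios, size=min(n_par, 2 * cfg.n_trios), replace=False)
                transmitted = rng.random(len(slots)) < tau
                for slot, tr in zip(slots, transmitted):
                    fam = trio_fams[slot // 2]
                    parent = f"{fam}-F" if slot % 2 == 0 else f"{fam}-M"
                    if tr:
                        emit(g, fclass, "transmitted", f"{fam}-P", fam)
                    else:
                        emit(g, fclass, "untransmitted_parental", parent, fam)

            # unphased alleles in singleton probands: carrier prob 2 h tau
            p_carry = min(2.0 * h[fclass][g] * tau, 1.0)
            k_single = rng.binomial(cfg.n_singletons, p_carry)
            if k_single:
                for si in rng.choice(cfg.n_singletons, size=k_single, replace=False):
                    sid = singleton_ids[si]
                    emit(g, fclass, "unphased", sid, sid[:-2])

    variants = pd.DataFrame(rows)
    if len(variants) == 0:
        from .records import VARIANT_COLUMNS

        variants = pd.DataFrame(columns=VARIANT_COLUMNS + ["fclass"])
    else:
        # recurrent sites share an allele count within the cohort
        ac = variants.groupby(["chrom", "pos", "ref", "alt"])["gene"].transform("size")
        variants["cohort_ac"] = ac.astype(int)
        from .records import VARIANT_COLUMNS

        variants = variants[VARIANT_COLUMNS + ["fclass"]].reset_index(drop=True)

    # ---- control allele counts -------------------------------------------
    ctrl_rows = []
    for g in range(cfg.n_genes):
        an_g = max(1, int(np.floor(2 * cfg.n_controls * cov_controls[g] + 0.5)))
        for fclass in ("synonymous", "T-mis", "D-mis", "LOF"):
            q = h[fclass][g] / 2.0  # population allele frequency per chromosome
            ctrl_rows.append(
                {
                    "gene": genes[g],
                    "fclass": fclass,
                    "ctrl_ac": int(rng.binomial(an_g, q)),
                    "ctrl_an": an_g,
                }
            )
    controls = pd.DataFrame(ctrl_rows)

    coverage = pd.DataFrame(
        {
            "gene": genes,
            "callable_fraction_cases": cov_cases,
            "callable_fraction_controls": cov_controls,
        }
    )

    # ---- phenotypes -------------------------------------------------------
    proband_ids = [f"{f}-P" for f in trio_fams] + singleton_ids
    dam = variants[
        variants["fclass"].isin(DAMAGING_CLASSES)
        & variants["origin"].isin(["de_novo", "transmitted", "unphased"])
    ]
    risk_genes = set(np.array(genes)[is_risk])
    carrier_gene: dict[str, str] = {}
    for r in dam.itertuples():
        if r.gene in risk_genes and r.sample_id not in carrier_gene:
            carrier_gene[r.sample_id] = r.gene
    gene_to_subtype = dict(zip(genes, linked_subtype))
    gene_to_ndd = dict(zip(genes, ndd_assoc))

    subtypes = rng.choice(CARDIAC_SUBTYPES, size=len(proband_ids), p=_SUBTYPE_BASELINE)
    ec = rng.random(len(proband_ids)) < 0.25
    ndd = rng.random(len(proband_ids)) < 0.18
    for i, pid in enumerate(proband_ids):
        g = carrier_gene.get(pid)
        if g is None:
            continue
        if rng.random() < cfg.phenotype_concordance:
            subtypes[i] = gene_to_subtype[g]
        if gene_to_ndd[g]:
            ndd[i] = rng.random() < 0.7
            ec[i] = rng.random() < 0.4
    phenotypes = pd.DataFrame(
        {
            "proband_id": proband_ids,
            "cardiac_subtype": subtypes,
            "ec": ec.astype(int),
            "ndd": ndd.astype(int),
        }
    )

    return SimulatedCohort(
        variants=variants,
        pedigree=pedigree,
        phenotypes=phenotypes,
        truth=truth,
        controls=controls,
        coverage=coverage,
        mutability=mutability,
        config=cfg,
    )
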