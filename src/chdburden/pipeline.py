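"""End-to-end orchestration: filter -> aggregate -> burden -> meta -> TDT.

``analyze_cohort`` runs the full statistical pipeline on in-memory tables and
returns a results bundle; ``run_pipeline`` wraps it with file I/O, logging and
a JSON summary for the command line.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import case_control, dnm, filters, meta, tdt
from .records import DAMAGING_CLASSES, FilterThresholds, InputError

__all__ = ["PipelineResult", "analyze_cohort", "run_pipeline"]

log = logging.getLogger("chdburden")


@dataclass
class PipelineResult:
    counts: pd.DataFrame
    burden: pd.DataFrame  # per gene: DNM / case-control / meta / TDT columns
    qq: pd.DataFrame
    rejects: pd.DataFrame
    mixture: "meta.BivariateMixtureFDR"
    summary: dict


def _class_counts(counts: pd.DataFrame, genes: list[str], classes: list[str]) -> pd.DataFrame:
    sel = counts[counts["fclass"].isin(classes)]
    agg = sel.groupby("gene")[["n_dnm", "case_ac", "T", "U", "n_unphased"]].sum()
    return agg.reindex(genes, fill_value=0).astype(int)


def analyze_cohort(
    variants: pd.DataFrame,
    mutability: pd.DataFrame,
    controls: pd.DataFrame,
    coverage: pd.DataFrame,
    n_trios: int,
    n_singletons: int,
    thresholds: FilterThresholds | None = None,
    fdr_level: float = 0.05,
    phenotypes: pd.DataFrame | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the damaging-variant burden pipeline on one cohort.

    The headline analysis pools D-mis and LOF ("damaging"); synonymous and
    T-mis streams are carried through as negative controls for the QQ/lambda
    diagnostics.
    """
    n_probands = n_trios + n_singletons
    genes = mutability["gene"].tolist()
    rng = np.random.default_rng(seed)  # randomized PIT for the z-transforms

    classified = filters.classify_frame(variants.drop(columns=["fclass"], errors="ignore"))
    filtered = filters.filter_very_rare(classified, thresholds)
    counts, rejects = filters.aggregate_counts(filtered, genes)
    counts = filters.complete_counts(counts, genes)

    cov = coverage.set_index("gene").reindex(genes)
    cov_cases = cov["callable_fraction_cases"].fillna(1.0).to_numpy(float)

    mu_dam = dnm.damaging_mu(mutability).reindex(genes).to_numpy(float)
    ctrl_dam = (
        controls[controls["fclass"].isin(DAMAGING_CLASSES)]
        .groupby("gene")
        .agg(ctrl_ac=("ctrl_ac", "sum"), ctrl_an=("ctrl_an", "max"))
        .reindex(genes, fill_value=0)
    )

    streams = {
        "damaging": list(DAMAGING_CLASSES),
        "synonymous": ["synonymous"],
        "T-mis": ["T-mis"],
    }
    per_stream: dict[str, pd.DataFrame] = {}
    qq_rows = []
    for stream, classes in streams.items():
        cc = _class_counts(counts, genes, classes)
        if stream == "damaging":
            mu_s = mu_dam
        else:
            mu_s = mutability.set_index("gene")[f"mu_{classes[0]}"].reindex(genes).to_numpy(float)
        expected = n_trios * mu_s
        p_dnm = np.array(
            [dnm.poisson_burden(o, n_trios, m).p for o, m in zip(cc["n_dnm"], mu_s)]
        )
        ctrl_s = (
            controls[controls["fclass"].isin(classes)]
            .groupby("gene")
            .agg(ctrl_ac=("ctrl_ac", "sum"), ctrl_an=("ctrl_an", "max"))
            .reindex(genes, fill_value=0)
        )
        tuv_ac = (cc["case_ac"] - cc["n_dnm"]).clip(lower=0).to_numpy()
        case_an = np.array(
            [case_control.coverage_adjust(2 * n_probands, f) for f in cov_cases]
        )
        ctrl_an = np.maximum(ctrl_s["ctrl_an"].to_numpy(int), 1)
        ctrl_ac_arr = ctrl_s["ctrl_ac"].to_numpy(int)
        p_cc = case_control.fet_burden_vec(tuv_ac, case_an, ctrl_ac_arr, ctrl_an)
        p_dnm_mid = dnm.poisson_randp(cc["n_dnm"].to_numpy(), expected, rng)
        p_cc_mid = case_control.fet_randp_vec(tuv_ac, case_an, ctrl_ac_arr, ctrl_an, rng)
        p_fisher = np.array(
            [
                meta.fishers_method(max(a, meta.P_FLOOR), max(b, meta.P_FLOOR))
                for a, b in zip(p_dnm, p_cc)
            ]
        )
        df = pd.DataFrame(
            {
                "gene": genes,
                "stream": stream,
                "n_dnm": cc["n_dnm"].to_numpy(),
                "expected_dnm": expected,
                "enrichment_dnm": np.divide(
                    cc["n_dnm"], expected, out=np.zeros(len(genes)), where=expected > 0
                ),
                "tuv_ac": tuv_ac,
                "case_an": case_an,
                "ctrl_ac": ctrl_ac_arr,
                "ctrl_an": ctrl_an,
                "T": cc["T"].to_numpy(),
                "U": cc["U"].to_numpy(),
                "p_dnm": p_dnm,
                "p_cc": p_cc,
                "p_dnm_rand": p_dnm_mid,
                "p_cc_rand": p_cc_mid,
                "p_fisher": p_fisher,
            }
        )
        per_stream[stream] = df
        qq = dnm.qq_summary(p_fisher, n_probands)
        qq["stream"] = stream
        qq_rows.append((stream, qq))

    dam = per_stream["damaging"].copy()
    # randomized transforms: exact-uniform null despite discrete counts
    dam["z_dnm"] = [meta.p_to_z(min(max(p, meta.P_FLOOR), 1.0)) for p in dam["p_dnm_rand"]]
    dam["z_cc"] = [meta.p_to_z(min(max(p, meta.P_FLOOR), 1.0)) for p in dam["p_cc_rand"]]
    fit = meta.BivariateMixtureFDR().fit(dam[["z_dnm", "z_cc"]].to_numpy())
    ranked = meta.jl_fdr(dam, fit, level=fdr_level)
    ranked["q_bh_dnm"] = meta.bh_fdr(np.maximum(ranked["p_dnm"], meta.P_FLOOR))
    ranked["q_bh_cc"] = meta.bh_fdr(np.maximum(ranked["p_cc"], meta.P_FLOOR))

    # per-gene TDT on damaging transmissions
    chi2 = np.zeros(len(ranked))
    p_tdt = np.ones(len(ranked))
    informative = (ranked["T"] + ranked["U"]).to_numpy() > 0
    tu = ranked.loc[informative]
    chi2[informative] = ((tu["T"] - tu["U"]) ** 2 / (tu["T"] + tu["U"])).to_numpy()
    from scipy import stats as _st

    p_tdt[informative] = _st.chi2.sf(chi2[informative], 1)
    ranked["chi2_tdt"] = chi2
    ranked["p_tdt"] = p_tdt

    sig_genes = ranked.loc[ranked["significant"], "gene"].tolist()

    # ---- attributable fractions ------------------------------------------
    sig = ranked[ranked["significant"]]
    af_dnm = float(((sig["n_dnm"] - sig["expected_dnm"]).clip(lower=0) / n_trios).sum())
    af_cc = float(
        sum(
            case_control.attributable_fraction_cc(a, b, c, d)
            for a, b, c, d in zip(sig["tuv_ac"], sig["case_an"], sig["ctrl_ac"], sig["ctrl_an"])
        )
    )
    af_tdt = (
        float(((sig["T"] - (sig["T"] + sig["U"]) / 2).clip(lower=0) / n_trios).sum())
        if n_trios
        else 0.0
    )

    # combined: each proband counted once even with hits in two genes
    carriers = filtered[
        filtered["gene"].isin(sig_genes)
        & filtered["fclass"].isin(DAMAGING_CLASSES)
        & filtered["origin"].isin(["de_novo", "transmitted", "unphased"])
    ]["sample_id"].nunique()
    expected_bg = float(
        (sig["expected_dnm"]).sum()
        + (2 * (sig["ctrl_ac"] / sig["ctrl_an"]) * n_probands).sum()
    )
    af_combined = max(0.0, (carriers - expected_bg) / n_probands)
    af_combined = min(af_combined, af_dnm + af_cc + af_tdt, 1.0)

    panel_tdt = tdt.geneset_tdt(counts, genes, "damaging", n_trios) if (
        counts[counts["fclass"].isin(DAMAGING_CLASSES)][["T", "U"]].to_numpy().sum() > 0
    ) else None

    summary = {
        "n_genes": len(genes),
        "n_trios": n_trios,
        "n_singletons": n_singletons,
        "n_significant_genes": len(sig_genes),
        "significant_genes": sig_genes,
        "pi0": fit.pi0_,
        "predicted_risk_genes": meta.predicted_risk_genes(fit, len(genes)),
        "attributable_fraction_dnm": af_dnm,
        "attributable_fraction_cc": af_cc,
        "attributable_fraction_tdt": af_tdt,
        "attributable_fraction_combined": af_combined,
        "panel_tdt_transmitted_fraction": panel_tdt.transmitted_fraction if panel_tdt else None,
        "panel_tdt_p": panel_tdt.p if panel_tdt else None,
        "lambda_1000": {
            stream: float(qq.attrs["lambda_1000"]) for stream, qq in qq_rows
        },
        "expected_multihit_genes": dnm.expected_multihit_genes(mutability, n_trios, 2),
    }
    qq_all = pd.concat([q for _, q in qq_rows], ignore_index=True)
    return PipelineResult(
        counts=counts, burden=ranked, qq=qq_all, rejects=rejects, mixture=fit, summary=summary
    )


def run_pipeline(config) -> Path:
    """File-level pipeline: read inputs per config, analyze, write outputs.

    Writes burden.tsv, counts.tsv, qq.tsv, rejects.tsv, summary.json and a
    run.log into ``config.outdir``; returns the output directory.  Outputs are
    byte-identical for identical config and inputs.
    """
    from . import io as cio

    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info(
            "thresholds: max_pop_maf=%g max_cohort_maf=%g fdr=%g seed=%d",
            config.max_pop_maf,
            config.max_cohort_maf,
            config.fdr_level,
            config.seed,
        )
        variants = cio.read_variants(config.variants)
        ped = cio.read_pedigree(config.pedigree)
        mutability = cio.read_table(config.mutability)
        controls = cio.read_table(config.controls)
        coverage = (
            cio.read_table(config.coverage)
            if config.coverage
            else pd.DataFrame({"gene": mutability["gene"], "callable_fraction_cases": 1.0})
        )
        phenotypes = cio.read_table(config.phenotypes) if config.phenotypes else None
        thresholds = FilterThresholds(config.max_pop_maf, config.max_cohort_maf)
        result = analyze_cohort(
            variants,
            mutability,
            controls,
            coverage,
            n_trios=ped.attrs["n_trios"],
            n_singletons=ped.attrs["n_singletons"],
            thresholds=thresholds,
            fdr_level=config.fdr_level,
            phenotypes=phenotypes,
            seed=config.seed,
        )
        cio.write_table(result.burden, outdir / "burden.tsv")
        cio.write_table(result.counts, outdir / "counts.tsv")
        cio.write_table(result.qq, outdir / "qq.tsv")
        cio.write_table(result.rejects, outdir / "rejects.tsv")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(result.summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log.info("wrote results to %s", outdir)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        log.error("pipeline failed: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
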