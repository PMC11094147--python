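"""End-to-end orchestration of the QMP analysis stages.

The canonical stage order: contaminant removal against negative extraction
controls -> rare-ASV filter -> 16S copy-number correction -> qPCR load
estimation -> QMP rarefaction -> diversity / permutation statistics ->
genus associations -> survival classification -> DWV delta-Ct analysis.
"""

from __future__ import annotations

from . import association, classify, diversity, permutation, preprocess, qmp
from .datamodel import (
    CopyNumberMap,
    CountMatrix,
    CtTable,
    PipelineConfig,
    QMPMatrix,
    SampleTable,
    TaxonomyTable,
)

__all__ = ["preprocess_stage", "qmp_stage", "run_all"]


def preprocess_stage(
    counts: CountMatrix,
    samples: SampleTable,
    taxonomy: TaxonomyTable,
    copy_numbers: CopyNumberMap,
    config: PipelineConfig | None = None,
) -> dict:
    """Contaminant flagging, control/rare removal, copy-number correction."""
    config = config or PipelineConfig()
    contaminant_report = preprocess.flag_contaminants(
        counts, samples, alpha=config.contaminant_alpha
    )
    bee_ids = [s for s in samples.bee_ids if s in counts.data.index]
    decontaminated = counts.drop_asvs(
        contaminant_report.removed("removed_contaminant")
    ).select_samples(bee_ids)
    filtered, rare_report = preprocess.filter_rare(
        decontaminated, min_count=config.min_count, min_prevalence=config.min_prevalence
    )
    corrected = preprocess.copy_number_correct(filtered, taxonomy, copy_numbers)
    return {
        "contaminant_report": contaminant_report,
        "rare_report": rare_report,
        "filtered": filtered,
        "corrected": corrected,
        "bee_samples": samples.select(bee_ids),
    }


def qmp_stage(
    corrected: CountMatrix, ct: CtTable, config: PipelineConfig | None = None
) -> dict:
    """Bacterial load from Ct values, then rarefaction to even sampling depth."""
    config = config or PipelineConfig()
    loads = qmp.load_from_ct(ct, efficiency=config.qpcr_efficiency)
    profile = qmp.qmp_rarefy(
        corrected,
        loads,
        n_reps=config.rarefaction_replicates,
        seed=config.seed,
    )
    return {"loads": loads, "qmp": profile}


def run_all(
    counts: CountMatrix,
    samples: SampleTable,
    taxonomy: TaxonomyTable,
    copy_numbers: CopyNumberMap,
    ct: CtTable,
    tree=None,
    config: PipelineConfig | None = None,
) -> dict:
    """Run every analysis stage and return a nested results dictionary."""
    config = config or PipelineConfig()
    results: dict = {"config": config}

    pre = preprocess_stage(counts, samples, taxonomy, copy_numbers, config)
    results["preprocess"] = pre
    bee_samples: SampleTable = pre["bee_samples"]

    qmp_res = qmp_stage(pre["corrected"], ct, config)
    results["qmp"] = qmp_res
    profile: QMPMatrix = qmp_res["qmp"]

    # --- diversity -------------------------------------------------------
    alpha = diversity.alpha_diversity(profile)
    alpha_anova = {
        metric: association.nested_anova(alpha[metric], bee_samples)
        for metric in ("H", "D", "J")
    }
    distances = {
        "bray_curtis": diversity.bray_curtis(profile),
        "jaccard": diversity.jaccard_quant(profile),
    }
    if tree is not None:
        distances["wunifrac"] = diversity.weighted_unifrac(profile, tree)
    perm_tests = {
        name: permutation.permanova(
            dm, bee_samples, n_perm=config.n_permutations, seed=config.seed
        )
        for name, dm in distances.items()
    }
    disp_tests = {
        name: permutation.permdisp(
            dm,
            bee_samples.factor("condition", list(dm.ids)),
            n_perm=min(config.n_permutations, 999),
            seed=config.seed,
        )
        for name, dm in distances.items()
    }
    ordination = diversity.nmds(
        distances.get("wunifrac", distances["bray_curtis"]), seed=config.seed
    )
    results["diversity"] = {
        "alpha": alpha,
        "alpha_anova": alpha_anova,
        "distances": distances,
        "permanova": perm_tests,
        "permdisp": disp_tests,
        "nmds": ordination,
    }

    # --- associations ----------------------------------------------------
    genus_abund = association.pool_by_genus(profile, taxonomy)
    results["association"] = {
        "genus_abundance": genus_abund,
        "genus_anova": association.genus_anova(genus_abund, bee_samples),
        "total_abundance_anova": association.nested_anova(
            profile.totals(), bee_samples
        ),
        "indval": association.indval(
            profile,
            bee_samples,
            n_perm=min(config.n_permutations, 999),
            seed=config.seed,
        ),
    }

    # --- DWV -------------------------------------------------------------
    try:
        dwv = association.dwv_delta_ct(ct)
        results["dwv"] = {
            "table": dwv,
            "anova": association.dwv_anova(dwv, bee_samples),
        }
    except ValueError:
        results["dwv"] = None

    # --- classification --------------------------------------------------
    X, y = classify.build_features(genus_abund, bee_samples)
    ml_results = classify.run_models(
        X,
        y,
        n_seeds=config.ml_seeds,
        train_frac=config.ml_train_frac,
        seed0=config.seed,
    )
    summary = classify.feature_importance(X, y, ml_results, mode="coefficients")
    ml = {
        "results": ml_results,
        "median_auroc": summary.median_auroc,
        "coefficients": summary.coefficients,
    }
    # rerun excluding the all-survived location's samples, if one exists
    hives = bee_samples.hives
    frac_survived = (
        hives.assign(s=hives["condition"] == "survived").groupby("location")["s"].mean()
    )
    all_survived = frac_survived[frac_survived == 1.0].index.tolist()
    if all_survived and len(frac_survived) > 1:
        keep = [
            s
            for s in genus_abund.sample_ids
            if bee_samples.data.loc[s, "location"] not in all_survived
        ]
        X2, y2 = classify.build_features(
            genus_abund.select_samples(keep), bee_samples.select(keep)
        )
        if y2.nunique() == 2:
            sub = classify.run_models(
                X2,
                y2,
                n_seeds=config.ml_seeds,
                train_frac=config.ml_train_frac,
                models=("l2_logistic",),
                seed0=config.seed,
            )
            ml["median_auroc_excluding"] = {
                "locations": all_survived,
                **classify.summarize_auroc(sub),
            }
    results["classify"] = ml
    return results
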