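"""Contaminant flagging, rare-ASV prevalence filter, 16S copy-number correction.

Stage order in the standard pipeline: contaminant removal (against negative
extraction controls) -> rare filter -> copy-number correction.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .datamodel import CopyNumberMap, CountMatrix, FilterReport, SampleTable, TaxonomyTable

__all__ = ["flag_contaminants", "filter_rare", "copy_number_correct"]


def flag_contaminants(
    counts: CountMatrix, samples: SampleTable, alpha: float = 0.05
) -> FilterReport:
    """Flag ASVs significantly more prevalent in negative controls than bees.

    For each ASV a one-sided Fisher exact test is run on the 2x2
    presence/absence table (controls vs bee samples); ASVs whose prevalence
    is significantly higher in controls at ``alpha`` are flagged
    ``removed_contaminant``.  Presence means count > 0.
    """
    controls = [s for s in samples.control_ids if s in counts.data.index]
    bees = [s for s in samples.bee_ids if s in counts.data.index]
    if not controls:
        raise ValueError(
            "no negative controls in the count matrix; to run without "
            "decontamination, skip this stage explicitly"
        )
    if not bees:
        raise ValueError("no bee samples in the count matrix")
    present = counts.data > 0
    rows = []
    for asv in counts.asv_ids:
        c_pres = int(present.loc[controls, asv].sum())
        b_pres = int(present.loc[bees, asv].sum())
        table = [[c_pres, len(controls) - c_pres], [b_pres, len(bees) - b_pres]]
        if c_pres == 0:
            p = 1.0  # one-sided: never flag ASVs absent from controls
        else:
            p = float(fisher_exact(table, alternative="greater")[1])
        rows.append(
            {
                "asv_id": asv,
                "decision": "removed_contaminant" if p < alpha else "kept",
                "prevalence_controls": c_pres / len(controls),
                "prevalence_bees": b_pres / len(bees),
                "p_value": p,
            }
        )
    return FilterReport(pd.DataFrame(rows).set_index("asv_id"))


def filter_rare(
    counts: CountMatrix, min_count: int = 3, min_prevalence: float = 0.20
) -> tuple[CountMatrix, FilterReport]:
    """Drop rare ASVs: retain an ASV iff it is detected with more than
    ``min_count`` reads in at least ``min_prevalence`` of the samples.

    The sample threshold is ``ceil(min_prevalence * n_samples)`` and the
    boundary counts (>= threshold samples) retains.  Requires raw integer
    counts.
    """
    if not counts.is_integer:
        raise ValueError("rare-ASV filter requires an integer count matrix")
    n = counts.shape[0]
    threshold = math.ceil(min_prevalence * n)
    detected = (counts.data > min_count).sum(axis=0)
    keep = detected >= threshold
    report = FilterReport(
        pd.DataFrame(
            {
                "decision": np.where(keep, "kept", "removed_rare"),
                "n_detected": detected.astype(int),
                "sample_threshold": threshold,
            },
            index=counts.data.columns,
        )
    )
    kept = [a for a, k in zip(counts.asv_ids, keep) if k]
    if not kept:
        raise ValueError("rare filter removed every ASV")
    return counts.select_asvs(kept), report


def copy_number_correct(
    counts: CountMatrix, tax: TaxonomyTable, cn: CopyNumberMap
) -> CountMatrix:
    """Weight ASV counts by 16S copy number, then rescale per sample.

    Each count is divided by its genus's 16S copy number (high-copy taxa are
    down-weighted), then every sample's weighted counts are scaled so the
    per-sample total equals the original read total exactly.  Zero-total
    samples pass through unchanged.
    """
    genus = tax.genus_of(counts.asv_ids)
    cn_per_asv = cn.of(genus).to_numpy(dtype=float)
    x = counts.values
    w = x / cn_per_asv[None, :]
    orig_tot = x.sum(axis=1)
    w_tot = w.sum(axis=1)
    scale = np.divide(orig_tot, w_tot, out=np.ones_like(orig_tot), where=w_tot > 0)
    corrected = w * scale[:, None]
    zero = orig_tot == 0
    if zero.any():
        corrected[zero] = x[zero]
    return CountMatrix(
        pd.DataFrame(corrected, index=counts.data.index, columns=counts.data.columns)
    )
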