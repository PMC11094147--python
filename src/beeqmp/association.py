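"""Taxon-outcome association: genus pooling, nested two-way ANOVA,
indicator-value (IndVal) analysis with permutation, Benjamini-Hochberg
correction, and deformed-wing-virus delta-Ct analysis.

Bees are pseudo-replicates of their hive: the nested ANOVA therefore
aggregates responses to hive means by default (hives are the independent
units), with a bee-level variant using hive as the error stratum available
for sensitivity analysis.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from statsmodels.stats.multitest import multipletests

from ._rng import substream
from .datamodel import CountMatrix, CtTable, SampleTable, TaxonomyTable, DWV_ASSAYS
from .permutation import sequential_ss_projectors

__all__ = [
    "pool_by_genus",
    "nested_anova",
    "genus_anova",
    "indval",
    "bh_adjust",
    "dwv_delta_ct",
    "dwv_anova",
    "AnovaResult",
]


def pool_by_genus(abund: CountMatrix, tax: TaxonomyTable) -> CountMatrix:
    """Sum ASV columns within genus; per-sample totals are preserved."""
    genus = tax.genus_of(abund.asv_ids)
    pooled = abund.data.T.groupby(genus.to_numpy()).sum().T
    pooled = pooled[sorted(pooled.columns)]
    return CountMatrix(pooled)


@dataclass
class AnovaResult:
    """Sequential ANOVA table (df, SS, MS, F, p per term) plus model label."""

    table: pd.DataFrame
    model: str

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p_value"])


def _sequential_anova(y: np.ndarray, meta: pd.DataFrame, factors) -> pd.DataFrame:
    names, projectors, residual_projector, dfs, residual_df = sequential_ss_projectors(
        meta, factors
    )
    rows = []
    ss_res = float(y @ residual_projector @ y)
    ms_res = ss_res / residual_df if residual_df > 0 else np.nan
    tol = 1e-12 * max(1.0, float(y @ y))  # scale-relative zero-variance guard
    for name, P, df in zip(names, projectors, dfs):
        ss = float(y @ P @ y)
        if df > 0 and residual_df > 0 and ms_res > tol:
            F = (ss / df) / ms_res
            p = float(f_dist.sf(F, df, residual_df))
        elif df > 0 and residual_df > 0:
            F, p = (0.0, 1.0) if ss <= tol else (np.inf, 0.0)
        else:
            F, p = np.nan, np.nan
        rows.append({"term": name, "df": df, "SS": ss, "MS": ss / df if df else np.nan,
                     "F": F, "p_value": p})
    rows.append({"term": "Residual", "df": residual_df, "SS": ss_res,
                 "MS": ms_res, "F": np.nan, "p_value": np.nan})
    return pd.DataFrame(rows).set_index("term")


def nested_anova(
    y: pd.Series, samples: SampleTable, level: str = "hive"
) -> AnovaResult:
    """Two-way ANOVA of a per-sample response on condition and location.

    ``level='hive'`` (default): bee responses are averaged to hive means,
    the nesting unit, before fitting condition + location + interaction with
    sequential SS.  ``level='bee'`` fits at the bee level with hive as the
    error stratum for the hive-level terms.  If a condition x location cell
    has no hives, the interaction is dropped with a warning.
    """
    meta = samples.data.loc[y.index]
    if (meta["role"] != "bee").any():
        bad = meta.index[meta["role"] != "bee"].tolist()
        raise ValueError(f"non-bee sample(s) in ANOVA response: {bad}")
    hives = samples.hives.loc[sorted(meta["hive_id"].unique())]
    cells = hives.groupby(["condition", "location"]).size()
    full_grid = hives["condition"].nunique() * hives["location"].nunique()
    factors: list = ["condition", "location"]
    n_main = hives["condition"].nunique() + hives["location"].nunique() - 1
    if len(cells) <= n_main:
        # observed cells add no rank beyond the main effects
        warnings.warn("condition x location interaction dropped: empty cells leave no df")
    else:
        factors.append(("condition", "location"))
        if len(cells) < full_grid:
            warnings.warn(
                "condition x location cell(s) without hives; interaction df reduced"
            )

    if level == "hive":
        hive_means = y.groupby(meta["hive_id"]).mean()
        table = _sequential_anova(
            hive_means.to_numpy(dtype=float), hives.loc[hive_means.index], factors
        )
        return AnovaResult(table=table, model="hive-means two-way ANOVA")
    if level == "bee":
        table = _sequential_anova(
            y.to_numpy(dtype=float), meta, factors + ["hive_id"]
        )
        # retest hive-level terms against the hive (within-cell) stratum
        hive_row = table.loc["hive_id"]
        ms_hive = hive_row["MS"]
        for term in [t for t in table.index if t not in ("hive_id", "Residual")]:
            df_t = table.loc[term, "df"]
            if df_t > 0 and hive_row["df"] > 0 and ms_hive > 0:
                F = table.loc[term, "MS"] / ms_hive
                table.loc[term, "F"] = F
                table.loc[term, "p_value"] = float(
                    f_dist.sf(F, df_t, hive_row["df"])
                )
        return AnovaResult(table=table, model="bee-level ANOVA, hive error stratum")
    raise ValueError(f"unknown level {level!r}")


def genus_anova(
    genus_abund: CountMatrix,
    samples: SampleTable,
    level: str = "hive",
    log_transform: bool = False,
) -> pd.DataFrame:
    """Per-genus nested ANOVA with BH adjustment across genera.

    Condition and location p-values are BH-adjusted across genera (each term
    is its own family); the interaction is reported raw.
    """
    rows = {}
    for genus in genus_abund.asv_ids:
        y = genus_abund.data[genus]
        if log_transform:
            y = np.log1p(y)
        res = nested_anova(y, samples, level=level)
        t = res.table
        rows[genus] = {
            "p_condition": t.loc["condition", "p_value"],
            "p_location": t.loc["location", "p_value"],
            "p_interaction": (
                t.loc["condition:location", "p_value"]
                if "condition:location" in t.index
                else np.nan
            ),
        }
    out = pd.DataFrame(rows).T
    out["adj_p_condition"] = bh_adjust(out["p_condition"].to_numpy())
    out["adj_p_location"] = bh_adjust(out["p_location"].to_numpy())
    return out.sort_values("adj_p_condition")


def _indval_stats(
    X: np.ndarray, member: np.ndarray, presence: np.ndarray, group_correction: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IndVal A, B and statistic per (group, ASV) for one labeling.

    ``member``: (n_groups, n_samples) 0/1 matrix.  With
    ``group_correction`` (IndVal.g) specificity A uses group means,
    equalizing unbalanced group sizes.
    """
    sizes = member.sum(axis=1)
    sums = member @ X  # groups x asvs
    if group_correction:
        a_g = sums / sizes[:, None]
    else:
        a_g = sums
    denom = a_g.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, a_g / denom, 0.0)
    B = (member @ presence) / sizes[:, None]
    stat = np.sqrt(A * B)
    return A, B, stat


def indval(
    abund: CountMatrix,
    groups: pd.Series | SampleTable,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "sampled",
    group_correction: bool = True,
    presence_threshold: float = 0.0,
) -> pd.DataFrame:
    """Indicator-value analysis of each ASV for sample groups.

    For each ASV and group g: A (specificity) is the group-mean abundance
    share, B (fidelity) the within-group occurrence fraction, and
    IndVal = sqrt(A*B); the statistic is the maximum over groups, tested by
    permutation of group labels (BH-adjusted across ASVs).
    ``method='exact'`` enumerates every assignment of samples to groups of
    the observed sizes.
    """
    if isinstance(groups, SampleTable):
        labels = groups.factor("condition", abund.sample_ids)
    else:
        labels = groups.loc[abund.sample_ids]
    level_names = sorted(labels.unique())
    if len(level_names) < 2:
        raise ValueError("indval requires at least two non-empty groups")
    X = abund.values
    presence = (X > presence_threshold).astype(float)
    n = X.shape[0]
    member_obs = np.stack([(labels == g).to_numpy(float) for g in level_names])

    A, B, stat = _indval_stats(X, member_obs, presence, group_correction)
    best = stat.argmax(axis=0)
    obs = stat.max(axis=0)
    tol = 1e-12

    exceed = np.zeros(X.shape[1])
    if method == "exact":
        if len(level_names) != 2:
            raise ValueError("exact enumeration supports exactly two groups")
        n1 = int(member_obs[0].sum())
        total = 0
        for combo in itertools.combinations(range(n), n1):
            m = np.zeros((2, n))
            m[0, list(combo)] = 1.0
            m[1] = 1.0 - m[0]
            perm_stat = _indval_stats(X, m, presence, group_correction)[2].max(axis=0)
            exceed += perm_stat >= obs - tol
            total += 1
        p = exceed / total
        n_used = total
    elif method == "sampled":
        rng = substream(seed, "indval")
        for _ in range(int(n_perm)):
            idx = rng.permutation(n)
            m = member_obs[:, idx]
            perm_stat = _indval_stats(X, m, presence, group_correction)[2].max(axis=0)
            exceed += perm_stat >= obs - tol
        p = (1.0 + exceed) / (1.0 + n_perm)
        n_used = int(n_perm)
    else:
        raise ValueError(f"unknown method {method!r}")

    absent = X.sum(axis=0) <= 0
    p = np.where(absent, 1.0, p)
    out = pd.DataFrame(
        {
            "best_group": [level_names[b] for b in best],
            "A": A[best, np.arange(X.shape[1])],
            "B": B[best, np.arange(X.shape[1])],
            "stat": np.where(absent, 0.0, obs),
            "p_value": p,
        },
        index=abund.asv_ids,
    )
    out["adj_p"] = bh_adjust(out["p_value"].to_numpy())
    out.attrs["n_permutations"] = n_used
    out.attrs["method"] = method
    return out


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def dwv_delta_ct(ct: CtTable) -> pd.DataFrame:
    """Relative DWV abundance as delta-Ct = mean Ct_GAPDH - mean Ct_DWV.

    Triplicates are averaged per assay first; one row per sample x strain
    actually assayed.  Higher delta-Ct means more viral template.
    """
    gapdh = ct.mean_ct("GAPDH")
    if gapdh.empty:
        raise ValueError("no GAPDH assay in Ct table")
    rows = []
    seen = set()
    for assay in DWV_ASSAYS:
        strain = assay.split("_")[1]
        means = ct.mean_ct(assay)
        for sid, m in means.items():
            if sid not in gapdh.index:
                raise ValueError(f"sample {sid!r} has {assay} but no GAPDH assay")
            rows.append({"sample_id": sid, "strain": strain, "dct": gapdh[sid] - m})
            seen.add(sid)
    no_dwv = sorted(set(gapdh.index) - seen)
    if not rows:
        raise ValueError("no DWV assays in Ct table")
    if no_dwv:
        warnings.warn(f"sample(s) with GAPDH but no DWV assay: {no_dwv}")
    return pd.DataFrame(rows)


def dwv_anova(
    dwv: pd.DataFrame, samples: SampleTable, level: str = "hive"
) -> dict[str, AnovaResult]:
    """Nested two-way ANOVA of delta-Ct per DWV strain."""
    out = {}
    for strain, sub in dwv.groupby("strain"):
        y = sub.set_index("sample_id")["dct"]
        out[str(strain)] = nested_anova(y, samples, level=level)
    return out
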