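"""PERMANOVA (multi-factor, sequential sums of squares) and PERMDISP.

PERMANOVA follows the adonis partitioning: the distance matrix is
Gower-centered (G = -1/2 C D^2 C), sequential (Type I) sums of squares are
obtained by projecting G onto the nested sequence of dummy-coded model
matrices, and per-factor pseudo-F statistics are referred to a permutation
distribution obtained by relabeling samples.  An exhaustive-enumeration mode
is available for small n.  PERMDISP (homogeneity of multivariate
dispersions) delegates to scikit-bio's betadisper-style implementation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.distance import permdisp as _skbio_permdisp

from ._rng import substream
from .datamodel import SampleTable

__all__ = ["PermutationTestResult", "permanova", "permdisp", "sequential_ss_projectors"]

FactorSpec = Sequence[str | tuple[str, ...]]
DEFAULT_FACTORS: tuple = ("condition", "location", ("condition", "location"))


@dataclass
class PermutationTestResult:
    """Per-factor R^2, pseudo-F and permutation p, plus the residual row."""

    table: pd.DataFrame  # index: factors, Residual, Total
    n_permutations: int
    seed: int | None
    method: str

    def __post_init__(self):
        p = self.table["p_value"].dropna()
        if ((p <= 0) | (p > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")

    def p_value(self, factor: str) -> float:
        return float(self.table.loc[factor, "p_value"])

    def r_squared(self, factor: str) -> float:
        return float(self.table.loc[factor, "R2"])


def _term_name(term) -> str:
    return term if isinstance(term, str) else ":".join(term)


def _dummies(meta: pd.DataFrame, term) -> np.ndarray:
    if isinstance(term, str):
        codes = meta[term].astype(str)
    else:
        codes = meta[list(term)].astype(str).agg(":".join, axis=1)
    return pd.get_dummies(codes, dtype=float).to_numpy()


def sequential_ss_projectors(
    meta: pd.DataFrame, factors: FactorSpec
) -> tuple[list[str], list[np.ndarray], np.ndarray, list[int], int]:
    """Projection-matrix differences for a sequential (Type I) decomposition.

    Returns term names, per-term projector differences P_k = H_k - H_{k-1},
    the residual projector, per-term df (rank increments) and residual df.
    Terms whose columns are fully aliased by earlier ones get df 0 and a
    zero projector.
    """
    n = meta.shape[0]
    X = np.ones((n, 1))
    H_prev = np.full((n, n), 1.0 / n)
    rank_prev = 1
    names, projectors, dfs = [], [], []
    for term in factors:
        if isinstance(term, str) and meta[term].nunique() < 2:
            raise ValueError(f"factor {term!r} has a single level")
        X = np.hstack([X, _dummies(meta, term)])
        H = X @ np.linalg.pinv(X)
        rank = int(np.linalg.matrix_rank(X))
        names.append(_term_name(term))
        projectors.append(H - H_prev)
        dfs.append(rank - rank_prev)
        H_prev, rank_prev = H, rank
    residual_projector = np.eye(n) - H_prev
    residual_df = n - rank_prev
    return names, projectors, residual_projector, dfs, residual_df


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=0, keepdims=True)
    col = a.mean(axis=1, keepdims=True)
    return a - row - col + a.mean()


def _factor_f(G: np.ndarray, projectors, dfs, residual_projector, residual_df):
    ss = np.array([float((P * G).sum()) for P in projectors])
    ss_res = float((residual_projector * G).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_res = ss_res / residual_df if residual_df > 0 else np.nan
        f = np.array(
            [
                (s / df) / ms_res if df > 0 and ms_res > 0 else np.nan
                for s, df in zip(ss, dfs)
            ]
        )
    return ss, ss_res, f


def permanova(
    d: DistanceMatrix,
    samples: SampleTable | pd.DataFrame,
    factors: FactorSpec = DEFAULT_FACTORS,
    n_perm: int = 9999,
    seed: int = 0,
    method: str = "sampled",
) -> PermutationTestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``factors`` is an ordered sequence of metadata column names; a tuple
    entry denotes an interaction.  Order matters: sums of squares are
    sequential.  ``method='exact'`` enumerates all n! sample relabelings
    (n <= 9) and reports ``p = #{F_perm >= F_obs} / n!``; the default
    sampled mode uses ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    Permutation of samples is unrestricted (no strata).
    """
    meta = samples.data if isinstance(samples, SampleTable) else samples
    ids = list(d.ids)
    missing = [s for s in ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    meta = meta.loc[ids]
    if method == "sampled" and n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    names, projectors, residual_projector, dfs, residual_df = sequential_ss_projectors(
        meta, factors
    )
    n = len(ids)
    G = _gower_center(np.asarray(d.data, dtype=float))
    ss, ss_res, f_obs = _factor_f(G, projectors, dfs, residual_projector, residual_df)
    ss_total = float(np.trace(G))

    tol = 1e-12
    exceed = np.zeros(len(names))
    if method == "exact":
        if n > 9:
            raise ValueError("exact enumeration is limited to n <= 9 samples")
        total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.asarray(perm)
            Gp = G[np.ix_(idx, idx)]
            _, _, f_perm = _factor_f(Gp, projectors, dfs, residual_projector, residual_df)
            exceed += f_perm >= f_obs - tol
            total += 1
        p = exceed / total
        n_used = total
    elif method == "sampled":
        rng = substream(seed, "perm")
        for _ in range(int(n_perm)):
            idx = rng.permutation(n)
            Gp = G[np.ix_(idx, idx)]
            _, _, f_perm = _factor_f(Gp, projectors, dfs, residual_projector, residual_df)
            exceed += f_perm >= f_obs - tol
        p = (1.0 + exceed) / (1.0 + n_perm)
        n_used = int(n_perm)
    else:
        raise ValueError(f"unknown method {method!r}")

    rows = []
    for name, df_k, ss_k, f_k, p_k in zip(names, dfs, ss, f_obs, p):
        rows.append(
            {
                "factor": name,
                "df": df_k,
                "SS": ss_k,
                "R2": ss_k / ss_total if ss_total > 0 else np.nan,
                "pseudo_F": f_k,
                "p_value": p_k if df_k > 0 else np.nan,
            }
        )
    rows.append(
        {
            "factor": "Residual",
            "df": residual_df,
            "SS": ss_res,
            "R2": ss_res / ss_total if ss_total > 0 else np.nan,
            "pseudo_F": np.nan,
            "p_value": np.nan,
        }
    )
    rows.append(
        {
            "factor": "Total",
            "df": n - 1,
            "SS": ss_total,
            "R2": 1.0,
            "pseudo_F": np.nan,
            "p_value": np.nan,
        }
    )
    table = pd.DataFrame(rows).set_index("factor")
    return PermutationTestResult(
        table=table, n_permutations=n_used, seed=seed, method=method
    )


def permdisp(
    d: DistanceMatrix,
    grouping: pd.Series | Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
    test: str = "median",
) -> PermutationTestResult:
    """Homogeneity of multivariate dispersions (betadisper).

    Samples are embedded by principal coordinates, each sample's distance to
    its group spatial median (or centroid) is computed, and a one-way F on
    those distances is referred to a permutation distribution.
    """
    ids = list(d.ids)
    if isinstance(grouping, pd.Series):
        grouping = grouping.loc[ids]
    labels = pd.Series(list(grouping), index=ids, dtype=str)
    sizes = labels.value_counts()
    if len(sizes) < 2:
        raise ValueError("permdisp requires at least 2 groups")
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"group(s) of size 1: {small}")
    dm = np.asarray(d.data)
    if np.allclose(dm, 0.0):
        table = pd.DataFrame(
            [{"factor": "dispersion", "df": len(sizes) - 1, "SS": 0.0,
              "R2": np.nan, "pseudo_F": 0.0, "p_value": 1.0}]
        ).set_index("factor")
        return PermutationTestResult(table, n_perm, seed, "degenerate")
    res = _skbio_permdisp(
        d,
        labels.to_numpy(),
        permutations=int(n_perm),
        test=test,
        seed=int(seed) % (2**31),
        dimensions=min(10, len(ids) - 1),
    )
    table = pd.DataFrame(
        [
            {
                "factor": "dispersion",
                "df": len(sizes) - 1,
                "SS": np.nan,
                "R2": np.nan,
                "pseudo_F": float(res["test statistic"]),
                "p_value": float(res["p-value"]),
            }
        ]
    ).set_index("factor")
    return PermutationTestResult(table, int(n_perm), seed, test)
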