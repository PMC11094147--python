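"""Quantitative microbiome profiling (QMP) core.

QMP turns relative amplicon counts into absolute-abundance profiles by
rarefying every sample to an even *sampling depth* — the ratio of its
sequencing reads to its qPCR-estimated microbial load — rather than to an
even read count.  After rarefaction to the minimum sampling depth, each
sample's total rarefied reads are proportional to its microbial load, so
between-sample comparisons are on an absolute scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import substream
from .datamodel import CountMatrix, CtTable, LoadTable, QMPMatrix

__all__ = ["load_from_ct", "sampling_depth", "qmp_rarefy"]


def load_from_ct(ct: CtTable, efficiency: float = 2.0) -> LoadTable:
    """Microbial load (microbe:host DNA ratio) from qPCR threshold cycles.

    Replicate Ct values are averaged per assay first, then
    ``load = E ** (mean Ct_host - mean Ct_16S)`` with amplification
    efficiency ``E`` (default 2 = perfect doubling per cycle).
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    host = ct.mean_ct("host")
    bact = ct.mean_ct("bact16S")
    missing = sorted(set(host.index) ^ set(bact.index))
    if missing or host.empty or bact.empty:
        raise ValueError(
            f"samples missing a bact16S or host assay: {missing or 'all'}"
        )
    load = float(efficiency) ** (host - bact)
    return LoadTable(load.rename("load"))


def sampling_depth(total_reads: float, load: float) -> float:
    """Sequencing reads per unit of microbial load (the quantity QMP equalizes)."""
    if load <= 0:
        raise ValueError("load must be positive")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return total_reads / load


def _subsample_integer(rng, row: np.ndarray, n: int) -> np.ndarray:
    """Draw n reads without replacement (multivariate hypergeometric)."""
    return rng.multivariate_hypergeometric(row, n, method="marginals")


def _subsample_real(rng, row: np.ndarray, n: int) -> np.ndarray:
    """Draw n reads with probabilities proportional to real-valued counts."""
    p = row / row.sum()
    return rng.multinomial(n, p)


def qmp_rarefy(
    counts: CountMatrix,
    loads: LoadTable,
    n_reps: int = 1000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> QMPMatrix:
    """Rarefy every sample to the minimum sampling depth and average.

    ``S_min = min_i(N_i / L_i)`` over samples; sample *i* is subsampled to
    ``n_i = floor(S_min * L_i)`` reads (guaranteed <= N_i) in each of
    ``n_reps`` replicates, and the replicate mean is returned.  Integer
    matrices are subsampled without replacement (multivariate
    hypergeometric); copy-number-corrected real-valued matrices via
    multinomial draws with probabilities proportional to corrected counts.
    """
    L = loads.of(counts.sample_ids).to_numpy(dtype=float)
    X = counts.values
    N = X.sum(axis=1)
    if (N <= 0).any():
        bad = [s for s, t in zip(counts.sample_ids, N) if t <= 0]
        raise ValueError(f"zero-total sample(s) cannot be rarefied: {bad}")
    s_min = float(np.min(N / L))
    targets = np.floor(s_min * L).astype(np.int64)
    targets = np.minimum(targets, np.floor(N + 1e-9).astype(np.int64))
    if (targets < 1).any():
        bad = [s for s, t in zip(counts.sample_ids, targets) if t < 1]
        raise ValueError(
            f"degenerate load: target rarefaction depth below 1 read for {bad}"
        )
    if rng is None:
        rng = substream(seed, "qmp")

    integer_mode = counts.is_integer
    if integer_mode:
        Xi = np.round(X).astype(np.int64)
        # guard against float totals fractionally below the integer target
        targets = np.minimum(targets, Xi.sum(axis=1))
        draw = _subsample_integer
        rows = [Xi[i] for i in range(Xi.shape[0])]
    else:
        draw = _subsample_real
        rows = [X[i] for i in range(X.shape[0])]

    acc = np.zeros_like(X, dtype=float)
    for _ in range(int(n_reps)):
        for i, row in enumerate(rows):
            acc[i] += draw(rng, row, int(targets[i]))
    mean = acc / float(n_reps)
    data = pd.DataFrame(mean, index=counts.data.index, columns=counts.data.columns)
    return QMPMatrix(
        data,
        n_replicates=int(n_reps),
        min_sampling_depth=s_min,
        target_depths=pd.Series(targets, index=counts.data.index, name="target_depth"),
        seed=seed,
    )
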