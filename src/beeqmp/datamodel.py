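"""Domain types for the honey-bee gut QMP pipeline.

The central exchange object is :class:`CountMatrix` (samples x ASVs).  All
types validate their invariants at construction and address samples/ASVs by
label, never by position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "QMPMatrix",
    "SampleTable",
    "TaxonomyTable",
    "CopyNumberMap",
    "CtTable",
    "LoadTable",
    "PipelineConfig",
    "FilterReport",
    "CONDITIONS",
    "ROLES",
    "ASSAYS",
    "DWV_ASSAYS",
]

CONDITIONS = ("survived", "failed")
ROLES = ("bee", "negative_control")
ASSAYS = ("bact16S", "host", "GAPDH", "DWV_A", "DWV_B", "DWV_C")
DWV_ASSAYS = ("DWV_A", "DWV_B", "DWV_C")


def _check_unique(labels: pd.Index, what: str) -> None:
    if labels.has_duplicates:
        dup = labels[labels.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} labels: {dup}")


class CountMatrix:
    """Samples x ASVs matrix of non-negative abundances.

    Raw reads are integers; copy-number-corrected or QMP-averaged matrices
    are real-valued (``is_integer`` is False).
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] == 0:
            raise ValueError("no samples: count matrix has zero rows")
        if data.shape[1] == 0:
            raise ValueError("no ASVs: count matrix has zero columns")
        _check_unique(data.index, "sample")
        _check_unique(data.columns, "ASV")
        values = data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite count at sample {data.index[bad[0]]!r}, "
                f"ASV {data.columns[bad[1]]!r}"
            )
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at sample {data.index[bad[0]]!r}, "
                f"ASV {data.columns[bad[1]]!r}"
            )
        self.data = data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data.index.name = None
        self.data.columns.name = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def is_integer(self) -> bool:
        v = self.values
        return bool(np.allclose(v, np.round(v), atol=1e-9))

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def totals(self) -> pd.Series:
        """Per-sample read totals."""
        return self.data.sum(axis=1)

    def select_samples(self, ids: Iterable[str]) -> "CountMatrix":
        ids = list(ids)
        missing = [i for i in ids if i not in self.data.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return CountMatrix(self.data.loc[ids].copy())

    def select_asvs(self, ids: Iterable[str]) -> "CountMatrix":
        ids = list(ids)
        missing = [i for i in ids if i not in self.data.columns]
        if missing:
            raise KeyError(f"unknown ASV ids: {missing}")
        return CountMatrix(self.data[ids].copy())

    def drop_asvs(self, ids: Iterable[str]) -> "CountMatrix":
        drop = [i for i in ids if i in self.data.columns]
        return CountMatrix(self.data.drop(columns=drop))

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, CountMatrix) and self.data.equals(other.data)

    def __repr__(self) -> str:
        kind = "integer" if self.is_integer else "real"
        return f"<CountMatrix {self.shape[0]} samples x {self.shape[1]} ASVs ({kind})>"


class QMPMatrix(CountMatrix):
    """Averaged load-scaled rarefied abundances plus rarefaction metadata."""

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        n_replicates: int,
        min_sampling_depth: float,
        target_depths: pd.Series,
        seed: int | None = None,
    ):
        super().__init__(data)
        self.n_replicates = int(n_replicates)
        self.min_sampling_depth = float(min_sampling_depth)
        self.target_depths = target_depths.astype(float)
        self.seed = seed

    def __repr__(self) -> str:
        return (
            f"<QMPMatrix {self.shape[0]} samples x {self.shape[1]} ASVs, "
            f"{self.n_replicates} replicates, S_min={self.min_sampling_depth:.1f}>"
        )


class SampleTable:
    """Per-sample metadata: hive, location, condition, role.

    Negative extraction controls carry ``role='negative_control'`` and empty
    hive/location/condition.  Every bee sample must belong to a hive, every
    hive to exactly one location and one condition.
    """

    REQUIRED = ("hive_id", "location", "condition", "role")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        _check_unique(data.index, "sample")
        data = data.copy()
        data.index = data.index.astype(str)
        for col in self.REQUIRED:
            data[col] = data[col].fillna("").astype(str)
        bad_role = sorted(set(data["role"]) - set(ROLES))
        if bad_role:
            raise ValueError(f"unknown role token(s): {bad_role}")
        bees = data[data["role"] == "bee"]
        bad_cond = sorted(set(bees["condition"]) - set(CONDITIONS))
        if bad_cond:
            raise ValueError(f"unknown condition token(s): {bad_cond}")
        for col in ("hive_id", "location", "condition"):
            empty = bees.index[bees[col] == ""].tolist()
            if empty:
                raise ValueError(f"bee sample(s) missing {col}: {empty}")
        for col in ("location", "condition"):
            per_hive = bees.groupby("hive_id")[col].nunique()
            bad = per_hive[per_hive > 1].index.tolist()
            if bad:
                raise ValueError(f"hive(s) mapped to more than one {col}: {bad}")
        data.index.name = None
        self.data = data

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def bee_ids(self) -> list[str]:
        return list(self.data.index[self.data["role"] == "bee"])

    @property
    def control_ids(self) -> list[str]:
        return list(self.data.index[self.data["role"] == "negative_control"])

    @property
    def hives(self) -> pd.DataFrame:
        """One row per hive: location and condition."""
        bees = self.data[self.data["role"] == "bee"]
        return (
            bees.groupby("hive_id")[["location", "condition"]]
            .first()
            .sort_index()
        )

    def factor(self, name: str, samples: Sequence[str] | None = None) -> pd.Series:
        ids = list(samples) if samples is not None else self.bee_ids
        missing = [s for s in ids if s not in self.data.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return self.data.loc[ids, name]

    def select(self, ids: Iterable[str]) -> "SampleTable":
        return SampleTable(self.data.loc[list(ids)].copy())

    def __repr__(self) -> str:
        return (
            f"<SampleTable {len(self.bee_ids)} bees in {self.hives.shape[0]} hives, "
            f"{len(self.control_ids)} controls>"
        )


class TaxonomyTable:
    """ASV -> genus mapping (optional higher ranks kept as extra columns)."""

    def __init__(self, data: pd.DataFrame):
        if "genus" not in data.columns:
            raise ValueError("taxonomy table requires a 'genus' column")
        _check_unique(data.index, "ASV")
        data = data.copy()
        data.index = data.index.astype(str)
        data["genus"] = data["genus"].astype(str)
        self.data = data

    def genus_of(self, asv_ids: Iterable[str]) -> pd.Series:
        ids = list(asv_ids)
        missing = [a for a in ids if a not in self.data.index]
        if missing:
            raise ValueError(f"ASV(s) without genus assignment: {missing}")
        return self.data.loc[ids, "genus"]

    @property
    def genera(self) -> list[str]:
        return sorted(self.data["genus"].unique())


class CopyNumberMap:
    """Genus -> 16S rRNA gene copy number (>= 1).

    Taxa with more rRNA operon copies are over-counted by amplicon
    sequencing; counts are down-weighted by this number.
    """

    def __init__(self, values: Mapping[str, int] | pd.Series):
        s = pd.Series(dict(values), dtype=float)
        if (s < 1).any() or not np.isfinite(s).all():
            bad = s.index[(s < 1) | ~np.isfinite(s)].tolist()
            raise ValueError(f"copy numbers must be >= 1; offending genera: {bad}")
        self.values = s

    def of(self, genera: Iterable[str]) -> pd.Series:
        genera = list(genera)
        missing = [g for g in genera if g not in self.values.index]
        if missing:
            raise ValueError(f"no 16S copy number for genera: {missing}")
        return self.values.loc[genera]


class CtTable:
    """Long-format qPCR threshold cycles: sample x assay x replicate.

    Assays are run in triplicate; groups with fewer replicates are allowed
    but reported by :meth:`incomplete_groups`.
    """

    def __init__(self, data: pd.DataFrame):
        req = ["sample_id", "assay", "replicate", "ct"]
        missing = [c for c in req if c not in data.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        data = data.copy()
        data["sample_id"] = data["sample_id"].astype(str)
        data["assay"] = data["assay"].astype(str)
        bad = sorted(set(data["assay"]) - set(ASSAYS))
        if bad:
            raise ValueError(f"unknown assay token(s): {bad}")
        data["ct"] = data["ct"].astype(float)
        if (data["ct"] <= 0).any() or not np.isfinite(data["ct"]).all():
            row = data[(data["ct"] <= 0) | ~np.isfinite(data["ct"])].iloc[0]
            raise ValueError(
                f"Ct must be a positive cycle count; offending record: "
                f"sample {row['sample_id']!r}, assay {row['assay']!r}, Ct={row['ct']}"
            )
        dup = data.duplicated(subset=["sample_id", "assay", "replicate"])
        if dup.any():
            row = data[dup].iloc[0]
            raise ValueError(
                f"duplicate replicate index {row['replicate']} for sample "
                f"{row['sample_id']!r}, assay {row['assay']!r}"
            )
        self.data = data.reset_index(drop=True)

    def mean_ct(self, assay: str) -> pd.Series:
        """Replicate-averaged Ct per sample for one assay."""
        sub = self.data[self.data["assay"] == assay]
        return sub.groupby("sample_id")["ct"].mean()

    def incomplete_groups(self, expected: int = 3) -> pd.DataFrame:
        sizes = self.data.groupby(["sample_id", "assay"]).size()
        short = sizes[sizes < expected]
        return short.rename("n_replicates").reset_index()

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())


class LoadTable:
    """Per-sample microbial load (microbe:host DNA ratio, unitless)."""

    def __init__(self, values: pd.Series):
        s = values.astype(float)
        if (s <= 0).any() or not np.isfinite(s).all():
            bad = s.index[(s <= 0) | ~np.isfinite(s)].tolist()
            raise ValueError(f"loads must be positive and finite; offending samples: {bad}")
        s.index = s.index.astype(str)
        self.values = s

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def of(self, sample_ids: Iterable[str]) -> pd.Series:
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.values.index]
        if missing:
            raise ValueError(f"samples without load estimate: {missing}")
        return self.values.loc[ids]


@dataclass
class FilterReport:
    """Per-ASV filtering decisions with supporting statistics."""

    table: pd.DataFrame  # index asv_id; columns decision, + stats

    DECISIONS = ("kept", "removed_rare", "removed_contaminant")

    def __post_init__(self):
        bad = sorted(set(self.table["decision"]) - set(self.DECISIONS))
        if bad:
            raise ValueError(f"unknown filter decision(s): {bad}")
        _check_unique(self.table.index, "ASV")

    def removed(self, decision: str | None = None) -> list[str]:
        t = self.table
        if decision is None:
            return list(t.index[t["decision"] != "kept"])
        return list(t.index[t["decision"] == decision])

    @property
    def kept(self) -> list[str]:
        return list(self.table.index[self.table["decision"] == "kept"])


@dataclass
class PipelineConfig:
    """Tunable parameters for every pipeline stage, with study defaults."""

    min_count: int = 3
    min_prevalence: float = 0.20
    contaminant_alpha: float = 0.05
    rarefaction_replicates: int = 1000
    qpcr_efficiency: float = 2.0
    n_permutations: int = 9999
    ml_seeds: int = 100
    ml_train_frac: float = 0.8
    seed: int = 0

    def __post_init__(self):
        for name in ("min_prevalence", "contaminant_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.ml_train_frac < 1.0:
            raise ValueError("ml_train_frac must lie in (0, 1)")
        for name in ("min_count", "rarefaction_replicates", "n_permutations", "ml_seeds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.qpcr_efficiency <= 1.0:
            raise ValueError("qPCR amplification efficiency must exceed 1")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = sorted(set(d) - set(known))
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**known)
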