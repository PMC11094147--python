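"""TSV / newick / YAML / JSON readers and writers.

TSV is the canonical table dialect (UTF-8, header row, '.' decimal).  Readers
validate against the domain-type invariants and name the offending record in
error messages; ``write . read`` is the identity up to 1e-9 float formatting.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .datamodel import (
    CopyNumberMap,
    CountMatrix,
    CtTable,
    PipelineConfig,
    SampleTable,
    TaxonomyTable,
)

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_sample_table",
    "write_sample_table",
    "read_taxonomy_table",
    "write_taxonomy_table",
    "read_copy_number_table",
    "write_copy_number_table",
    "read_ct_table",
    "write_ct_table",
    "read_newick",
    "write_newick",
    "read_config",
    "write_config",
    "write_manifest",
]

_FLOAT_FMT = "%.10g"


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"no samples: {path} is empty") from None
    if df.shape[0] == 0 and df.shape[1] <= 1:
        raise ValueError(f"no samples: {path} is empty")
    return df


def read_count_table(path, orientation: str = "samples_by_asvs") -> CountMatrix:
    """Read a counts TSV whose first column holds row labels.

    ``orientation='asvs_by_samples'`` transposes after reading, so tables
    written either way round load into the canonical samples x ASVs layout.
    """
    if orientation not in ("samples_by_asvs", "asvs_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = _read_tsv(path)
    labels = raw.iloc[:, 0]
    body = raw.iloc[:, 1:]
    if body.shape[1] == 0:
        raise ValueError(f"no ASVs: {path} has no data columns")
    parsed = np.empty(body.shape, dtype=float)
    for j, col in enumerate(body.columns):
        try:
            parsed[:, j] = pd.to_numeric(body[col], errors="raise")
        except (ValueError, TypeError):
            bad = body[col][pd.to_numeric(body[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric cell {bad.iloc[0]!r} at row {labels.iloc[bad.index[0]]!r}, "
                f"column {col!r} in {path}"
            ) from None
    df = pd.DataFrame(parsed, index=labels.astype(str), columns=body.columns.astype(str))
    df.index.name = raw.columns[0]
    if orientation == "asvs_by_samples":
        df = df.T
    return CountMatrix(df)


def write_count_table(matrix: CountMatrix, path, label: str = "sample_id") -> None:
    df = matrix.data.copy()
    df.index.name = label
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_sample_table(path) -> SampleTable:
    df = _read_tsv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"sample table {path} missing 'sample_id' column")
    return SampleTable(df.set_index("sample_id"))


def write_sample_table(samples: SampleTable, path) -> None:
    df = samples.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_taxonomy_table(path) -> TaxonomyTable:
    df = _read_tsv(path)
    if "asv_id" not in df.columns:
        raise ValueError(f"taxonomy table {path} missing 'asv_id' column")
    return TaxonomyTable(df.set_index("asv_id"))


def write_taxonomy_table(tax: TaxonomyTable, path) -> None:
    df = tax.data.copy()
    df.index.name = "asv_id"
    df.to_csv(path, sep="\t")


def read_copy_number_table(path) -> CopyNumberMap:
    df = _read_tsv(path)
    req = {"genus", "copy_number"}
    if not req <= set(df.columns):
        raise ValueError(f"copy-number table {path} needs columns {sorted(req)}")
    try:
        values = pd.to_numeric(df["copy_number"], errors="raise")
    except (ValueError, TypeError):
        raise ValueError(f"non-numeric copy number in {path}") from None
    return CopyNumberMap(pd.Series(values.to_numpy(), index=df["genus"].astype(str)))


def write_copy_number_table(cn: CopyNumberMap, path) -> None:
    df = cn.values.rename("copy_number").to_frame()
    df.index.name = "genus"
    df.to_csv(path, sep="\t", float_format="%g")


def read_ct_table(path) -> CtTable:
    df = _read_tsv(path)
    req = ["sample_id", "assay", "replicate", "ct"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table {path} missing columns: {missing}")
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise")
    df["ct"] = pd.to_numeric(df["ct"], errors="raise")
    return CtTable(df[req])


def write_ct_table(ct: CtTable, path) -> None:
    ct.data.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_newick(path, clamp_negative: bool = False) -> TreeNode:
    """Read a rooted/unrooted newick tree with branch lengths.

    Negative branch lengths are rejected unless ``clamp_negative`` is set,
    in which case they are clamped to zero.
    """
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.is_tip() and (node.name is None or node.name == ""):
            raise ValueError("newick tree contains an unlabeled leaf")
        if node.length is not None and node.length < 0:
            if clamp_negative:
                node.length = 0.0
            else:
                raise ValueError(
                    f"negative branch length at node {node.name!r}; "
                    "pass clamp_negative=True to clamp to zero"
                )
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(raw)


def write_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def write_manifest(path, *, stage: str, inputs: dict, parameters: dict, seed) -> None:
    """Write a JSON run manifest: inputs, parameters, seed, versions."""
    from . import __version__

    manifest: dict[str, Any] = {
        "stage": stage,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "parameters": parameters,
        "seed": seed,
        "versions": {
            "beeqmp": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
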