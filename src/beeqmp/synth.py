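"""Synthetic study generator.

Emulates the sampling design of the field study the pipeline targets: 23
hives across three northern-Virginia apiary locations (12 Gainesville with 8
winter failures, 9 Upperville all surviving, 2 Vienna with 1 failure), 5-8
forager bees per hive (mean ~7.3, ~168 bee samples), 77 ASVs across the ten
characteristic honey-bee gut genera, qPCR-derived bacterial loads with an
approximately two-fold survived:failed effect, a relative-share boost of the
beneficial genera Commensalibacter and Snodgrassella in surviving hives,
negative extraction controls carrying kitome contaminant ASVs, triplicate Ct
values, and per-strain deformed-wing-virus delta-Ct levels.

Every latent quantity is recorded in a ``truth`` dictionary so downstream
estimators can be validated against the generating parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._rng import substream
from .datamodel import CopyNumberMap, CountMatrix, CtTable, SampleTable, TaxonomyTable

__all__ = ["SynthDesign", "SynthStudy", "generate_study", "generate_worked_micro", "null_design"]

# classic reagent/kitome contaminant genera used for planted contaminant ASVs
_CONTAMINANT_GENERA = (
    "Ralstonia",
    "Sphingomonas",
    "Pseudomonas",
    "Cutibacterium",
    "Methylobacterium",
    "Bradyrhizobium",
    "Acinetobacter",
    "Delftia",
)


@dataclass(frozen=True)
class SynthDesign:
    """All knobs of the generative model, defaulting to the study design."""

    locations: tuple[str, ...] = ("Gainesville", "Upperville", "Vienna")
    hives_per_location: tuple[int, ...] = (12, 9, 2)
    failed_hives_per_location: tuple[int, ...] = (8, 0, 1)
    # bees per hive drawn from {5,6,7,8}; weights give mean ~7.3 (so ~168 bees)
    bees_per_hive_range: tuple[int, int] = (5, 8)
    bees_per_hive_weights: tuple[float, ...] = (0.05, 0.10, 0.35, 0.50)

    genera: tuple[str, ...] = (
        "Lactobacillus",
        "Gilliamella",
        "Bombilactobacillus",
        "Bifidobacterium",
        "Snodgrassella",
        "Bartonella",
        "Commensalibacter",
        "Frischella",
        "Apilactobacillus",
        "Bombella",
    )
    # 77 ASVs total; copy numbers reproduce the 64@4 / 10@2 / 1@3 / 2@5 split
    asvs_per_genus: tuple[int, ...] = (16, 13, 10, 9, 8, 7, 6, 5, 2, 1)
    copy_numbers: tuple[int, ...] = (4, 4, 2, 4, 4, 4, 4, 4, 5, 3)
    base_genus_props: tuple[float, ...] = (
        0.25, 0.18, 0.12, 0.15, 0.12, 0.05, 0.06, 0.04, 0.02, 0.01,
    )
    # beneficial genera whose relative share is boosted in surviving hives
    effect_genera: tuple[str, ...] = ("Commensalibacter", "Snodgrassella")
    genus_effect_multipliers: tuple[float, ...] = (2.5, 2.0)

    # Dirichlet hierarchy: hive-level then bee-level concentration.
    # hive_concentration=None removes the hive stage (bees i.i.d. given design).
    hive_concentration: float | None = 60.0
    bee_concentration: float = 250.0

    # total microbial load (microbe:host ratio), log-normal
    load_median: float = 1.0
    load_sigma: float = 0.5  # ln-scale, bee level
    hive_load_sigma: float = 0.3  # ln-scale, hive level
    load_condition_multiplier: float = 2.0  # survived vs failed

    # sequencing depth, log-normal clipped to the plausible read range
    depth_median: float = 33000.0
    depth_sigma: float = 0.35
    depth_range: tuple[int, int] = (9461, 73402)

    # negative extraction controls and planted contaminants
    n_controls: int = 8
    control_depth_median: float = 2000.0
    control_depth_sigma: float = 0.5
    n_contaminants: int = 5
    contaminant_prev_controls: float = 0.9
    contaminant_prev_bees: float = 0.05
    contaminant_share_bees: float = 0.003
    control_leak_share: float = 0.1

    # qPCR model (efficiency-2 back-computation; Gaussian replicate noise)
    efficiency: float = 2.0
    ct_host_mean: float = 24.0
    ct_host_sigma: float = 0.5
    ct_replicate_sigma: float = 0.15
    n_ct_replicates: int = 3

    # DWV delta-Ct (Ct_GAPDH - Ct_DWV) means per strain and location;
    # strain C carries the planted between-location shift
    gapdh_ct_mean: float = 20.0
    gapdh_ct_sigma: float = 0.3
    dwv_dct_means: tuple[tuple[float, ...], ...] = (
        (-1.0, -1.0, -1.0),  # DWV_A
        (0.5, 0.5, 0.5),  # DWV_B
        (-0.94, 0.55, 0.42),  # DWV_C
    )
    dwv_hive_sigma: float = 0.5
    dwv_bee_sigma: float = 1.0

    seed: int = 0

    def __post_init__(self):
        if len(self.hives_per_location) != len(self.locations):
            raise ValueError("hives_per_location must match locations")
        if len(self.failed_hives_per_location) != len(self.locations):
            raise ValueError("failed_hives_per_location must match locations")
        if sum(self.hives_per_location) < 1:
            raise ValueError("design needs at least one hive")
        for n_fail, n_hive in zip(self.failed_hives_per_location, self.hives_per_location):
            if not 0 <= n_fail <= n_hive:
                raise ValueError("failed hives per location must lie in [0, hives]")
        n_genera = len(self.genera)
        if n_genera < 1:
            raise ValueError("design needs at least one genus")
        for name, t in (
            ("asvs_per_genus", self.asvs_per_genus),
            ("copy_numbers", self.copy_numbers),
            ("base_genus_props", self.base_genus_props),
        ):
            if len(t) != n_genera:
                raise ValueError(f"{name} must have one entry per genus")
        if any(a < 1 for a in self.asvs_per_genus):
            raise ValueError("each genus needs at least one ASV")
        if any(c < 1 for c in self.copy_numbers):
            raise ValueError("copy numbers must be >= 1")
        props = np.asarray(self.base_genus_props, dtype=float)
        if (props <= 0).any() or abs(props.sum() - 1.0) > 1e-6:
            raise ValueError("base_genus_props must be positive and sum to 1")
        if any(g not in self.genera for g in self.effect_genera):
            raise ValueError("effect_genera must be a subset of genera")
        if len(self.genus_effect_multipliers) != len(self.effect_genera):
            raise ValueError("one multiplier per effect genus required")
        if any(m <= 0 for m in self.genus_effect_multipliers):
            raise ValueError("effect multipliers must be positive")
        if self.load_condition_multiplier <= 0:
            raise ValueError("load_condition_multiplier must be positive")
        lo, hi = self.bees_per_hive_range
        if not 1 <= lo <= hi:
            raise ValueError("bees_per_hive_range must satisfy 1 <= lo <= hi")
        if len(self.bees_per_hive_weights) != hi - lo + 1:
            raise ValueError("bees_per_hive_weights must cover the bees range")
        for p in (
            self.contaminant_prev_controls,
            self.contaminant_prev_bees,
            self.control_leak_share,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_contaminants > len(_CONTAMINANT_GENERA):
            raise ValueError(f"at most {len(_CONTAMINANT_GENERA)} contaminants supported")
        if len(self.dwv_dct_means) != 3:
            raise ValueError("dwv_dct_means needs one row per strain (A, B, C)")
        for row in self.dwv_dct_means:
            if len(row) != len(self.locations):
                raise ValueError("each DWV strain needs one delta-Ct mean per location")


@dataclass
class SynthStudy:
    """A complete generated study plus the latent truth record."""

    counts: CountMatrix
    samples: SampleTable
    taxonomy: TaxonomyTable
    copy_numbers: CopyNumberMap
    ct: CtTable
    tree: TreeNode
    truth: dict


def null_design(iid_bees: bool = True, **overrides) -> SynthDesign:
    """Default design with every planted condition effect removed.

    With ``iid_bees`` the hive-level Dirichlet stage is flattened as well, so
    bee community profiles are exchangeable across the whole study — the
    regime under which unrestricted permutation tests are exactly calibrated.
    """
    kw = dict(
        load_condition_multiplier=1.0,
        genus_effect_multipliers=tuple(1.0 for _ in SynthDesign().effect_genera),
    )
    if iid_bees:
        kw["hive_concentration"] = None
    kw.update(overrides)
    return SynthDesign(**kw)


def _coalescent_join(rng: np.random.Generator, nodes, heights, scale: float):
    """Random coalescent merge of subtrees; returns (root, root_height)."""
    nodes = list(nodes)
    heights = list(heights)
    h = max(heights)
    while len(nodes) > 1:
        k = len(nodes)
        h += rng.exponential(scale / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = h - heights[i]
        b.length = h - heights[j]
        parent = TreeNode(children=[a, b])
        nodes[j] = parent
        heights[j] = h
        del nodes[i], heights[i]
    return nodes[0], heights[0]


def _random_tree(rng: np.random.Generator, asvs_by_genus: Mapping[str, Sequence[str]]) -> TreeNode:
    """Genus-structured random ultrametric tree over all ASV leaves."""
    genus_roots, genus_heights = [], []
    for genus, leaves in asvs_by_genus.items():
        tips = [TreeNode(name=a, length=0.0) for a in leaves]
        root, h = _coalescent_join(rng, tips, [0.0] * len(tips), scale=0.05)
        genus_roots.append(root)
        genus_heights.append(h)
    root, _ = _coalescent_join(rng, genus_roots, genus_heights, scale=0.5)
    root.length = None
    return root


def generate_study(design: SynthDesign | None = None, seed: int | None = None) -> SynthStudy:
    """Draw one complete synthetic study from the generative model.

    The model is hierarchical: hive-level genus proportions are Dirichlet
    perturbations of a (condition-adjusted) base composition, bee-level
    proportions are Dirichlet perturbations of their hive's, ASV counts are
    multinomial at a log-normal sequencing depth, and Ct values are
    back-computed from the true loads under the efficiency-2 model so the
    load estimator recovers them up to replicate noise.
    """
    design = design or SynthDesign()
    rng = substream(design.seed if seed is None else seed, "synth")

    genera = list(design.genera)
    base_props = np.asarray(design.base_genus_props, dtype=float)
    effect = np.ones(len(genera))
    for g, m in zip(design.effect_genera, design.genus_effect_multipliers):
        effect[genera.index(g)] = m

    # --- hives ---------------------------------------------------------
    hive_rows = []
    prefixes = [loc[:4].upper() for loc in design.locations]
    if len(set(prefixes)) < len(prefixes):  # disambiguate short location names
        prefixes = [f"{p}{i}" for i, p in enumerate(prefixes)]
    for loc, prefix, n_hives, n_fail in zip(
        design.locations, prefixes, design.hives_per_location,
        design.failed_hives_per_location,
    ):
        failed_idx = set(rng.choice(n_hives, size=n_fail, replace=False).tolist())
        for k in range(n_hives):
            hive_rows.append(
                {
                    "hive_id": f"{prefix}{k + 1:02d}",
                    "location": loc,
                    "condition": "failed" if k in failed_idx else "survived",
                }
            )
    hives = pd.DataFrame(hive_rows).set_index("hive_id")

    # --- ASVs, taxonomy, copy numbers ----------------------------------
    asv_ids, tax_rows, asvs_by_genus = [], [], {}
    counter = 0
    for genus, n_asv in zip(genera, design.asvs_per_genus):
        ids = []
        for _ in range(n_asv):
            counter += 1
            ids.append(f"ASV{counter}")
        asv_ids.extend(ids)
        asvs_by_genus[genus] = ids
        tax_rows.extend({"asv_id": a, "genus": genus} for a in ids)
    contaminant_ids = []
    contaminant_genera = list(_CONTAMINANT_GENERA[: design.n_contaminants])
    for genus in contaminant_genera:
        counter += 1
        aid = f"ASV{counter}"
        contaminant_ids.append(aid)
        asvs_by_genus[genus] = [aid]
        tax_rows.append({"asv_id": aid, "genus": genus})
    all_ids = asv_ids + contaminant_ids

    taxonomy = TaxonomyTable(pd.DataFrame(tax_rows).set_index("asv_id"))
    cn_values = {g: float(c) for g, c in zip(genera, design.copy_numbers)}
    cn_values.update({g: 4.0 for g in contaminant_genera})
    copy_numbers = CopyNumberMap(cn_values)

    # fixed ASV composition within each genus
    within = {
        g: rng.dirichlet(np.ones(len(asvs_by_genus[g]))) if len(asvs_by_genus[g]) > 1 else np.ones(1)
        for g in genera
    }

    # --- per-bee latent state and counts --------------------------------
    n_cols = len(all_ids)
    sample_rows, count_rows, sample_ids = [], [], []
    true_loads, true_depths, bee_genus_props, hive_genus_props = {}, {}, {}, {}
    nums = np.arange(design.bees_per_hive_range[0], design.bees_per_hive_range[1] + 1)
    weights = np.asarray(design.bees_per_hive_weights, dtype=float)
    weights = weights / weights.sum()

    for hive_id, hive in hives.iterrows():
        survived = hive["condition"] == "survived"
        hive_base = base_props * np.where(survived, effect, 1.0)
        hive_base = hive_base / hive_base.sum()
        if design.hive_concentration is None:
            hive_props = hive_base
        else:
            hive_props = rng.dirichlet(hive_base * design.hive_concentration)
            hive_props = np.clip(hive_props, 1e-12, None)
            hive_props = hive_props / hive_props.sum()
        hive_genus_props[hive_id] = hive_props
        hive_load_eff = rng.normal(0.0, design.hive_load_sigma)
        n_bees = int(rng.choice(nums, p=weights))
        for b in range(n_bees):
            sid = f"{hive_id}_b{b + 1}"
            sample_ids.append(sid)
            sample_rows.append(
                {
                    "sample_id": sid,
                    "hive_id": hive_id,
                    "location": hive["location"],
                    "condition": hive["condition"],
                    "role": "bee",
                }
            )
            props = rng.dirichlet(hive_props * design.bee_concentration)
            props = np.clip(props, 1e-12, None)
            props = props / props.sum()
            bee_genus_props[sid] = props
            load = design.load_median * math.exp(
                hive_load_eff + rng.normal(0.0, design.load_sigma)
            )
            if survived:
                load *= design.load_condition_multiplier
            true_loads[sid] = load

            p_asv = np.concatenate([props[i] * within[g] for i, g in enumerate(genera)])
            p_full = np.zeros(n_cols)
            p_full[: len(asv_ids)] = p_asv
            present = rng.random(design.n_contaminants) < design.contaminant_prev_bees
            if present.any():
                share = design.contaminant_share_bees * present
                p_full[: len(asv_ids)] *= 1.0 - share.sum()
                p_full[len(asv_ids):] = share
            depth = int(
                np.clip(
                    design.depth_median * math.exp(rng.normal(0.0, design.depth_sigma)),
                    *design.depth_range,
                )
            )
            true_depths[sid] = depth
            count_rows.append(rng.multinomial(depth, p_full))

    # --- negative extraction controls -----------------------------------
    for c in range(design.n_controls):
        sid = f"NEG{c + 1:02d}"
        sample_ids.append(sid)
        sample_rows.append(
            {"sample_id": sid, "hive_id": "", "location": "", "condition": "", "role": "negative_control"}
        )
        p_full = np.zeros(n_cols)
        present = rng.random(design.n_contaminants) < design.contaminant_prev_controls
        if design.n_contaminants and not present.any():
            present[rng.integers(design.n_contaminants)] = True
        contam_mass = 1.0 - design.control_leak_share
        if present.any():
            w = rng.dirichlet(np.ones(int(present.sum())))
            p_full[len(asv_ids) :][present] = contam_mass * w
        # low-level cross-talk from abundant bee taxa
        leak_cols = rng.choice(len(asv_ids), size=min(5, len(asv_ids)), replace=False)
        p_full[leak_cols] += (1.0 - p_full.sum()) * rng.dirichlet(np.ones(len(leak_cols)))
        p_full = p_full / p_full.sum()
        depth = max(
            1,
            int(design.control_depth_median * math.exp(rng.normal(0.0, design.control_depth_sigma))),
        )
        true_depths[sid] = depth
        count_rows.append(rng.multinomial(depth, p_full))

    counts = CountMatrix(
        pd.DataFrame(np.asarray(count_rows), index=sample_ids, columns=all_ids)
    )
    samples = SampleTable(pd.DataFrame(sample_rows).set_index("sample_id"))

    # --- qPCR Ct back-computation ---------------------------------------
    log_e = math.log(design.efficiency)
    loc_index = {loc: i for i, loc in enumerate(design.locations)}
    strains = ("DWV_A", "DWV_B", "DWV_C")
    dwv_hive_eff = {
        (hive_id, s): rng.normal(0.0, design.dwv_hive_sigma)
        for hive_id in hives.index
        for s in strains
    }
    ct_rows = []
    true_dct: dict[str, dict[str, float]] = {s: {} for s in strains}
    for sid in samples.bee_ids:
        hive_id = samples.data.loc[sid, "hive_id"]
        loc = samples.data.loc[sid, "location"]
        host_ct = rng.normal(design.ct_host_mean, design.ct_host_sigma)
        bact_ct = host_ct - math.log(true_loads[sid]) / log_e
        gapdh_ct = rng.normal(design.gapdh_ct_mean, design.gapdh_ct_sigma)
        assay_truth = {"host": host_ct, "bact16S": bact_ct, "GAPDH": gapdh_ct}
        for s_i, strain in enumerate(strains):
            dct = (
                design.dwv_dct_means[s_i][loc_index[loc]]
                + dwv_hive_eff[(hive_id, strain)]
                + rng.normal(0.0, design.dwv_bee_sigma)
            )
            true_dct[strain][sid] = dct
            assay_truth[strain] = gapdh_ct - dct
        for assay, truth_ct in assay_truth.items():
            for rep in range(1, design.n_ct_replicates + 1):
                ct_rows.append(
                    {
                        "sample_id": sid,
                        "assay": assay,
                        "replicate": rep,
                        "ct": max(truth_ct + rng.normal(0.0, design.ct_replicate_sigma), 1e-3),
                    }
                )
    ct = CtTable(pd.DataFrame(ct_rows))

    tree = _random_tree(rng, asvs_by_genus)

    truth = {
        "design": design,
        "hives": hives,
        "loads": pd.Series(true_loads, name="load"),
        "depths": pd.Series(true_depths, name="depth"),
        "hive_genus_props": pd.DataFrame(hive_genus_props, index=genera).T,
        "bee_genus_props": pd.DataFrame(bee_genus_props, index=genera).T,
        "within_genus_props": {g: within[g].tolist() for g in genera},
        "contaminant_asvs": contaminant_ids,
        "effect_genera": list(design.effect_genera),
        "dwv_true_dct": {s: pd.Series(d) for s, d in true_dct.items()},
    }
    return SynthStudy(counts, samples, taxonomy, copy_numbers, ct, tree, truth)


def generate_worked_micro(seed: int = 0) -> SynthStudy:
    """Miniature study (4 hives x 2 bees, 3 genera x 2 ASVs) for which
    brute-force permutation enumeration is feasible."""
    design = SynthDesign(
        locations=("LocA", "LocB"),
        hives_per_location=(2, 2),
        failed_hives_per_location=(1, 1),
        bees_per_hive_range=(2, 2),
        bees_per_hive_weights=(1.0,),
        genera=("GenA", "GenB", "GenC"),
        asvs_per_genus=(2, 2, 2),
        copy_numbers=(4, 2, 4),
        base_genus_props=(0.5, 0.3, 0.2),
        effect_genera=("GenA",),
        genus_effect_multipliers=(2.0,),
        hive_concentration=60.0,
        n_controls=2,
        n_contaminants=1,
        depth_median=800.0,
        depth_range=(300, 2000),
        control_depth_median=200.0,
        dwv_dct_means=((-1.0, -1.0), (0.5, 0.5), (-0.9, 0.5)),
        seed=seed,
    )
    return generate_study(design, seed=seed)
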