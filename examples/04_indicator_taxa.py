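"""Which taxa are associated with winter survival?

Pools ASVs to genus level, runs nested two-way ANOVAs (hive means;
condition + location + interaction; BH-adjusted across genera) and
indicator-value (IndVal) analysis with label permutation on ASVs.
"""

import warnings

import beeqmp as bq
from beeqmp.pipeline import preprocess_stage

warnings.filterwarnings("ignore", message=".*interaction df reduced.*")

study = bq.generate_study(seed=1)
pre = preprocess_stage(study.counts, study.samples, study.taxonomy,
                       study.copy_numbers)
profile = bq.qmp_rarefy(pre["corrected"], bq.load_from_ct(study.ct),
                        n_reps=200, seed=2)
bees = pre["bee_samples"]

genus = bq.pool_by_genus(profile, study.taxonomy)
anova = bq.genus_anova(genus, bees)
print("nested two-way ANOVA per genus (BH-adjusted):")
print(anova.round(4))
print(f"-> the generator planted shifts on {study.truth['effect_genera']};")
print("   those genera should carry the smallest condition p-values")

total = bq.nested_anova(profile.totals(), bees)
print(f"\ntotal QMP abundance condition p = {total.p_value('condition'):.4f}")
print("-> detects the ~2x higher overall bacterial load in surviving hives")

iv = bq.indval(profile, bees, n_perm=999, seed=5)
print("\ntop indicator ASVs (IndVal = sqrt(specificity x fidelity)):")
print(iv.sort_values("adj_p").head(5).round(4))
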