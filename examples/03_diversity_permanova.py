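"""Alpha/beta diversity and permutation tests on QMP profiles.

Computes Shannon/Simpson/Pielou alpha diversity, weighted UniFrac and
Bray-Curtis distances, an NMDS ordination, and PERMANOVA (sequential SS:
condition, location, interaction) plus PERMDISP on hive condition.
"""

import beeqmp as bq
from beeqmp.pipeline import preprocess_stage

study = bq.generate_study(seed=1)
pre = preprocess_stage(study.counts, study.samples, study.taxonomy,
                       study.copy_numbers)
profile = bq.qmp_rarefy(pre["corrected"], bq.load_from_ct(study.ct),
                        n_reps=200, seed=2)
bees = pre["bee_samples"]

alpha = bq.alpha_diversity(profile)
print("alpha diversity (first bees):")
print(alpha.head(3).round(3))

wu = bq.weighted_unifrac(profile, study.tree)
perm = bq.permanova(wu, bees, n_perm=9999, seed=3)
print("\nPERMANOVA on weighted UniFrac:")
print(perm.table.round(4))
print("-> a small p for 'condition' means gut community composition")
print("   differs between hives that survived and failed the winter")

bc = bq.bray_curtis(profile)
for name, dm in (("weighted UniFrac", wu), ("Bray-Curtis", bc)):
    disp = bq.permdisp(dm, bees.factor("condition", list(dm.ids)), seed=3)
    print(f"\nPERMDISP ({name}) p = {disp.p_value('dispersion'):.3f}")
print("-> PERMDISP checks the PERMANOVA assumption of homogeneous group")
print("   dispersions: a small p means groups differ in spread as well as")
print("   position, so the PERMANOVA signal should be read with care")

nm = bq.nmds(wu, seed=4)
print(f"\nNMDS stress = {nm.stress:.3f} (values < 0.2 are interpretable)")
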