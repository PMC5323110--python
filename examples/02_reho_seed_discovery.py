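"""Regional homogeneity mapping and data-driven seed discovery.

Computes Kendall's-W ReHo maps for a small two-group cohort, normalizes
each map by its whole-brain mean, smooths, and runs the covariate-
adjusted group GLM.  The planted elevation of local homogeneity in the
two seed regions of the patient group surfaces as suprathreshold
clusters, which become the seed ROIs for connectivity analysis.
"""

from rehofc import generate_cohort
from rehofc.preprocess import preprocess_series
from rehofc.reho import normalize_reho, reho_map, select_seeds, smooth_map
from rehofc.stats import cluster_table, group_glm, logit_gm, t_critical

cohort = generate_cohort(n_patient=20, n_control=20, seed=3, n_volumes=150)
atlas = cohort.atlas
masks = {"wm": atlas.regions["wm"], "csf": atlas.regions["csf"]}

reho_maps, gm_logit = [], []
for i in range(cohort.n_subjects):
    clean, _ = preprocess_series(cohort.bold(i), cohort.motions[i], masks,
                                 global_signal=False)
    rmap = normalize_reho(reho_map(clean, neighborhood=27))
    reho_maps.append(smooth_map(rmap.values, 8.0, atlas.voxel_size_mm,
                                atlas.brain_mask))
    gm_logit.append(logit_gm(cohort.gm_maps[i], mask=atlas.brain_mask))

stat = group_glm(reho_maps, cohort.groups(),
                 cohort.phenotypes[["age", "gender", "education"]],
                 gm_logit, atlas.brain_mask)
table = cluster_table(stat, voxel_p=0.005, min_extent_voxels=74, atlas=atlas,
                      network="ReHo")
print("ReHo group-difference clusters (patients - controls):")
print(table[["region_label", "extent_voxels", "peak_stat"]].to_string(index=False))

seeds = select_seeds(stat, t_critical(0.005, stat.df), 74, atlas)
print("\nDiscovered seeds:", [(s.name, s.size) for s in seeds])
print("Positive peaks mean higher local temporal synchrony in patients; "
      "the two planted seed regions should top the list.")
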