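"""Simulate a two-generation, multi-site breeding study and inspect it.

The generator emulates a conifer progeny trial: a small founder pool crossed
into full-sib F1 families replicated over three sites, with a subset of F1
trees reused as parents of an F2 trial on a fourth site.
"""

from treegs import SimulationConfig, build_study_bundle, build_A, status_number

# scaled-down study so the example runs in seconds
config = SimulationConfig(
    f1_site_sizes=(110, 110, 110),
    f2_size=80,
    f2_genotyped=60,
    n_markers=500,
    n_qtl=60,
    n_f1_families=25,
    n_f2_parents=10,
    n_f2_families=15,
    seed=2,
)
bundle = build_study_bundle(config)

print(f"pedigree size:        {len(bundle.pedigree)}")
print(f"F1 genotyped:         {len(bundle.f1_ids)}")
print(f"F2 genotyped:         {len(bundle.f2_ids)} (validation set)")
print(f"marker panel:         {bundle.genotypes_f1.shape[1]} SNPs")
print(f"phenotype records:    {len(bundle.phenotypes_htj)} juvenile height")

relmat = build_A(bundle.pedigree)
ns_f1 = status_number(relmat, bundle.f1_ids)
print(f"F1 status number Ne:  {ns_f1:.1f}")

# Reusing ~30 founders across 25 families concentrates coancestry, so the
# effective population size is far below the census size — the low-Ne regime
# in which marker-based prediction is dominated by relatedness.
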