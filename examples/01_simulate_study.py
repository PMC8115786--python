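"""Generate a synthetic mini-study and look at what was planted.

The generator builds a random mini-genome, derives every cytosine's context
(CG/CHG/CHH) from the sequence on both strands, draws one pooled bisulfite
library per condition and a 3-replicate NB expression experiment over the
13-condition acclimation/dehydration design, and records all planted truth.
"""

from methylmem.simulate import SimulationParams, simulate_study

params = SimulationParams(
    n_contigs=1, contig_len=120_000, n_genes=20,
    n_short=3, n_mid=3, n_long=2, n_rdt_only=2, n_plain_deg=2,
    n_mrg_short=2, n_mrg_mid=1, n_mrg_plain=1,
)
study = simulate_study(params, seed=1)

print(f"contigs: {list(study.sequences)}; genes: {len(study.genes)}")
print("cytosines by context:")
print(study.skeleton["context"].value_counts().to_string())
print(f"conditions: {', '.join(study.design.conditions)}")
print("planted memory classes:")
print(study.truth.planted_memory_class.value_counts().to_string())
print(f"planted promoter regions: {len(study.truth.planted_regions)}")
# Each planted region shifts the true methylation level of one promoter in
# one condition, opposite in direction to that gene's planted expression
# change — the ground truth for the methylation-regulated-gene screen.
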