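"""Global methylation profile of one sample.

Per context this reports the mC frequency (what fraction of covered
cytosines are methylated above the bisulfite error rate) and the mean
methylation level over those methylated sites — the two numbers a
whole-genome bisulfite study quotes per sample. CG/CHG levels are high and
CHH low, as in plant genomes.
"""

from methylmem.methylome import global_summary
from methylmem.simulate import SimulationParams, simulate_study

study = simulate_study(
    SimulationParams(n_contigs=1, contig_len=150_000, n_genes=10), seed=2
)
for cond in ("F", "AD"):
    print(f"sample {cond}:")
    print(global_summary(study.site_tables[cond]).round(2).to_string())
    print()
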