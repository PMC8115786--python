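"""Classify dehydration-stress memory genes from per-contrast DEG flags.

Short-term memory genes respond to rapid dehydration only at the initial
stage after acclimation (AD/A), mid-term also four weeks later (A4D/A4),
long-term through eighteen weeks (A18D/A18) — all pre-induced by the slow
soil-drying acclimation itself (SD/F) and silent in non-acclimated controls.
Running the classifier on the generator's truth flags recovers every planted
class exactly, which is the point: the logic is a pure function of the flags.
"""

from methylmem.memory import classify_memory, memory_summary
from methylmem.simulate import SimulationParams, simulate_study

study = simulate_study(SimulationParams(), seed=5)
calls = classify_memory(study.truth.planted_deg)
print(memory_summary(calls).to_string(index=False))

recovered = {c.gene_id: c.category for c in calls}
planted = study.truth.planted_memory_class
n_match = sum(
    recovered[g] == cls for g, cls in planted.items() if cls != "none"
)
n_planted = int((planted != "none").sum())
print(f"planted memory genes recovered: {n_match}/{n_planted}")
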