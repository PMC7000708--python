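"""Stepwise structure search from a superset meta-model.

Simulates data from the attendance structure, starts the search from that
structure plus three spurious edges, and shows how the forward (modification
index > 3.84) and backward (p > 0.05) phases plus AICc selection prune the
model.
"""

from zoosem import default_attendance_config, run_search, simulate_variables, standardize
from zoosem.model import PathModelSpec

config = default_attendance_config()
superset = PathModelSpec(
    config.variables,
    tuple(config.edges)
    + (
        ("attendance", "area"),
        ("total_animals", "mammal_richness"),
        ("species_richness", "gdp"),
    ),
)

data = standardize(simulate_variables(config, seed=7).data)
result = run_search(superset, data)

print("search trace:")
for step in result.trace.steps:
    edge = f"{step.edge[0]} ~ {step.edge[1]}" if step.edge else "-"
    value = f"{step.statistic}={step.value:.3f}" if step.value is not None else ""
    print(f"  [{step.phase:>8}] {step.action:<6} {edge:<42} {value:<12} "
          f"AICc={step.aicc:.2f}")

true_set = set(config.edges)
final_set = set(result.spec.edges)
print()
print(f"candidates visited: {len(result.candidates)}; "
      f"selection decisive: {result.selection.decisive} "
      f"(runner-up {result.selection.delta:.2f} AICc units behind)")
print(f"spurious edges remaining: {sorted(final_set - true_set) or 'none'}")
print(f"generating edges lost:    {sorted(true_set - final_set) or 'none'}")
print()
print("Each removal lowers AICc by about (Wald z^2 - 2); truly null edges are")
print("pruned, while weak generating edges (|beta| ~ 0.1 at n=458) are the")
print("ones at risk of going with them - a power limit, not a search defect.")
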