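"""Fit a path model to data simulated from the published attendance structure.

Draws 458 synthetic institutions from the standardized structural equations of
the attendance model, z-scores the columns, fits the model by maximum
likelihood and prints fit statistics and coefficient estimates next to the
generating values.
"""

from zoosem import default_attendance_config, fit_path_model, simulate_variables, standardize

config = default_attendance_config()        # n = 458, published coefficients
sim = simulate_variables(config, seed=42)
data = standardize(sim.data, clusters=sim.clusters)

fit = fit_path_model(config.spec(), data)
print(fit.summary())
print()
table = fit.edge_table()[["lhs", "rhs", "estimate", "se", "pvalue"]].copy()
table["generating"] = [config.edges[(o, p)] for o, p in zip(table["lhs"], table["rhs"])]
print(table.round(3).to_string(index=False))
print()
print("Each estimate is a standardized direct effect; at n=458 they sit within")
print("a couple of standard errors of the generating coefficients. chi2 tests")
print("the model-implied covariance against the sample covariance (a large p")
print("means the structure is consistent with the data).")
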