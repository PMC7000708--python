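"""End-to-end run: species-level synthetic data through both analyses.

Generates a holdings table and institution covariates with known structure,
runs the attendance analysis (metrics -> standardization -> stepwise search ->
effects) and then the in situ analysis on the project-reporting subset, and
writes both report bundles.
"""

from pathlib import Path

from zoosem import (
    AnalysisConfig,
    HoldingsSimConfig,
    run_attendance_analysis,
    run_insitu_analysis,
    simulate_holdings,
)

cfg = HoldingsSimConfig(
    n_institutions=200,
    n_countries=20,
    pool_size=900,
    richness_coef=20.0,
    insitu_fraction=0.6,
)
holdings, institutions = simulate_holdings(cfg, seed=11)
print(f"simulated {len(holdings.institutions)} institutions, "
      f"{holdings.counts.shape[1]} species held, "
      f"{int(institutions['in_situ_projects'].notna().sum())} reporting in situ projects")

attendance = run_attendance_analysis(holdings, institutions,
                                     config=AnalysisConfig(seed=0))
print()
print("attendance model:")
print(attendance.fit.summary())
print("retained attendance predictors:",
      sorted(p for o, p in attendance.fit.spec.edges if o == "attendance"))

insitu = run_insitu_analysis(holdings, institutions, attendance,
                             config=AnalysisConfig(seed=0))
print()
print("in situ model (attendance-side structure frozen, GDP dropped):")
for _, row in insitu.fit.edge_table().query("lhs == 'in_situ'").iterrows():
    print(f"  in_situ ~ {row['rhs']:<18} {row['estimate']:+.3f} (p={row['pvalue']:.4f})")
print("strongest mediated pathway into in situ:")
best = max(insitu.mediation, key=lambda m: abs(m.estimate))
print(f"  {' -> '.join(best.chain)}: {best.estimate:+.3f} (z={best.z:.2f})")

out = Path("scratch") / "example_reports"
attendance.write(out / "attendance")
insitu.write(out / "insitu")
print()
print(f"report bundles written under {out} (coefficients.csv, effects.csv,")
print("fit.json, trace.json, graph.dot, metadata.json). The in situ analysis")
print("should recover a clearly positive attendance -> in situ pathway, the")
print("signature the whole system analysis is built to detect.")
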