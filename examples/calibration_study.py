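"""Empirical FWER, FDR and sensitivity of the four tests by simulation.

Generates a synthetic base of table families with FAERS-like marginals,
then re-draws exposed counts under the conditional binomial model: at
Delta = 0 every test's family-wise error is measured; at Delta > 0 one
fifth of each family's drugs carries a disparity of size Delta and FDR /
sensitivity are scored against the truth labels. Reduced scale (~15 s).
"""

from aedisparity import SimScenario, generate_synthetic_base, run_simulation

base = generate_synthetic_base(150, seed=2024)
print(f"synthetic base: {len(base)} families, "
      f"J between {min(f.J for f in base)} and {max(f.J for f in base)}")

sc0 = SimScenario(base=base, delta=0.0, aes_per_stratum=30,
                  iterations_per_ae=150, alpha=0.05, seed=5)
t0 = run_simulation(sc0).table
print("\nDelta = 0 (all nulls true): empirical FWER at nominal 0.05")
print(t0[t0.stratum == "all"][["method", "adjustment", "fwer"]]
      .pivot(index="method", columns="adjustment", values="fwer")
      .round(4).to_string())

sc1 = SimScenario(base=base, delta=0.1, aes_per_stratum=30,
                  iterations_per_ae=150, alpha=0.05, seed=5)
t1 = run_simulation(sc1).table
print("\nDelta = 0.1 (20% of drugs shifted): FDR and sensitivity")
sub = t1[t1.stratum == "all"]
print(sub[["method", "adjustment", "fdr", "sensitivity"]]
      .round(4).to_string(index=False))

print("\nLR and normal tests hold the 5% level and FDR; the subgroup-ratio"
      "\ntests (PRR/ROR) inflate both, so their detections are not"
      "\nerror-controlled and cannot be compared on sensitivity alone.")
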