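"""Simulate multi-study genotype data with known truth and recover it.

Generates case-control genotype counts under a per-allele odds ratio
psi = 1.5 with no between-study heterogeneity, analyzes each replicate with
the full pipeline, and summarizes estimator behaviour: the mean pooled OR
should sit near 1.5, CI coverage near 95%, and tau2 near 0.
"""

import math

from snpmeta import SimConfig, recover_parameters, simulate_studies

cfg = SimConfig(k=10, n_cases=800, n_controls=800, q=0.2, psi=1.5, tau=0.0, seed=42)

table = simulate_studies(cfg)
print("one simulated table:")
print(table.to_dataframe().to_string(index=False))

summary = recover_parameters(cfg, n_reps=200)
print(f"\nover {summary.n_reps} replicates (true per-allele OR = {cfg.psi}):")
print(f"  mean pooled OR        {math.exp(summary.mean_log_or):.3f}")
print(f"  95% CI coverage       {summary.ci_coverage:.3f}")
print(f"  mean tau2             {summary.mean_tau2:.4f}")
print(f"  Q-test rejection rate {summary.q_rejection_rate:.3f} (alpha = .10)")
print("\nCoverage near .95 and mean OR near the truth indicate the pooled")
print("estimator and its Wald interval are well calibrated at this scale.")
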