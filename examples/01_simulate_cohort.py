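"""Simulate a small screening cohort: genotypes, event clouds, outcomes.

Generates LD-structured genotypes, per-donor cytometry events under three
conditions with a genetic effect on the evoked NE2 neutrophil gate, and
EHR-style outcome records with delayed entry.
"""

import numpy as np

from hemascan import (
    CausalEffect,
    OutcomeEffect,
    SimulationConfig,
    simulate_covariates,
    simulate_donor_states,
    simulate_events,
    simulate_genotypes,
    simulate_outcomes,
)
from hemascan.simulate import latent_frame

cfg = SimulationConfig(
    n_donors=100,
    n_variants=200,
    events_per_sample=1_000,
    causal_effects=[CausalEffect(50, "Pam3CSK4_19h", "NE2", 1.0)],
    outcome_effects=[OutcomeEffect("tone", "T2D", 0.3)],
    seed=1,
)

gm = simulate_genotypes(cfg)
print(f"genotypes: {gm.n_donors} donors x {gm.n_variants} variants")
print(f"  MAF range {gm.variants['maf'].min():.3f}-{gm.variants['maf'].max():.3f}")
r = np.corrcoef(gm.dosages[:, 0], gm.dosages[:, 1])[0, 1]
print(f"  adjacent-variant LD r^2 = {r**2:.2f} (ld_rho = {cfg.ld_rho})")

states = simulate_donor_states(cfg, gm)
tables = simulate_events(states[0], "Pam3CSK4_19h", cfg)
print(f"\ndonor {states[0].donor}, Pam3CSK4_19h: "
      f"{len(tables)} channel event tables, {tables[0].n} events each")

cov = simulate_covariates(cfg, states)
out = simulate_outcomes(latent_frame(states), cfg)
cases = out["diagnosis_age"].notna() | out["problem_list_only"]
print(f"\noutcomes for {out['outcome'].nunique()} endpoints: "
      f"{cases.sum()} case records / {len(out)} donor-endpoint pairs")
print("mean entry age %.1f, mean eGFR %.1f" % (out["entry_age"].mean(), cov["eGFR"].mean()))
# The causal variant shifts the NE2 gate weight per effect allele; the
# tone latent links disease status to evoked gate weights and outcomes.
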