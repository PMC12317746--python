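"""Full two-stage pipeline: integrate samples and detect shared domains.

Simulates four samples with strong sample-wise batch effects, runs the
pipeline, and scores the recovered domains against the simulated regions.
Because stage 2 only connects mutually nearest niches *across* samples (and
embeds with Pearson residuals), the batch shift barely hurts recovery.
"""

import spatialmnn as sm

sims = sm.simulate_dataset(sm.SimConfig(
    n_samples=4, seed=23, batch_shift_frac=5.0, batch_var_frac=1.25))
print("per-sample batch shifts:", [round(x.Es, 1) for x in sims])

out = sm.run_pipeline([x.sample for x in sims], sm.RunConfig(seed=23))
print(f"detected {out.n_domains} shared domains "
      f"(simulation has 4 regions)")

for sim in sims:
    p = next(q for q in out.partitions
             if q.sample_id == sim.sample.sample_id)
    truth = sim.regions[p.kept_units]
    pred = out.unit_domain[p.sample_id]
    print(f"  {p.sample_id}: {p.n_niches} niches, "
          f"ARI {sm.ari(truth, pred):.3f}, NMI {sm.nmi(truth, pred):.3f}")
print("ARI/NMI near 1 mean the shared domain labels line up with the "
      "ground-truth tissue regions in every sample despite the batch shift.")
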