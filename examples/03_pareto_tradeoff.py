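"""Trace the biomass-vs-product Pareto front of a toy producer.

The front answers: at a given growth rate, what is the best attainable
product rate?  Its shape shows where growth and production compete.
"""

from strepflux import ToyModelSpec, compute_pareto, generate_toy_model

model, truth = generate_toy_model(ToyModelSpec())
front = compute_pareto(model, truth.biomass_id, truth.product_id, n_steps=10)

print(f"front: clamp {front.objective_a_id}, maximize {front.objective_b_id}")
print(f"{'mu (1/h)':>10s} {'max q_p (mmol/gDW/h)':>22s}")
for p in front.points:
    print(f"{p.fixed_value:10.3f} {p.max_value:22.4f}")

# Expected: q_p stays at the supply-capped 0.5 while carbon is abundant,
# then falls to 0 as the biomass clamp approaches mu_max = 1.0 — the
# zero-growth endpoint equals the single-objective product maximum, and
# production only ever decreases as growth increases.
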