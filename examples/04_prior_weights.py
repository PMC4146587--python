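"""Use literature-style prior knowledge as weighted regularization.

Known regulations get penalty weights below 1, making them cheaper to select
than unknown candidates.  Here the generating edges are declared as priors
with weight 0.3 and the search is compared with and without them.
"""

import varssm as v

spec = v.cascade_pathway()
grid = v.TimeGrid.from_observed(v.DEFAULT_OBSERVED_TIMES, k=1)
data = v.simulate_linear_course(spec, grid, v.DrugSchedule(C0=5, kel=0.3),
                                v.NoiseModel(rho=0.01, system_sd=0.0, floor=1e-6),
                                replicates=3, seed=7)
gi = {g: i for i, g in enumerate(data.genes)}

plain = v.PenaltyConfig.default(5, 1)
weighted = v.PenaltyConfig.default(5, 1)
for reg, tgt in data.truth:
    weighted.cA[gi[tgt], gi[reg]] = 0.3

for label, pen in (("unweighted", plain), ("priors w=0.3", weighted)):
    est = v.search(data, grid, pen, v.SearchConfig(C_max=3))
    edges = {(e.regulator, e.target) for e in est.edges if not e.is_exogenous}
    c = v.confusion(data.truth, edges, data.genes)
    print(f"{label:>13s}: precision {c.pr:.3f}  recall {c.rr:.3f} "
          f"(TP {c.tp}, FP {c.fp}, FN {c.fn})")
print("Down-weighting known edges makes the penalty prefer them over "
      "correlated impostors, typically trading false positives for trues.")
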