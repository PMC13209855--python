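"""Powder quality control on one formulation batch: moisture, solubility,
encapsulation efficiency, densities, and flowability indices.

Each metric is computed per analytical replicate and then averaged — the
standard reporting convention for triplicate bench assays — which for
nonlinear quantities (EE, Carr's Index, Hausner Ratio) differs from
evaluating the formula at the replicate means.
"""

from capmetrics import powder

# triplicate oven-drying masses (g): initial, dried
moisture_reps = [(2.0000, 1.9314), (2.0011, 1.9329), (1.9987, 1.9302)]
mc = [powder.moisture_content(mi, md) for mi, md in moisture_reps]
mean, sd, n = powder.summarize_replicates(mc)
print(f"moisture content:  {mean:.2f} ± {sd:.2f} % (n={n})")

# solubility from dried supernatant aliquots (g residue per 10 g aliquot)
sol = [powder.solubility(r, powder_mass=0.100) for r in (0.0282, 0.0285, 0.0279)]
mean, sd, n = powder.summarize_replicates(sol)
print(f"water solubility:  {mean:.2f} ± {sd:.2f} %")

# encapsulation efficiency from surface and total oil (g/100 g)
ee = [powder.encapsulation_efficiency(s, t)
      for s, t in [(20.1, 35.2), (20.6, 36.4), (20.7, 35.4)]]
mean, sd, n = powder.summarize_replicates(ee)
print(f"encaps. efficiency:{mean:6.2f} ± {sd:.2f} %")

# flowability from bulk (poured) and tapped density
rho_b = powder.bulk_density(3.9466, 10.0)                    # g/mL
rho_t = powder.tapped_density(5.0, [10.0, 8.1, 7.55, 7.51])  # <1% settled
flow = powder.flowability_indices(rho_b, rho_t)
print(f"bulk density:      {powder.g_ml_to_kg_m3(rho_b):.1f} kg/m³")
print(f"tapped density:    {powder.g_ml_to_kg_m3(rho_t):.1f} kg/m³")
print(f"Carr's Index:      {flow.carr_index:.1f} %   (>38% = very poor flow)")
print(f"Hausner Ratio:     {flow.hausner_ratio:.2f}     (>1.6 = cohesive powder)")
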