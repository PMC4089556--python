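"""Generate the three synthetic data streams consumed by the pipeline.

Each table mimics the corresponding study data: drug quantities per
compartment under the 14-day sampling design, omics fold-changes at days
1/3/14 for 13 species at two doses (227 values after mimicking the study's
incomplete design), and per-line viability dose-response curves.
"""

from nrf2pk import (SyntheticScenario, generate_omics_dataset,
                    generate_pk_dataset, generate_viability_dataset)

scenario = SyntheticScenario(seed=7)

pk = generate_pk_dataset(scenario)
print(f"drug measurements: {len(pk)} rows")
print(pk.head(4).to_string(index=False))

om = generate_omics_dataset(scenario, drop=7)
print(f"\nomics fold-changes: {len(om)} values")
print(om.groupby("species")["fold_change"].mean().round(2).to_string())

vi = generate_viability_dataset(scenario)
print(f"\nviability observations: {len(vi)} rows, "
      f"lines {sorted(vi.cell_line.unique())}")
print("""
Noise is multiplicative lognormal (per-type geometric SDs) for drug and
omics values -- matching the calibration likelihood -- and additive normal
for viability fractions.""")
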