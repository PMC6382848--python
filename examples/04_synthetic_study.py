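"""Generate a reduced synthetic study and inspect the analysis table.

The scenario allocates cells to the three mean-annual-rainfall ranges
(dry R1 <= 630, mesic R2 630-1200, humid R3 1200-2500 mm/y), adds cells
that the land-cover filters must remove, and draws tree/grass cover from
the built-in generating models on standardized predictors.
"""

from tgbcover import Scenario, make_dataset

scenario = Scenario(n_cells={"R1": 80, "R2": 80, "R3": 40}, n_masked_cells=20, seed=1)
study = make_dataset(scenario)

print(f"cells generated: {study.n_cells} (incl. {scenario.n_masked_cells} to be masked)")
print(f"analysis table:  {len(study.cell_table)} cells")
print(study.cell_table["mar_range"].value_counts().to_string())
print()
print(study.cell_table.head(5).round(3).to_string(index=False))
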