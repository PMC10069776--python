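"""Simulate MCAR, MAR and MNAR missingness in a near-complete table.

MCAR plans are nested across proportions; MAR masks follow a logistic
missingness model fitted to a gappy reference table (with the intercept
calibrated to a target amount); MNAR deletes a distribution tail or a
whole category.
"""

import numpy as np

import phyloimpute as pi
from phyloimpute.traits import apply_transforms

spec = pi.default_simulation_spec(n_taxa=120, seed=9, pre_missing_fraction=0.0)
tree = pi.simulate_tree(spec)
table = apply_transforms(pi.simulate_traits(tree, spec))

# --- MCAR: nested plans, exactly round(p*n) cells per trait
plans = pi.mask_mcar(table, [0.10, 0.20, 0.30], replicate_seed=1)
for p in plans:
    print(f"MCAR @ {p.proportion_label}: {len(p.cells)} cells "
          f"({len(p.cells_for('latitude'))} in latitude)")
print("0.10 subset of 0.20:", plans[0].cells < plans[1].cells)

# --- MAR: fit missing(latitude) ~ other traits on a reference whose gaps
# really do depend on body size, then mask the table with it.
reference = pi.inject_mar_missingness(table, "latitude", "svl_female",
                                      intercept=-1.5, slope=2.0, seed=2)
model = pi.fit_mar_model(reference, "latitude")
print("\nMAR model predictors for latitude:", model.predictors)
plan = pi.mask_mar(table, model, target_proportion=0.2, replicate_seed=3)
print(f"MAR masked {len(plan.cells)} cells (target {round(0.2 * table.n_species)})")

# --- MNAR: the lower decile of a numeric trait; one whole category.
plan = pi.mask_mnar(table, "clutch_largest", {"side": "lower", "fraction": 0.10})
vals = np.exp([table.data.at[sp, "clutch_largest"] for sp, _ in plan.cells])
print(f"\nMNAR masked clutch values (lower decile): {sorted(round(float(v)) for v in vals)}")
plan = pi.mask_mnar(table, "insular", {"category": "yes", "fraction": 1.0})
print(f"MNAR masked every observed 'yes' insular cell: {len(plan.cells)} cells")
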