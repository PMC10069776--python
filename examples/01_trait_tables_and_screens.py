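"""Build a trait table, apply the dataset-construction screens, transform.

Shows the small worked-example table, the severe-outlier rule
(Q3 + 3*IQR), the 90% class-imbalance screen, and the near-complete-case
filter that every downstream step operates on.
"""

import numpy as np

import phyloimpute as pi

table, tree = pi.make_worked_example()
print("worked example:", table.n_species, "species x", len(table.specs), "traits")
print(table.data, end="\n\n")

# Severe-outlier screen on a vector with one extreme value.  Q3 = 4 and
# IQR = 2, so the threshold is 10 and only the 100 is flagged.
flagged = pi.detect_severe_outliers([1, 2, 3, 4, 100])
print("outlier indices in [1,2,3,4,100]:", flagged)

# Class-imbalance screen: a categorical trait with > 90% of observations in
# one category carries too little information to impute or score.
print("keep 91:9 split?", pi.screen_class_imbalance(["a"] * 91 + ["b"] * 9))
print("keep 90:10 split?", pi.screen_class_imbalance(["a"] * 90 + ["b"] * 10))

# Near-complete-case filter: every trait ends at <= 10% missingness and any
# gappy row keeps >= 3 observed companion traits.
near = pi.build_near_complete_case(table)
print("near-complete rows:", near.n_species, "of", table.n_species)
for tr in near.trait_names:
    print(f"  {tr:10s} missingness {near.missing_fraction(tr):.2f}")

# Natural-log model scale for the numeric traits (and back).
work = pi.apply_transforms(near)
print("\nbody_size on model scale:", np.round(work.data["body_size"].values, 3))
back = pi.invert_transforms(work)
print("round-trip max error:",
      float(np.nanmax(np.abs(back.data["body_size"] - near.data["body_size"]))))
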