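"""Generate a study-shaped synthetic cohort and inspect its raw codes.

130 persons answer 118 ICF items (59 body-function 'b' codes, 59
activity/participation 'd' codes) on the 0-4 qualifier scale, with 8/9
missing codes sprinkled in and a binary group label (~28% minority).
"""

import numpy as np

from icfscale import make_study_like_fixture

matrix, groups, items = make_study_like_fixture(seed=1)

codes, counts = np.unique(matrix.values, return_counts=True)
print(f"cohort: {matrix.n_persons} persons x {matrix.n_items} items")
print(f"b-items: {sum(c.startswith('b') for c in matrix.item_codes)}, "
      f"d-items: {sum(c.startswith('d') for c in matrix.item_codes)}")
print("code frequencies:")
for c, n in zip(codes, counts):
    print(f"  code {int(c)}: {n:5d} cells")
print(f"group label: {groups.sum()} of {len(groups)} persons in the minority group")
print()
print("Codes 0-4 grade impairment severity (0 = none, 4 = complete); 8 and 9")
print("are the 'not specified' / 'not applicable' missing codes the shaping")
print("stage recodes to missing before imputation.")
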