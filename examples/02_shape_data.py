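"""Run the data-shaping stage: from ordinal qualifier codes to a clean
binary functioning/disabled matrix.

Order of operations: recode 8/9 to missing -> drop persons with > 30%
missing -> drop items with >= 5% missing -> kNN imputation (k = 5) ->
binarize (codes 0-1 = functioning = 1) -> Guttman-error person screen
(adjusted boxplot fence) -> drop constant items.
"""

from icfscale import make_study_like_fixture
from icfscale.shaping import shape

matrix, _, _ = make_study_like_fixture(seed=1)
result = shape(matrix)

print(f"input: {matrix.n_persons} x {matrix.n_items}")
print(f"items removed for missingness (>= 5%): {len(result.removed_items_missing)}")
print(f"persons removed for missingness (> 30%): {len(result.removed_persons_missing)}")
g = result.guttman_report
print(f"Guttman errors G+: median {int(sorted(g.g_plus)[len(g.g_plus) // 2])}, "
      f"max {int(g.g_plus.max())}, adjusted fence {g.upper_fence:.2f}")
print(f"persons flagged as G+ outliers: {len(result.removed_persons_guttman)}")
print(f"constant items dropped: {len(result.removed_items_degenerate)}")
print(f"shaped binary matrix: {result.binary.n_persons} x {result.binary.n_items}")
print()
print("G+ counts response patterns that pass a harder item while failing an")
print("easier one; persons far above the skew-adjusted fence answer too")
print("inconsistently to scale and are excluded.")
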