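"""The Mann-Whitney test at the heart of the scan, on hand-checkable inputs.

With tie-free pooled samples of at most 16 values the p-value comes from the
complete null distribution of U over all C(n1+n2, n1) group assignments;
larger or tied samples use a tie-corrected normal approximation with
continuity correction.
"""

from mirenrich import mann_whitney

u, p, method = mann_whitney([1, 2, 3], [4, 5, 6], alternative="less")
print(f"x={{1,2,3}} vs y={{4,5,6}}, 'less':    U={u:.1f} p={p:.4f} ({method})")
print("  -> the all-smallest split is 1 of the C(6,3)=20 assignments: p=1/20")

u, p, method = mann_whitney([5], [1, 2, 3, 4], alternative="greater")
print(f"x={{5}} vs y={{1,2,3,4}}, 'greater': U={u:.1f} p={p:.4f} ({method})")
print("  -> the largest value has 5 possible placements: p=1/5")

u, p, method = mann_whitney([1, 2, 3], [1, 2, 3])
print(f"identical samples, two-sided:      U={u:.1f} p={p:.4f} ({method})")
print("  -> ties force the approximation; U=n1*n2/2 and p clamps to 1")
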