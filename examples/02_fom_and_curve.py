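"""The Wilcoxon figure of merit and the empirical AFROC curve.

Reduces a scored response to rating data by hand and shows that the
trapezoidal area under the (1,1)-extended AFROC curve equals the
pairwise Wilcoxon statistic when every rating is finite.
"""
from kyt_froc import RatingData, afroc_curve, compute_fom

# two hazard points: detected at ratings 0.8 and 0.4
# two hazard-free scenes: one carries an FP maximum 0.5, one is unmarked
data = RatingData(
    lesion_ratings={"hp1": 0.8, "hp2": 0.4},
    normal_fp_max={"n1": 0.5},
)
theta = compute_fom(data, n_lesions=2, n_fp_scenes=2)
print(f"figure of merit theta = {theta:.3f}")
# 4 pairs: (0.8 vs 0.5)=1, (0.8 vs unmarked)=1, (0.4 vs 0.5)=0,
# (0.4 vs unmarked)=1  ->  3/4

curve = afroc_curve(data, n_lesions=2, n_fp_scenes=2)
print("AFROC operating points (threshold, FPF, LLF):")
for p in curve.points:
    print(f"  {p.threshold!s:>5}  ({p.fpf:.2f}, {p.llf:.2f})")
print(f"area (Wilcoxon)    = {curve.area:.3f}")
print(f"area (trapezoidal) = {curve.trapezoid_area():.3f}")
# The curves agree here; with undetected points or unmarked scenes the
# Wilcoxon sum stays the definition of record and the polyline is
# display-only.

complete = RatingData(
    lesion_ratings={"hp1": 0.9, "hp2": 0.6},
    normal_fp_max={"n1": 0.6, "n2": 0.2},
)
c = afroc_curve(complete, 2, 2)
print(
    f"complete ratings: wilcoxon {c.area:.4f} == "
    f"trapezoid {c.trapezoid_area():.4f}"
)
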