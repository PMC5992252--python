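"""Walkthrough: screen many causes for hump candidates.

A 20-year noisy surface is simulated with slowly drifting hump heights.
For each cause and year the screen computes the distance between the
cause-deleted and all-cause first differences of the force of mortality
(ages 10-34), projects the cause x year distance matrix on two principal
components for visual review, and proposes a flag set from the
noise-aware drawdown rule: a hump cause must rise and then fall inside
the window, so its pooled rate shows a statistically significant
maximum drawdown; a monotone Gompertz-type cause does not.
"""

from humpdec import drawdown_zscores, multi_year_surface, select_causes

surf = multi_year_surface(n_years=20, seed=2024)
res = select_causes(surf)

print("shape-distance matrix (first 5 years):")
print(res.distances.iloc[:, :5].to_string(float_format=lambda v: f"{v:.5f}"))

print("\nPCA scores (2 axes, explained "
      f"{res.explained[0]:.2f} + {res.explained[1]:.2f}):")
print(res.scores.to_string(float_format=lambda v: f"{v:.2f}"))

z = drawdown_zscores(surf)
print("\ndrawdown z-scores (flag if > 6):")
print(z.to_string(float_format=lambda v: f"{v:.1f}"))

print("\nflagged hump candidates:", res.flagged)
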