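"""Screen calculated structural features against stability attributes.

For each feature-attribute pair over a variant panel, a Pearson r and a
two-sided p (t statistic, n-2 dof) are computed; a pair is flagged when
|r| > 0.5 and p < 0.1.  Here one association (DI vs DLS growth rate) is
planted at rho = 0.8 in a 12-sample synthetic panel next to null columns.
"""

from vhhfc.fixtures import make_stability_table
from vhhfc.stats import correlation_screen, screen_frame

features, attributes, truth = make_stability_table(
    n_samples=12,
    planted={("di", "dls_rate_nm_per_week"): 0.8},
    n_null_features=3,
    seed=2024,
)

results = correlation_screen(features, attributes)
frame = screen_frame(results)[["feature", "attribute", "r", "p", "significant"]]
print(frame.round(3).to_string(index=False))
print()
print("Only the planted DI/DLS pair clears |r| > 0.5 with p < 0.1; the null")
print("features stay unflagged, which is what a calibrated screen should do.")
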