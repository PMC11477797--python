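"""Williams-plot applicability-domain analysis of a fitted model.

A prediction is reliable only inside the training data's descriptor-space
region: leverage h above h* = 3(p+1)/n flags structural outliers
(extrapolation), |standardized residual| > 3 flags response outliers.
"""

from pacqsar import fit_mlr, williams, williams_plot
from pacqsar.synthetic import generate_regression, model1_like_spec

data = generate_regression(model1_like_spec(seed=1))
model = fit_mlr(data)
report = williams(model, data)

print(f"h* = {report.h_star:.3f}  (n=62 compounds, p=7 descriptors)")
counts = report.table["ad_class"].value_counts()
for cls, cnt in counts.items():
    print(f"  {cls:>20s}: {cnt}")

outliers = report.outliers()
if len(outliers):
    print("\ncompounds to treat with caution:")
    print(outliers[["id", "h", "sr", "ad_class"]].to_string(index=False))

williams_plot(report, "williams.svg")
print("\nwrote williams.svg (leverage vs standardized residual with h* and "
      "±3 guides)")
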