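"""Choose the ridge pair on a grid under the four selection criteria and
compare their computational cost.

The unsupervised criterion refits CCA once per held-out sample at every grid
point (v*n factorizations); the three supervised criteria — Welch t,
Wilcoxon rank-sum, Wilks lambda on the first canonical component — need a
single factorization per grid point (v), an order-n saving at identical grid
resolution.
"""

from srcca import SyntheticSpec, generate_two_view, make_grid, select_parameters

ds = generate_two_view(SyntheticSpec(), seed=0)
grid = make_grid(0.001, 0.2, 20)

for criterion, labels in [("rcca-loo", None), ("tt", ds.labels),
                          ("wrst", ds.labels), ("wlt", ds.labels)]:
    res = select_parameters(ds.x_view, ds.y_view, labels, grid, criterion)
    print(f"{criterion:8s} -> lambda = ({res.lambda_x:.3f}, {res.lambda_y:.3f}) "
          f"using {res.factorizations:4d} CCA factorizations")
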