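"""Fit plain and ridge-regularized CCA on a small two-view dataset and show
why regularization is indispensable when n < p + q + 1.

With 19 samples against 76 total features, plain CCA's auto-covariances are
singular: every in-sample canonical correlation saturates at 1 and the
leading embedding components become mutually correlated — they carry the
same (overfitted) information.  A modest ridge restores distinct,
essentially uncorrelated components with honest correlations below 1.
"""

import numpy as np

from srcca import SyntheticSpec, compute_covariances, generate_two_view, project, solve_rcca

ds = generate_two_view(SyntheticSpec(), seed=0)  # n=19, p=25, q=51
cov = compute_covariances(ds.x_view, ds.y_view)

plain = solve_rcca(cov, 0.0, 0.0, d=3)
emb = project(ds.x_view, plain, "x", 2)
print("plain CCA      corr:", np.round(plain.correlations, 4),
      " degenerate:", plain.degenerate)
print("  |corr(comp1, comp2)| of the embedding:",
      round(abs(np.corrcoef(emb.T)[0, 1]), 3))

ridged = solve_rcca(cov, 0.05, 0.05, d=3)
emb_r = project(ds.x_view, ridged, "x", 2)
print("ridge λ=0.05   corr:", np.round(ridged.correlations, 4),
      " degenerate:", ridged.degenerate)
print("  |corr(comp1, comp2)| of the embedding:",
      round(abs(np.corrcoef(emb_r.T)[0, 1]), 4))
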