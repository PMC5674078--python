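"""The a priori similarity map: unscaled PCA of the descriptor table.

Because melting point and molecular mass have far larger numeric spreads
than the other six descriptors, covariance (unscaled) PCA places nearly all
variance in two components, and the biplot shows MP and Mr as two dominant
near-orthogonal arrows.
"""

import numpy as np

from thzchem import biplot_vectors, pca_fit, simulate_descriptors

desc = simulate_descriptors(27, seed=1)
model = pca_fit(desc.to_numpy(float), n_components=2, scale=False)
evr = model.explained_variance_ratio
print(f"PC1 + PC2 explain {100 * evr.sum():.1f}% of descriptor variance "
      f"({100 * evr[0]:.1f}% + {100 * evr[1]:.1f}%)")

bi = biplot_vectors(model, feature_names=list(desc.columns))
lengths = np.linalg.norm(bi.arrows, axis=1)
for name, (x, y), L in zip(bi.feature_names, bi.arrows, lengths):
    print(f"  {name:>5}: arrow = ({x:8.2f}, {y:8.2f})  |length| = {L:7.2f}")

mp = bi.arrows[list(desc.columns).index("MP")]
mr = bi.arrows[list(desc.columns).index("Mr")]
cos = mp @ mr / (np.linalg.norm(mp) * np.linalg.norm(mr))
print(f"cos(angle MP, Mr) = {cos:.3f}: the two dominant descriptors are "
      "nearly orthogonal, so the 2D map is effectively an (MP, Mr) plane.")
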