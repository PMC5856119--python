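"""Segment a scene by hierarchical K-means and fuse with the supervised map.

Each cluster collects the supervised labels of its pixels into a density
vector; majority voting gives the cluster a class, and the TMD rendering
blends the top-3 densities into one colour per cluster.
"""

import numpy as np

from hsbrain import (ClassifierConfig, PhantomSpec, PreprocessConfig,
                     calibrate, class_densities, cluster_sizes,
                     generate_dataset, hierarchical_kmeans, knn_filter,
                     pca_first_component, predict_probabilities, preprocess,
                     render_tmd, train_classifier)
from hsbrain.constants import CLASS_NAMES

spec = PhantomSpec(rows=64, cols=64, bands=100)
chain = PreprocessConfig(target_bands=64)
ds, (scene,) = generate_dataset(spec, n_subjects=3, seed=5,
                                preprocess_config=chain, max_per_class=200)
model = train_classifier(ds, ClassifierConfig(seed=5))
cube = preprocess(calibrate(scene.raw, scene.refs).cube, chain)
filtered = knn_filter(predict_probabilities(model, cube),
                      pca_first_component(cube), K=25)

seg = hierarchical_kmeans(cube, K=8, seed=5)
dens = class_densities(seg, filtered)
tmd = render_tmd(seg, dens)

print("cluster  size  vote        top densities")
for k in range(seg.K):
    order = np.argsort(-dens.densities[k])[:3]
    tops = ", ".join(
        f"{CLASS_NAMES[[1, 2, 3, 4][j]]}={dens.densities[k][j]:.2f}"
        for j in order if dens.densities[k][j] > 0)
    print(f"{k:>7}  {cluster_sizes(seg)[k]:>4}  "
          f"{CLASS_NAMES[int(tmd.votes[k])]:<10}  {tops}")
print("\neach cluster is painted with the convex blend of its top-3 class"
      "\ncolours (tumor red, normal green, vessel blue, background black)")
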