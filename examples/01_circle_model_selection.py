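"""Automatic (sigma, k) selection on a nonlinear-boundary clustering problem.

Builds three concentric rings of 2-D points, runs K-spectral clustering over
a grid of affinity bandwidths and cluster counts, and selects the pair with
minimal compactness W/B.  Plain k-means is shown for contrast: it cuts the
rings by angle and fails, while the spectral embedding separates them.
"""

from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from epireg import generate_circles, select_parameters
from epireg.dimreduction import default_sigma_grid

points, rings = generate_circles(n_per_ring=100, radii=(1.0, 3.0, 5.0),
                                 noise_sd=0.05, seed=2)
sigma, k, result = select_parameters(points, default_sigma_grid(points),
                                     k_grid=[2, 3, 4, 5], seed=2)
kmeans = KMeans(n_clusters=3, n_init=10, random_state=0).fit(points)

print(f"selected bandwidth sigma = {sigma:.3f}, cluster count k = {k}")
print(f"compactness (W/B) at the optimum = {result.score:.4f}")
print(f"spectral clustering vs true rings: ARI = "
      f"{adjusted_rand_score(rings, result.labels):.3f}")
print(f"k-means on raw coordinates:        ARI = "
      f"{adjusted_rand_score(rings, kmeans.labels_):.3f}")
print()
print("ARI = 1 means the three rings are recovered exactly; k-means near 0")
print("shows why the spectral step matters for nonlinear cluster boundaries.")
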