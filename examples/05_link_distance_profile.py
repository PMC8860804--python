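"""Distance profile of connected region pairs across coupling types.

Compares the Euclidean centroid distances of the links found by each
connectivity measure with a one-way ANOVA and Dunn-Sidak-corrected
post-hoc t-tests — the question being whether one coupling mechanism
preferentially spans longer distances than the others.

Here the networks are built directly (as if returned by the NBS stage)
over the package's synthetic atlas geometry.
"""

import numpy as np

from dirconn import (
    DirectedNetwork,
    link_distance_anova,
    link_distances,
    synthetic_roi_table,
)

rng = np.random.default_rng(2)
table = synthetic_roi_table(84)
centroids = table.centroids


def random_network(n_links, long_range=False):
    links = []
    while len(links) < n_links:
        a, b = rng.integers(0, 84, size=2)
        if a == b:
            continue
        d = np.linalg.norm(centroids[a] - centroids[b])
        if long_range and d < 80:  # keep only distant pairs
            continue
        links.append((int(a), int(b), float(rng.normal(4, 0.5))))
    return DirectedNetwork(links=links, p_value=0.01)


networks = {
    "dpli_theta": [random_network(22)],
    "dpli_gamma": [random_network(16)],
    "nmi": [random_network(20, long_range=True)],
}
groups = {m: link_distances(nets, centroids) for m, nets in networks.items()}
for m, d in groups.items():
    print(f"{m}: {len(d)} links, mean distance {d.mean():.1f} mm")

report = link_distance_anova(groups)
print(f"\none-way ANOVA: F = {report['F']:.2f}, p = {report['p']:.2e}")
print("post-hoc t-tests (Dunn-Sidak adjusted):")
print(report["posthoc"].to_string(index=False))
print(
    "\nA significant F with the PAC group sitting above the phase-synchrony\n"
    "groups indicates phase-amplitude coupling links span longer distances."
)
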