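"""Recovering a planted coupling network with the directed NBS.

Simulates 12 subjects x 2 conditions where, in the "memory" condition
only, the high-theta phase of three regions modulates the gamma
amplitude of a common target region (a 3-link star).  Per-subject nMI
matrices are computed through the full preprocessing chain, logit
transformed, and contrasted across conditions with the directed
network-based statistic (paired t-test first level, weakly connected
components, max-component-size permutation null).
"""

from dirconn import PlantedPacLink, SimulationConfig, gen_dataset, nbs_paired
from dirconn.pipeline import all_connectivity

PLANTED = [(0, 5), (1, 5), (2, 5)]
cfg = SimulationConfig(
    n_subjects=12, n_rois=20, n_trials=2, trial_duration=10.0,
    planted_pac_links=tuple(PlantedPacLink(i, j, depth=0.8) for i, j in PLANTED),
    seed=42,
)
print("simulating", cfg.n_subjects, "subjects,", cfg.n_rois, "ROIs ...")
dataset = gen_dataset(cfg)
stacks = all_connectivity(dataset)
networks = nbs_paired(
    stacks["nmi"]["memory"], stacks["nmi"]["math"], n_perm=1000, seed=1
)

print(f"planted links: {sorted(PLANTED)}")
for net in networks:
    print(
        f"significant component: {net.n_links} links / {net.n_nodes} nodes, "
        f"p = {net.p_value:.4f}"
    )
    for src, dst, t in sorted(net.links):
        tag = " (planted)" if (src, dst) in PLANTED else ""
        print(f"  {src:2d} -> {dst:2d}   t = {t:5.2f}{tag}")
    types = net.node_types
    print("  node types:", {k: types[k] for k in sorted(types)})
if not networks:
    print("no significant component found")
print(
    "\nThe component-level p is the fraction of condition-swap permutations\n"
    "whose largest weakly connected component is at least as big."
)
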