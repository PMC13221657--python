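"""Gene-wise bootstrap confidence intervals for node ages.

Loci are resampled with replacement; each replicate re-optimizes branch
lengths on the fixed topology, re-dates the tree under the same
calibrations, and contributes one age per node. The 2.5th/97.5th
percentiles give per-node 95% intervals.
"""

from cycadphylo import bootstrap, simulate
from cycadphylo.likelihood import poisson_model
from cycadphylo.phyloio import CalibrationConstraint

config = simulate.SimulationConfig(
    seed=5, n_taxa=8, n_loci=40, sites_per_locus=150,
    theta=1.0, sigma_rate=0.2, dup_fraction=0.0, occupancy_target=1.0,
)
ds = simulate.simulate_dataset(config)
c1, c2 = ds.species_tree.seed_node.child_nodes()
calibrations = [CalibrationConstraint(
    "crown",
    next(l.taxon.label for l in c1.leaf_iter()),
    next(l.taxon.label for l in c2.leaf_iter()),
    300.0, 300.0,
)]

table = bootstrap.genewise_bootstrap(
    ds.alignments, ds.phylogram, poisson_model(), calibrations,
    lam=1.0, n_replicates=40, seed=5,
)
truth = ds.true_ages()
print("node age 95% CIs (true age in brackets):")
for tips in table.nodes():
    lo, hi = table.ci(tips)
    mark = "*" if lo <= truth.get(tips, -1) <= hi else " "
    print(f"  [{lo:7.1f}, {hi:7.1f}] {mark} (true {truth.get(tips, float('nan')):7.1f})")
print(f"mean 95% CI width: {table.mean_ci_width():.2f} Ma")
# Widths reflect among-locus variation (gene-specific rates, coalescent
# noise, finite sites); a starred interval covers the true age.
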