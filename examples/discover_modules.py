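"""Discover candidate modules in a simulated cohort with known truth.

Generates a 200-sample cohort with three planted 4-gene exclusive
modules, runs the greedy discovery over the reduced influence network,
and prints the top catalog entries per size next to the planted truth.
"""

from unicovex import (
    DiscoveryConfig,
    PlantedCohortParams,
    build_catalog,
    generate_planted_cohort,
    reduce_to_average_degree,
)

cohort = generate_planted_cohort(PlantedCohortParams(seed=1))
print("planted truth modules:")
for truth in cohort.truth_modules:
    print("  ", ";".join(sorted(truth)))

net = reduce_to_average_degree(cohort.network, 15)
catalog = build_catalog(cohort.matrix, net, DiscoveryConfig())
print(f"\ncatalog: {catalog.n_modules} distinct candidate modules")
for size in sorted(catalog.by_size):
    print(f"size {size}:")
    for mod in catalog.by_size[size][:3]:
        s = mod.score
        print(
            f"   {';'.join(sorted(mod.genes)):28s} composite={s.composite:7.2f} "
            f"Ex={s.ex_score:.2f} H={s.entropy:.2f} cov={s.min_coverage}"
        )
print(
    "\nThe top size-4 entries are the planted modules: exclusivity,\n"
    "coverage and balance jointly identify them."
)
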