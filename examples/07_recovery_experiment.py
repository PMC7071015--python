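"""End-to-end parameter recovery: can restraints refold a known structure?

Generates a synthetic ground-truth macrocycle, forward-simulates its NOESY
spectrum, calibrates restraints, refolds from ten random starts, clusters
the results, and compares every structure to the truth.  With noise-free
restraints the best structure should land essentially on the ground truth
with every restraint satisfied.  Takes a few minutes at this scale.
"""

from cyclomimic import (AnnealingSchedule, SyntheticNOESYConfig,
                        parse_design, recovery_experiment)

seq = parse_design("HYWSENLFQ", "PG", cyclic=True)
report = recovery_experiment(
    seq,
    noesy_cfg=SyntheticNOESYConfig(seed=101),
    sched=AnnealingSchedule(steps=10000),
    n_structures=10,
    seed=0,
)

print(f"restraints used              : {report.n_restraints}")
print(f"best backbone RMSD to truth  : {report.best_rmsd:.3f} A")
print(f"restraint satisfaction (best): "
      f"{100 * report.fraction_satisfied_best:.1f} %")
print(f"max violation (best)         : {report.max_violation_best:.3f} A")
print(f"cluster sizes                : {report.cluster_sizes}")
print(f"seeds                        : {report.seeds}")
print("\nper-structure ranking vs truth:")
print(report.table.to_string(index=False))

# A best RMSD well under 1 A with 100 % restraint satisfaction means the
# pipeline inverted its own forward model: the distance information in the
# simulated spectrum suffices to determine the macrocycle's fold.
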