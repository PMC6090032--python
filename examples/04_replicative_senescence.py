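"""Replicative senescence of the five fibroblast lines.

Initialises each line at passage 5 from its donor's leukocyte copy number
and methylation index, simulates per-passage loss of hypermethylated
copies to the line's final passage, and prints the endpoint contrasts:
only the two 3M lines lose copies, and their index falls into the 1M band.
"""

from rdnacn import (
    build_default_unit,
    default_retention,
    init_line,
    simulate_passages,
    simulate_study,
)

unit = build_default_unit()
retention = default_retention(unit)

study = simulate_study(unit, retention, seed=0)
print(study.to_string(index=False))

print("\nHSF-66 trajectory (every tenth passage):")
state = init_line("HSF-66", 35, 640.0, 2.2, retention, unit)
traj = simulate_passages(state, unit, retention, seed=1).to_frame()
print(traj[traj.passage % 10 == 5].to_string(index=False))
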