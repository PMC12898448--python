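# Default headgroup+interfacial vs tail partition, keyed by lipid species code.
# Atom names match the pseudo-atoms of the built-in toy membrane generator:
#   P  - phosphate reference atom         GL - glycerol/backbone interfacial atom
#   T1, T2 - acyl/sphingosine tail atoms  O3 - cholesterol hydroxyl
#   R1 - sterol ring carbon
# The table is user-editable; real CHARMM-style topologies should extend the
# lists with their own atom names (unassigned names raise, listing the names).
POPC: {head: [P, GL], tail: [T1, T2]}
SAPI: {head: [P, GL], tail: [T1, T2]}
SAPE: {head: [P, GL], tail: [T1, T2]}
SAPC: {head: [P, GL], tail: [T1, T2]}
OSM:  {head: [P, GL], tail: [T1, T2]}
SLPC: {head: [P, GL], tail: [T1, T2]}
SOPE: {head: [P, GL], tail: [T1, T2]}
CHOL: {head: [O3], tail: [R1, T1]}
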