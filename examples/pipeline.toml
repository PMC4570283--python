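# End-to-end synthetic demonstration config for `isodrift run-all`.
# Simulates genotypes on a known split tree, applies QC, then runs the PBS
# scan, an outgroup f3, divergence dating and the selection simulation.

[run]
stages = ["simulate-genotypes", "qc", "pbs-scan", "f3", "divergence-tree", "wf-sim"]
output_dir = "isodrift_out"
seed = 1

[simulate_genotypes]
n_loci = 5000
n_per_pop = 20

[simulate_genotypes.tree]
root = "root"

[simulate_genotypes.tree.branches]
anc = ["root", 200, 5000]
Isolate = ["anc", 500, 2471]
Neighbor = ["anc", 500, 10000]
EastAsia = ["root", 700, 10000]

[qc]
r2_threshold = 0.4
window = 50
step = 5
pihat_threshold = 0.6

[pbs_scan]
focal = "Isolate"
sister = "Neighbor"
outgroup = "EastAsia"
ne = 2471
percentile = 99

[f3]
mode = "outgroup"
o = "EastAsia"
a = "Isolate"
b = "Neighbor"

[divergence_tree]
ne = 2471
generation_years = 25

[wf_sim]
scenario = "actn3"
n_replicates = 1000
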