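"""Why the subgraph reduction matters: the binary-tree benchmark.

Builds a full directed binary tree with a short cycle through the root, one
target per level (ranked by level), and compares the stepwise procedure with
per-step subgraph reduction against the rank of the full-network walk-count
matrix.  Walk counts grow exponentially with walk length, so on the deeper
trees the raw full-network matrix saturates double precision and its rank
collapses, while the reduced computation keeps every target.
"""
from targetcontrol import full_matrix_rank, make_tree_benchmark, stepwise_target_control

for h in (6, 7, 8, 10):
    bench = make_tree_benchmark(h, seed=1)
    res = stepwise_target_control(bench.network, bench.root, bench.targets)
    baseline = full_matrix_rank(bench.network, bench.root, bench.targets)
    print(
        f"h={h:2d} ({bench.network.n_nodes:5d} nodes): "
        f"stepwise-reduced tau = {res.tau}/{h}, "
        f"full-matrix rank = {baseline}/{h}"
        f"{'  <- baseline deficient' if baseline < h else ''}"
    )

print(
    "\nBy construction every per-level target is controllable from the root;"
    "\ntau < h would be a numerical failure, which only the baseline exhibits."
)
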