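# focs

Significance scoring for individual, already-optimized network communities.

Given an undirected (multi)graph — unipartite or bipartite — and a candidate
community produced by any detection algorithm, `focs` asks how unlikely the
community's internal connectivity would be under a degree-preserving random
graph with no community structure, and returns a score with the usual
p-value interpretation (small = significant).

How it works, in brief:

1. **Community-conditional null.** For a tested node, the edges leaving the
   community and the edges internal to the exterior are broken into stubs
   and the node's stubs are re-assigned uniformly without replacement; its
   community in-degree is then hypergeometric. Members are tested on the
   partition with themselves moved to the exterior.
2. **Exact-uniform discrete p-values.** The discrete CDF is uniformized by
   drawing uniformly on the CDF step containing the observation
   (`corrected_quantile`); under the null the result is exactly
   Uniform[0, 1] (property-tested by simulation).
3. **Worst-node order statistic.** The community's "worst" member (largest
   p-value) is compared against the minimum of `|exterior| + 1` uniforms on
   `[p(second worst), 1]` (`min_order_cdf`).
4. **Iteration.** The worst node is moved to the exterior and the statistic
   recomputed, up to a fraction `rho` (default 0.25) of the original
   members; the minimum over iterations is the final score.

The package also ships seeded synthetic generators (truncated power-law
degrees, configuration-model null graphs, planted-partition graphs with a
mixing parameter) and the two simulation harnesses used to validate the
score: a null false-positive-rate calibration and a detection-power sweep.

## Library quick start

```python
import numpy as np
from focs import Graph, Community, focs_score, load_edge_list

graph = load_edge_list("network.tsv")           # "u v [multiplicity]" lines
community = Community({"a", "b", "c"}, id="c1")
result = focs_score(graph, community, rho=0.25, seed=1)
print(result.score, result.iteration_f, result.removal_order)
```

Bipartite graphs use `load_edge_list(path, bipartite=True)` (column 1 is
side U, column 2 side V) and `BipartiteCommunity(u_members, v_members)`.

## Command line

```sh
# score every community in a membership file (node-id community-id)
focs score network.tsv communities.tsv --seed 1 --output results.tsv

# false-positive calibration on configuration-model null graphs
focs null-calibration --n-networks 200 --seed 1 --output calibration.tsv

# power sweep over the mixing parameter
focs power --mu-grid 0.1,0.5,0.9 --seed 1 --output power.tsv
```

Tables are TSV; logging goes to stderr. Every `--output` table gets a
`<output>.manifest.json` side file with the resolved parameters, seed,
package version and input digests. For a fixed seed the output tables are
byte-identical across runs. Experiment commands also accept
`--config file.json` (or `key=value` lines) mirroring the config
dataclasses in `focs.benchmarks`.

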