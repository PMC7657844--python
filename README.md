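# elastica

Elastic embedding (EE) and its time-series extension (TSEE) for expression
matrices, with a row-partitioned parallel execution path that is provably
consistent with the serial one.

EE maps N high-dimensional samples to low-dimensional coordinates by
minimizing an energy with a quadratic attractive term (preserving local
distances, weighted by perplexity-calibrated entropic affinities) and an
exponential repulsive term (preserving global structure, weighted by squared
distances), traded off by `lambda` (default 10). TSEE adds `beta`-scaled
temporal dissimilarities to the repulsive weights so samples far apart in
experimental time repel more. Optimization uses the spectral-direction
quasi-Newton scheme: the regularized attractive graph Laplacian is factorized
once and reused to precondition every iteration's gradient, with Armijo
backtracking line search.

The parallel path partitions all N×N matrices into contiguous row blocks
(sizes differing by at most 1) owned by P workers; global sums are reduced
from per-row partials gathered in row order, the symmetrization step
exchanges transpose blocks, and coordinates/search directions are
re-assembled by all-gather. Bandwidth calibration bisects on a canonical
dyadic bracket, so each bandwidth is a pure function of its distance row and
warm-start order affects speed only. Together these make the parallel fit
bitwise identical to the serial one for every worker count.

## CLI

```bash
# synthetic data (data CSV + labels/times sidecars)
elastica simulate tree --branches 10 --per-branch 144 --features 60 --seed 0 --output tree.csv
elastica simulate clusters --samples 4423 --clusters 4 --features 50 --output mix.csv
elastica simulate timeseries --stages 39 --per-stage 30 --dt 0.5 --output ts.csv

# single-cell preprocessing: filter -> log-normalize -> variable genes -> PCA
elastica preprocess --input counts.mtx --min-features 200 --min-cells 50 \
    --hvg 2000 --pca 50 --output pcs.csv

# embedding (serial or row-partitioned parallel via --workers)
elastica fit --input pcs.csv --dims 2 --lambda 10 --perplexity 20 \
    --max-iter 200 --tol 1e-6 --mu auto --seed 0 --workers 1 --output emb.csv

# time-series embedding
elastica fit-tsee --input ts.csv --times ts_times.csv --beta 1.0 --output emb.csv

# relative Frobenius error between two embeddings
elastica compare emb_a.csv emb_b.csv
```

Count input is Matrix Market (`.mtx`, genes × cells, with `genes.tsv` /
`barcodes.tsv` sidecars) or dense CSV/TSV (cells × genes). Every fit writes
an embedding CSV (`sample_id, dim_1..dim_d`, 17 significant digits) plus a
JSON run report with the parameters, seed, input hash and energy trace.
`--workers` can also be set through the `ELASTICA_WORKERS` environment
variable.

## Library

```python
import numpy as np
from elastica import EEParams, fit, parallel_fit, relative_error, make_tree
from elastica.preprocess import pca_reduce

Y = pca_reduce(make_tree(seed=1).data, 7).values
params = EEParams(lambda_=10.0, perplexity=20.0, dim=2, seed=1)
serial = fit(Y, params)
dist = parallel_fit(Y, params, P=4)
print(relative_error(serial.coords, dist.coords))  # 0.0
```

Modules: `elastica.affinity` (distances, sigma calibration, weight
normalization), `elastica.optimizer` (energy, gradient, preconditioner,
line search, fit), `elastica.parallel` (partitioning and the worker
dataflow), `elastica.preprocess`, `elastica.synthetic_data`, `elastica.cli`.

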