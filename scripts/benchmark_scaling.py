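"""Qualitative strong-scaling benchmark (not an acceptance surface).

Times the row-partitioned fit for several worker counts on a synthetic tree
dataset and prints the speedup S = T_1 / T_P and parallel efficiency S / P.
The backend simulates the worker dataflow in one process, so wall-clock
speedup here reflects overhead, not real parallel hardware; the numbers are
informational only.

Usage:  python scripts/benchmark_scaling.py --n 720 --workers 1 2 4
"""

from __future__ import annotations

import argparse
import time

from elastica.optimizer import EEParams, fit, relative_error
from elastica.parallel import parallel_fit
from elastica.preprocess import pca_reduce
from elastica.synthetic_data import make_tree


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n", type=int, default=720, help="samples (per-branch x 10)")
    parser.add_argument("--workers", type=int, nargs="+", default=[1, 2, 4])
    parser.add_argument("--max-iter", type=int, default=50)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    per_branch = max(args.n // 10, 2)
    ds = make_tree(10, per_branch, 60, 0.1, seed=args.seed)
    Y = pca_reduce(ds.data, 7).values
    params = EEParams(max_iter=args.max_iter, seed=args.seed)

    t0 = time.perf_counter()
    ref = fit(Y, params)
    t_serial = time.perf_counter() - t0
    print(f"serial: {t_serial:.2f} s ({ref.n_iter} iterations)")

    t1 = None
    for P in args.workers:
        t0 = time.perf_counter()
        emb = parallel_fit(Y, params, P=P)
        tp = time.perf_counter() - t0
        if t1 is None:
            t1 = tp
        err = relative_error(ref.coords, emb.coords)
        print(
            f"P={P}: {tp:.2f} s  speedup {t1 / tp:.2f}  "
            f"efficiency {t1 / (tp * P):.2f}  rel_err {err:.2e}"
        )


if __name__ == "__main__":
    main()
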