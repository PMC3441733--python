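#!/usr/bin/env python
"""Planted-miRNA recovery across repeated simulated experiments.

Repeats the full simulate -> scan -> classify -> enrich pipeline and asks
how often the transfected (planted) miRNA tops the down-regulated
enrichment ranking among decoys, and how often decoys cross adjP < 0.05
when there is no effect at all (mu = 0).
"""

import argparse
from pathlib import Path

import pandas as pd

from mirseed import SimulationConfig, recovery_experiment
from mirseed.io import write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-runs", type=int, default=50)
    ap.add_argument("--n-decoys", type=int, default=50)
    ap.add_argument("--outdir", type=Path, default=Path("results/recovery"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(rng_seed=args.seed)
    summary = recovery_experiment(cfg, n_decoys=args.n_decoys,
                                  n_runs=args.n_runs)
    write_table(summary["runs"], args.outdir / "recovery_runs.tsv")
    print(f"effect mu={cfg.effect_mu}: planted miRNA ranked first in "
          f"{summary['frac_rank1']:.1%} of {args.n_runs} runs "
          f"(rank distribution {summary['rank_distribution']})")
    print(f"decoy false-positive rate at adjP<0.05: "
          f"{summary['decoy_fp_rate']:.4f}")

    null_cfg = SimulationConfig(rng_seed=args.seed + 1, effect_mu=0.0)
    null = recovery_experiment(null_cfg, n_decoys=args.n_decoys,
                               n_runs=max(10, args.n_runs // 2))
    write_table(null["runs"], args.outdir / "null_runs.tsv")
    print(f"null (mu=0) decoy false-positive rate: "
          f"{null['decoy_fp_rate']:.4f}")
    print(f"tables written to {args.outdir}")


if __name__ == "__main__":
    main()
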