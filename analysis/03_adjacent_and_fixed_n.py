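"""Single-step adjacent-cell blocks and fixed-n random-specimen selection.

Evaluates (a) contiguous blocks of 20/40/60/80% of cells against the
bootstrap's random subsets and (b) selection of 200 random specimens per
sample for species richness and the dominant-species share; also runs the
dry-vs-fresh-weight paired t-test over all tubes.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mosqsub import (
    ExperimentConfig,
    evaluate_adjacent,
    evaluate_fixed_n,
    paired_t,
    simulate_samples,
)
from mosqsub import io as mio
from mosqsub._rng import stream


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    config = ExperimentConfig(seed=args.seed)
    samples = simulate_samples(config)
    args.out_dir.mkdir(parents=True, exist_ok=True)

    frames = []
    for method in ("area", "volume", "weight_fresh", "weight_dry"):
        adj = evaluate_adjacent(samples, method=method, fractions=config.fractions)
        adj.insert(0, "method", method)
        frames.append(adj)
    adjacent = pd.concat(frames, ignore_index=True)
    adjacent.to_csv(args.out_dir / "adjacent.csv", index=False)
    a = adjacent[adjacent.method == "area"].set_index("fraction")
    print("adjacent blocks (area method), mean +/- SD consistency of totals:")
    for f in config.fractions:
        print(f"  {int(f * 100):3d}%: {a.loc[f, 'mean_c_total']:6.1f} +/- {a.loc[f, 'sd_c_total']:5.1f}")

    fx_seed = int(stream(args.seed, "fixed_n").integers(0, 2**31))
    fx = evaluate_fixed_n(samples, n=config.fixed_n, seed=fx_seed)
    fx.per_sample.to_csv(args.out_dir / "fixed_n.csv", index=False)
    print(
        f"fixed-n (n={config.fixed_n}): species missed "
        f"{fx.missed_species_mean:.1f}% +/- {fx.missed_species_sd:.1f}%"
    )
    if fx.r_proportion is not None:
        print(
            f"  r(dominant-species share est vs actual) = {fx.r_proportion.estimate:.2f} "
            f"(P = {fx.r_proportion.p_value:.2g})"
        )
    if fx.r_species is not None:
        print(
            f"  r(detected vs actual species count)     = {fx.r_species.estimate:.2f} "
            f"(P = {fx.r_species.p_value:.2g})"
        )

    wet = np.concatenate([s.cell_wet_mg for s in samples])
    dry = np.concatenate([s.cell_dry_mg for s in samples])
    keep = wet > 0
    tt = paired_t(dry[keep], wet[keep])
    loss = 1 - dry[keep] / wet[keep]
    mio.dump_json(
        {
            "t": tt.estimate,
            "df": tt.df,
            "p_value": tt.p_value,
            "mean_loss_fraction": float(loss.mean()),
            "sd_loss_fraction": float(loss.std(ddof=1)),
        },
        args.out_dir / "weight_ttest.json",
    )
    print(
        f"drying: loss {100 * loss.mean():.1f}% +/- {100 * loss.std(ddof=1):.1f}%, "
        f"paired t({tt.df}) = {tt.estimate:.2f}"
    )


if __name__ == "__main__":
    main()
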