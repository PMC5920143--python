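#!/usr/bin/env python
"""Run the prison missing-data grid (small-sample trial) and summarize it.

Two mechanisms (MCAR; dependence-conditioned MAR) x two loss rates (10/30%),
on top of the preset 18% follow-up dropout. With n=50 even MCAR at 30% moves
the change-score statistics; the dependence-conditioned losses additionally
shrink MSe (the long-dependence, heterogeneous responders leave) and distort
the group contrasts.
"""

import argparse
from pathlib import Path

from amputebias.experiment import prison_grid, run_demonstration, write_report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--replications", type=int, default=200)
    ap.add_argument("--out", type=Path, default=Path("results/prison"))
    ap.add_argument("--plots", action="store_true")
    args = ap.parse_args()

    grid = prison_grid(base_seed=args.seed, replications=args.replications)
    res = run_demonstration(grid)
    files = write_report(res, args.out, plots=args.plots)

    mean = res.mean_bias()
    for effect in ("asi_total_chs_post", "asi_cognitive_chs_post"):
        sub = mean[mean.effect == effect]
        print(f"mean bias (%) of the {effect} group effect:")
        print(
            sub.pivot_table(index=["statistic", "mechanism"], columns="loss_rate",
                            values="bias_percent").round(2).to_string()
        )
        print()
    n_fail = len(res.failures())
    if n_fail:
        print(f"note: {n_fail} condition cells infeasible/inestimable (see failures.csv)")
    for p in files:
        print("wrote", p)


if __name__ == "__main__":
    main()
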