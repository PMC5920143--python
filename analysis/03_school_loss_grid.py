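#!/usr/bin/env python
"""Run the school missing-data grid and summarize the bias it induces.

Five mechanisms (MCAR, MAR1a, MAR1b, MAR2a, MAR2b) x four loss rates
(10/20/30/40%) x replicated amputations, tracking MSe, F, partial eta^2 and
the treatment mean difference of the post-score ANOVA and of the simple
treatment effect among 3rd-year pupils in the change-score ANOVA.
"""

import argparse
from pathlib import Path

from amputebias.experiment import run_demonstration, school_grid, write_report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--replications", type=int, default=200)
    ap.add_argument("--out", type=Path, default=Path("results/school"))
    ap.add_argument("--plots", action="store_true")
    args = ap.parse_args()

    grid = school_grid(base_seed=args.seed, replications=args.replications)
    res = run_demonstration(grid)
    files = write_report(res, args.out, plots=args.plots)

    mean = res.mean_bias()
    post = mean[mean.effect == "post_treatment"]
    print("mean bias (%) of the post-score treatment effect, by mechanism and rate:")
    print(
        post.pivot_table(index=["statistic", "mechanism"], columns="loss_rate",
                         values="bias_percent").round(2).to_string()
    )
    print("\nreadings: MCAR leaves MSe/eta2/MD near zero; MAR1b biases them down,")
    print("MAR2b up, monotonically in the loss rate; F falls under every mechanism.")
    n_fail = len(res.failures())
    if n_fail:
        print(f"warning: {n_fail} condition cells failed (see failures.csv)")
    for p in files:
        print("wrote", p)


if __name__ == "__main__":
    main()
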