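"""Robustness curves under intentionality-graded removal, with Weibull fits.

Simulates R50 (fraction of primary extinctions needed to extinguish half
the web, cascades included) across the intentionality grid I = 0..0.95 for
a subset of cohort webs plus the analytic fixtures, 100 replicates per
grid point, then fits the cumulative Weibull to each drop curve.  The
expectation: heterogeneous (scale-free) webs lose more robustness as the
attack becomes targeted, with a sigmoid (c > 1) drop; the complete web is
the analytic control with a flat curve at exactly 0.5.
"""

from pathlib import Path

import pandas as pd

from foodwebtopo import fit_weibull, fixture_webs, robustness_curve
from foodwebtopo.synthetic_data import generate_cohort

SEED = 42
N_REPS = 100
OUT = Path("results/analysis")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(20, 20, seed=SEED)
    subset = cohort[:3] + cohort[20:23]  # 3 scale-free + 3 random
    subset += [fixture_webs()["complete_10"], fixture_webs()["star_10"]]

    curve_rows, wb_rows = [], []
    for web in subset:
        curve = robustness_curve(web, n_reps=N_REPS, seed=SEED)
        params = fit_weibull(curve, seed=SEED)
        for I, mean in zip(curve.I_grid, curve.r50_mean):
            curve_rows.append({"id": web.id, "I": I, "r50_mean": mean})
        wb_rows.append(
            {"id": web.id, "a": params.a, "b": params.b, "c": params.c,
             "rss": params.rss, "converged": params.converged,
             "drop": curve.r50_mean[0] - curve.r50_mean[-1]}
        )
        print(
            f"{web.id}: R50(0)={curve.r50_mean[0]:.3f} "
            f"R50(0.95)={curve.r50_mean[-1]:.3f} "
            f"drop={wb_rows[-1]['drop']:.3f} "
            f"weibull a={params.a:.3f} b={params.b:.2f} c={params.c:.2f}"
        )
    pd.DataFrame(curve_rows).to_csv(OUT / "robustness_curves.csv", index=False)
    pd.DataFrame(wb_rows).to_csv(OUT / "weibull_params.csv", index=False)

    wb = pd.DataFrame(wb_rows)
    sf_drop = wb[wb["id"].str.startswith("sf_")]["drop"].mean()
    rnd_drop = wb[wb["id"].str.startswith("rand_")]["drop"].mean()
    print(f"mean drop: scale-free {sf_drop:.3f} vs random {rnd_drop:.3f}")


if __name__ == "__main__":
    main()
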