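"""Relate topology distance to a disturbance covariate with known slope.

Plants disturbance = 0.1 + 0.5 * D2PG + N(0, 0.1^2), clipped to [0, 1],
on the classified cohort, then runs the raw and binned linear regressions
with bin-count optimisation (largest count whose binned |R| > 0.8) on both
distance targets.  D2PG should come back with a positive slope and D2PL —
anti-correlated with D2PG by construction of the plane — a negative one.

Requires 02_classify_topologies.py to have written classification.csv.
"""

from pathlib import Path

import pandas as pd

from foodwebtopo import generate_disturbance_table, pressure_relation

SEED = 42
OUT = Path("results/analysis")


def main() -> None:
    cls = pd.read_csv(OUT / "classification.csv")
    table = generate_disturbance_table(cls, beta0=0.1, beta1=0.5,
                                       noise_sd=0.1, seed=SEED)
    print(f"clip rate: {table.attrs['clip_rate']:.2%}")

    rows = []
    for target in ("D2PG", "D2PL"):
        rel = pressure_relation(table, target)
        rows.append(
            {"target": target,
             "raw_slope": rel["raw"].slope, "raw_R": rel["raw"].R,
             "binned_slope": rel["binned"].slope, "binned_R": rel["binned"].R,
             "n_bins": rel["n_bins"], "fallback": rel["fallback"],
             "n_webs": rel["raw"].n}
        )
        print(
            f"{target}: raw slope={rel['raw'].slope:+.3f} (R={rel['raw'].R:+.2f})"
            f"  binned slope={rel['binned'].slope:+.3f} "
            f"(R={rel['binned'].R:+.2f}, {rel['n_bins']} bins"
            f"{', fallback' if rel['fallback'] else ''})"
        )
    pd.DataFrame(rows).to_csv(OUT / "regressions.csv", index=False)
    print(f"wrote {OUT / 'regressions.csv'}")


if __name__ == "__main__":
    main()
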