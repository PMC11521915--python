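"""Budget impact of the two upgrade scenarios.

Recomputes every hospital's payout when district hospitals are (a) staffed
and equipped to the IPHS norms — staffing shortfall priced at current
salaries, capital upgrade financed at one-fifth of the existing capital
stock per year, inpatient volume uplifted — or (b) upgraded to medical
colleges with tertiary outpatient coefficients, tertiary case tariffs and
the tertiary per-bed indirect rate. Reports the mean payout uplift of each
scenario over the base case.
"""

import argparse
from pathlib import Path

from hospfin.impact import allocate, national_rollup, payouts_to_frame, percent_change
from hospfin.scenarios import IPHS_BED_UPLIFT_PRESET, ScenarioConfig
from hospfin.synthetic import read_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument(
        "--registry", type=Path, default=Path("results/national_registry.csv")
    )
    ap.add_argument(
        "--scenario",
        choices=["base", "iphs", "medical-college", "all"],
        default="all",
    )
    ap.add_argument(
        "--iphs-bed-uplift",
        type=float,
        default=IPHS_BED_UPLIFT_PRESET,
        help="bed-capacity factor of the IPHS scenario",
    )
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    registry = read_csv(args.registry)
    cfg = ScenarioConfig(iphs_bed_uplift=args.iphs_bed_uplift)
    wanted = (
        ["base", "iphs", "medical-college"] if args.scenario == "all" else [args.scenario]
    )

    means = {}
    for scenario in wanted:
        payouts = [allocate(h, cfg, scenario=scenario) for h in registry]
        summary = national_rollup(payouts)
        means[scenario] = summary.stats.loc["total", "mean"]
        tag = scenario.replace("-", "_")
        payouts_to_frame(payouts).to_csv(
            args.outdir / f"payouts_{tag}.csv", index=False
        )
        summary.stats.to_csv(args.outdir / f"national_summary_{tag}.csv")
        print(
            f"{scenario:<16} mean INR {means[scenario]/1e6:,.0f}M; "
            f"inpatient mean INR {summary.stats.loc['inpatient','mean']/1e6:,.0f}M"
        )

    if "base" in means:
        for scenario in ("iphs", "medical-college"):
            if scenario in means:
                print(
                    f"{scenario} mean payout uplift over base: "
                    f"{percent_change(means['base'], means[scenario]):.1f}%"
                )
    print(f"tables written to {args.outdir}/")


if __name__ == "__main__":
    main()
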