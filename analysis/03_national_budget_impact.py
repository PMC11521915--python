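"""National budget impact under existing care standards.

Allocates the three payment streams — outpatient global budget from the
published risk-adjustment coefficients, case-based inpatient payment, and
the per-bed indirect budget — to every hospital in the national registry,
then rolls up means, ranges, max/min ratios, per-state variation and
component shares.
"""

import argparse
from pathlib import Path

from hospfin.impact import allocate, inr_to_usd, national_rollup, payouts_to_frame
from hospfin.synthetic import read_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument(
        "--registry", type=Path, default=Path("results/national_registry.csv")
    )
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    registry = read_csv(args.registry)
    payouts = [allocate(h) for h in registry]
    states = {h.hospital_id: h.district.state for h in registry}
    summary = national_rollup(payouts, states)

    payouts_to_frame(payouts).to_csv(args.outdir / "payouts_base.csv", index=False)
    summary.stats.to_csv(args.outdir / "national_summary_base.csv")
    summary.by_state.to_csv(args.outdir / "state_summary_base.csv")

    mean_total = summary.stats.loc["total", "mean"]
    lo, hi = summary.stats.loc["total", "min"], summary.stats.loc["total", "max"]
    print(f"hospitals allocated: {summary.n_hospitals}")
    print(
        f"mean annual payout: INR {mean_total/1e6:,.0f} million "
        f"(US$ {inr_to_usd(mean_total)/1e6:,.2f} million)"
    )
    print(
        f"range: INR {lo/1e6:,.0f}M to {hi/1e6:,.0f}M "
        f"({summary.stats.loc['total', 'max_min_ratio']:.1f} times)"
    )
    print(
        "stream shares of total payout: "
        + ", ".join(f"{k} {v:.1f}%" for k, v in summary.shares_pct.items())
    )
    print(f"tables written to {args.outdir}/")


if __name__ == "__main__":
    main()
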