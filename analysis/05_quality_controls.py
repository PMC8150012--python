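#!/usr/bin/env python
"""Positive controls on the simulated cohort.

Checks baseline balance (Cohen's d < 0.3 on BMI, age, gender ratio and
pre-intervention trained ratings), the game-experience global index
balance, the items-liking check against the 50-point scale midpoint, and
expectancy blinding via the phi coefficient of the two 2x2 contingency
tables -- applying the removal procedure when phi exceeds 0.2. Writes
results/qc_report.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from foodict import quality_controls as qc
from foodict import synthetic_cohort as sc


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--mode", choices=["remove", "replace"], default="remove")
    ap.add_argument("--out", type=Path, default=Path("results/qc_report.json"))
    args = ap.parse_args()

    if (args.cohort / "participants.csv").exists():
        tables = sc.read_tables(args.cohort)
    else:
        tables = sc.generate_trial(45, sc.EffectConfig(seed=args.seed))
    participants = tables["participants"]
    report = {}

    pre_scores = (
        tables["ratings"][tables["ratings"]["session"] == "pre"]
        .merge(tables["items"][["id", "category"]], left_on="item_id", right_on="id")
        .groupby(["participant_id", "category"], observed=True)["rating"]
        .mean()
        .reset_index()
    )
    balance = qc.baseline_balance(participants, pre_scores)
    report["baseline_balance"] = balance.to_dict("records")
    print(balance.to_string(index=False))

    geq = qc.geq_scores(tables["geq"]).set_index("participant_id")
    groups = participants.set_index("id")["group"].loc[geq.index]
    d_geq = qc.cohens_d(geq.loc[groups == "experimental", "global"],
                        geq.loc[groups == "control", "global"])
    report["geq"] = {"d_global": d_geq, "balanced": abs(d_geq) < 0.3}
    print(f"GEQ global index: d = {d_geq:.3f} "
          f"({'balanced' if abs(d_geq) < 0.3 else 'needs balancing'})")
    if abs(d_geq) >= 0.3:
        removed = qc.balance_by_exclusion(geq["global"], groups, "balance")
        report["geq"]["removed"] = removed

    liking = pre_scores.groupby("participant_id")["rating"].mean()
    d_lik = qc.one_sample_d(liking, 50.0)
    report["items_liking"] = {"d_vs_midpoint": d_lik, "liked": abs(d_lik) > 0.3}
    print(f"items liking vs midpoint: d = {d_lik:.2f}")

    expectancy = tables["expectancy"].merge(
        participants[["id", "group"]], left_on="participant_id", right_on="id"
    )
    rng = np.random.default_rng([args.seed, 5])
    report["expectancy"] = {}
    for var in ("expected_valuation", "expected_weight_loss"):
        df = expectancy[["participant_id", "group", var]].rename(columns={var: "value"})
        glevels = sorted(df["group"].unique())
        table = [
            [int(((df["group"] == g) & (df["value"] == v)).sum()) for v in (1, 0)]
            for g in glevels
        ]
        phi = qc.phi_coefficient(table)
        stat, p, method = qc.association_test(table)
        entry = {"table": table, "phi": phi, "test": {"stat": stat, "p": p,
                                                      "method": method}}
        print(f"{var}: table {table}, phi = {phi:.3f} ({method} p = {p:.3f})")
        if abs(phi) > qc.PHI_THRESHOLD:
            base = {g: df.loc[df["group"] == g, "value"].mean() for g in glevels}
            actions, final_phi, _ = qc.expectancy_match(
                df, mode=args.mode, rng=rng,
                base_rate=base if args.mode == "replace" else None,
            )
            entry["actions"] = [a.__dict__ for a in actions]
            entry["final_phi"] = final_phi
            print(f"  {len(actions)} {args.mode} actions -> phi = {final_phi:.3f}")
        report["expectancy"][var] = entry

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(report, indent=2, default=str))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
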