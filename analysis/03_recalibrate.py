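"""Recalibrate the five absolute-risk models to the synthetic cohort.

For each model with published absolute risks, compares expected and
observed (Kaplan-Meier) 10-year risk by decile of expected risk, fits the
calibration line, and emits recalibrated risks: decile tables under
results/analysis/recalibration/, plus, for the point-score models, an
updated risk table in the model-spec format with each stratum's risk
replaced by its recalibrated value.
"""

import argparse
import logging
from pathlib import Path

import yaml

import crcvalid as cv
from crcvalid.calibration import calibration_table, recalibrate
from crcvalid.followup import apply_exclusions, build_followup
from crcvalid.registry import evaluate_cohort, load_registry

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path,
                    default=ROOT / "scratch" / "cohort.csv")
    ap.add_argument("--groups", type=int, default=10)
    args = ap.parse_args()
    logging.disable(logging.INFO)

    cohort = cv.read_cohort(args.cohort)
    cohort, _ = apply_exclusions(cohort)
    cohort = cohort.reset_index(drop=True)
    fu = build_followup(cohort, "CRC")
    times = fu["time_years"].to_numpy()
    events = fu["event"].to_numpy()

    outdir = ROOT / "results" / "analysis" / "recalibration"
    outdir.mkdir(parents=True, exist_ok=True)

    for name, spec in sorted(load_registry().items()):
        if not spec.has_absolute_risk:
            continue
        frame = evaluate_cohort(spec, cohort, enforce_sex=False)
        usable = (~frame["excluded"] & frame["risk_10y"].notna()).to_numpy()
        cal = calibration_table(
            name, frame["risk_10y"].to_numpy()[usable],
            times[usable], events[usable], n_groups=args.groups,
        )
        direction = "overestimates" if cal.slope < 1 else "underestimates"
        print(f"{name:<11} slope {cal.slope:6.3f}  intercept "
              f"{cal.intercept:+.5f}  ({direction} risk)")
        tab = cal.table.copy()
        tab.insert(0, "model", name)
        tab.to_csv(outdir / f"recalibration_{name}.csv", index=False,
                   float_format="%.12g")
        if spec.risk_table:
            # recalibrated risk table in the model-spec format
            risks = [s.risk for s in spec.risk_table]
            new_risks, _ = recalibrate(risks, cal.slope, cal.intercept)
            payload = {
                "model": name,
                "recalibrated": True,
                "risk_table": [
                    {"min_points": s.min_points, "max_points": s.max_points,
                     "risk": round(float(r), 6)}
                    for s, r in zip(spec.risk_table, new_risks)
                ],
            }
            with open(outdir / f"risk_table_{name}_recalibrated.yaml",
                      "w") as fh:
                yaml.safe_dump(payload, fh, sort_keys=False)
    print(f"recalibration tables written to {outdir}")


if __name__ == "__main__":
    main()
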