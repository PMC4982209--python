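"""Score EQ-5D-3L questionnaire responses with the UK TTO tariff: survivor
mean utilities at 6 and 12 months (with 95 % CIs) and the Welch comparison
against age-/sex-matched population reference values by age band."""

import argparse
import json
from pathlib import Path

import numpy as np

from icuecon import compare_to_reference, eq5d_utility, mean_wave_utility, read_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    patients, _, quests = read_cohort(args.cohort)
    args.out.mkdir(parents=True, exist_ok=True)

    summary = {}
    for wave in ("6m", "12m"):
        mean, ci, n = mean_wave_utility(quests, wave)
        summary[wave] = {"mean": mean, "ci": list(ci), "n": n}
        print(f"{wave:>3}: mean EQ-5D index {mean:.4f} "
              f"(95 % CI {ci[0]:.4f}-{ci[1]:.4f}), n={n}")

    # survivor utilities by age band vs the reference population
    merged = quests.merge(patients, left_on="patient_id", right_on="id")
    ret = merged[merged["returned"].astype(bool)].copy()
    ret["utility"] = [eq5d_utility(s) for s in ret["eq5d_state"]]
    comparisons = {}
    for wave in ("6m", "12m"):
        sub = ret[ret["wave"] == wave]
        bands = {}
        for band, sel in (("under_65", sub["age"] < 65), ("over_65", sub["age"] >= 65)):
            vals = sub.loc[sel, "utility"]
            if len(vals) >= 2:
                bands[band] = {"mean": vals.mean(), "sd": vals.std(ddof=1), "n": len(vals)}
        table = compare_to_reference(bands)
        comparisons[wave] = table.to_dict("index")
        for band, row in table.iterrows():
            print(f"{wave:>3} {band}: difference vs reference "
                  f"{row['difference']:+.3f} (t={row['t']:.2f}, p={row['p']:.2g})")

    out = args.out / "eq5d_summary.json"
    out.write_text(json.dumps({"wave_utilities": summary,
                               "reference_comparison": comparisons}, indent=2))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
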