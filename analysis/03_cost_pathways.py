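"""Micro-cost every care pathway (initial ICU stay, post-ICU hospital stay,
post-hospital NHS and patient/carer costs) and write per-patient cost
breakdowns plus a pathway summary table."""

import argparse
from pathlib import Path

from icuecon import breakdown_table, load_unit_costs, read_cohort, summarise_costs


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--unit-costs", type=Path, default=None,
                    help="unit-cost YAML (bundled illustrative table by default)")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    patients, crf, quests = read_cohort(args.cohort)
    costs = load_unit_costs(args.unit_costs)
    table = breakdown_table(patients, crf, quests, costs)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "cost_breakdown.csv", index=False)

    icu_days = patients["icu_days"].sum()
    print(f"mean ICU cost          GBP {table['icu_cost'].mean():>9,.0f}"
          f"   (daily {table['icu_cost'].sum() / icu_days:,.0f})")
    print(f"mean post-ICU cost     GBP {table['post_icu_hospital_cost'].mean():>9,.0f}")
    print(f"mean hospital cost     GBP {table['hospital_cost'].mean():>9,.0f}"
          f"   (ICU share {table['icu_cost'].sum() / table['hospital_cost'].sum():.0%})")
    complete = table["total_societal_cost"].notna()
    print(f"post-hospital costs observed for {complete.sum()} of {len(table)} patients "
          "(both questionnaires returned or died within the year); "
          "the remainder are imputed in the next stage")

    rows = summarise_costs(table.merge(patients, left_on="patient_id", right_on="id"),
                           "none", value_col="hospital_cost")
    rows.to_csv(args.out / "hospital_cost_summary.csv", index=False)
    print(f"wrote {args.out / 'cost_breakdown.csv'}")


if __name__ == "__main__":
    main()
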