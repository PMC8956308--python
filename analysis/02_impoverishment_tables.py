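#!/usr/bin/env python
"""Impoverishing effects of OOP health payments: headline and grouped tables.

Reads the simulated survey, computes pre/post-payment poverty metrics at
the national and both international poverty lines, and the grouped
breakdowns (district, region, urban/rural, expenditure quintile).

Writes results/tables/*.csv.
"""

from pathlib import Path

from impovmap import impoverishment, impoverishment_by_group, read_fixture
from impovmap.poverty import STANDARD_LINES, grouped_report_frame

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "tables"


def main() -> None:
    records, _, _ = read_fixture(ROOT.parent / "scratch" / "survey")
    OUT.mkdir(parents=True, exist_ok=True)
    for label, line in STANDARD_LINES.items():
        table = impoverishment(records, line).to_report_frame()
        table.to_csv(OUT / f"impoverishment_{label}.csv", index=False)
        if label == "national":
            print(f"national line ({line.per_year:,.0f} MWK/person/year):")
            print(table.to_string(index=False))
    for grouping in ("district_id", "region", "rural", "quintile"):
        tabs = impoverishment_by_group(
            records, STANDARD_LINES["national"], grouping
        )
        frame = grouped_report_frame(tabs)
        frame.to_csv(OUT / f"impoverishment_national_by_{grouping}.csv", index=False)
    head = grouped_report_frame(
        impoverishment_by_group(records, STANDARD_LINES["national"], "quintile")
    )
    head = head[head["metric"] == "head_count_pct"]
    print("\nhead count by expenditure quintile:")
    print(head.to_string(index=False))


if __name__ == "__main__":
    main()
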