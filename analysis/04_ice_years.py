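"""Classify station-years as high or low ice under both schemes.

Derives breakup dates (first 2-day run below 15% concentration after the
winter maximum), fits each station's at-most-one-change breakup changepoint
to get its DOY threshold, and applies the spring open-water rule (>5
consecutive zero-ice days, Mar 1 - May 1). Writes ice_years.csv.
"""
import logging
from pathlib import Path

from bloomstage.config import RunConfig
from bloomstage.io import read_ice_series, write_table
from bloomstage.pipeline import ice_year_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    table = ice_year_table(read_ice_series(ROOT / "data" / "ice.csv"), RunConfig())
    write_table(table, ROOT / "ice_years.csv")
    no_ice = table[table["no_ice_flag"]]
    print(f"{len(table)} station-years; {len(no_ice)} with no winter ice "
          f"({sorted(set(zip(no_ice['station_id'], no_ice['year'])))})")
    for scheme in ("breakup", "concentration"):
        counts = table[f"class_by_{scheme}"].value_counts().to_dict()
        print(f"by {scheme}: {counts}")
    by_year = table.groupby("year")["class_by_concentration"].apply(
        lambda s: (s == "LOW").mean())
    print("\nfraction of stations LOW (concentration scheme) per year:")
    print(by_year.round(2).to_string())


if __name__ == "__main__":
    main()
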