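"""Packaged reference fixture: per-condition mean NPX values of the printed
secretome table (sections a-d) plus its printed subtraction columns for QC.

The table lists 79 protein entries across four sections; CCL17 is printed in
both the conditioning (b) and inhibited (c) sections with identical means and
is stored once, annotated ``sections="b,c"`` -- hence 78 unique profiles.
Values are stored with dot decimals exactly as printed (two decimals);
classification operates on these rounded means.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .npx import ConditionProfile

#: Printed subtraction columns per section: (minuend, subtrahend) per column.
SECTION_SUBTRACTIONS = {
    "a": [("med", "pbmc"), ("med", "rmsc"), ("med", "coc"), ("med", "d3")],
    "b": [("coc", "med"), ("coc", "pbmc"), ("coc", "rmsc"), ("coc", "d3")],
    "c": [("d3", "med"), ("d3", "pbmc"), ("d3", "rmsc"), ("d3", "coc")],
    "d": [("d3", "med"), ("d3", "pbmc"), ("d3", "rmsc"), ("d3", "coc")],
}

#: Printed section -> intended category label.
SECTION_LABELS = {"a": "consumed", "b": "conditioning", "c": "inhibited",
                  "d": "immunomodulatory"}


def _data_path(name: str):
    return resources.files("mscpotency.data").joinpath(name)


def load_table1_frame() -> pd.DataFrame:
    """The fixture as a DataFrame: protein, sections, med, pbmc, rmsc, coc, d3."""
    with resources.as_file(_data_path("table1_profiles.csv")) as path:
        return pd.read_csv(path)


def load_table1_fixture() -> list[ConditionProfile]:
    """78 unique :class:`ConditionProfile` records, section-annotated."""
    frame = load_table1_frame()
    return [ConditionProfile(protein=row["protein"], med=row["med"],
                             pbmc=row["pbmc"], rmsc=row["rmsc"], coc=row["coc"],
                             d3=row["d3"], sections=row["sections"])
            for _, row in frame.iterrows()]


def load_table1_subtractions() -> pd.DataFrame:
    """The printed subtraction columns: protein, section, sub1..sub4.

    One row per printed listing (79 rows; CCL17 appears for sections b and c).
    """
    with resources.as_file(_data_path("table1_subtractions.csv")) as path:
        return pd.read_csv(path)


def listing_count() -> int:
    """Number of printed listings (79; CCL17 counted in both its sections)."""
    return int(load_table1_frame()["sections"].str.split(",").str.len().sum())


def qc_subtractions(tolerance: float = 0.005) -> pd.DataFrame:
    """Compare printed subtraction columns against subtraction of rounded means.

    Returns one row per printed subtraction cell with the recomputed value and a
    ``discrepant`` flag where |printed - recomputed| > tolerance (default half a
    printed decimal).  Discrepancies are flagged, never corrected: they indicate
    that the printed differences were computed from unrounded inputs.
    """
    means = load_table1_frame().set_index("protein")
    printed = load_table1_subtractions()
    records = []
    for _, row in printed.iterrows():
        spec = SECTION_SUBTRACTIONS[row["section"]]
        for i, (hi, lo) in enumerate(spec, start=1):
            recomputed = round(
                float(means.loc[row["protein"], hi])
                - float(means.loc[row["protein"], lo]), 2)
            value = float(row[f"sub{i}"])
            records.append({
                "protein": row["protein"], "section": row["section"],
                "column": f"{hi}-{lo}", "printed": value,
                "recomputed": recomputed,
                "discrepant": abs(value - recomputed) > tolerance})
    return pd.DataFrame(records)
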