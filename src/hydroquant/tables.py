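"""Bundled cross-tabulations of the published cohort counts.

The package ships the categorical counts of the clinical study cohort
(62 patients with vestibular migraine, Meniere's disease, or both) as a
versioned CSV with a transcription note per cell, so the association
statistics can be recomputed without patient-level data.

Known transcription caveats, kept as printed: the "no EH" row of the
EH-location table sums to 35 while the same row of the EH-laterality
table sums to 34; each table is used as printed without reconciliation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import ContingencyTable, chi_square, fisher_exact_rxc

__all__ = ["available_tables", "load_table", "reproduce_printed_statistics"]

_DATA_PACKAGE = "hydroquant.data"
_DATA_FILE = "printed_tables.csv"

# (table_id, expected printed statistic) for the chi-square reproductions
PRINTED_CHI2 = {
    "eh_presence_all": {"chi2": 29.1, "df": 2, "phi": 0.7},
    "eh_presence_definite": {"chi2": 20.9, "df": 2, "phi": 0.7},
    "headache_all": {"chi2": 32.1, "df": 2, "phi": 0.7},
    "headache_definite": {"chi2": 20.4, "df": 2, "phi": 0.7},
    "tinnitus3_all": {"chi2": 16.3, "df": 4, "phi": 0.5},
}


def _raw() -> pd.DataFrame:
    with resources.files(_DATA_PACKAGE).joinpath(_DATA_FILE).open() as fh:
        return pd.read_csv(fh)


def available_tables() -> list[str]:
    return list(_raw()["table_id"].unique())


def load_table(table_id: str) -> ContingencyTable:
    """A bundled table as a :class:`ContingencyTable`, label order as filed."""
    df = _raw()
    sub = df[df["table_id"] == table_id]
    if sub.empty:
        raise KeyError(f"unknown table {table_id!r}; see available_tables()")
    rows = list(dict.fromkeys(sub["row_label"]))
    cols = list(dict.fromkeys(sub["col_label"]))
    pivot = sub.pivot(index="row_label", columns="col_label", values="count")
    pivot = pivot.loc[rows, cols]
    return ContingencyTable(pivot.to_numpy(), rows, cols)


def reproduce_printed_statistics(fisher_tables: bool = True) -> pd.DataFrame:
    """Recompute every bundled association statistic from the raw counts.

    Returns one row per statistic with the recomputed value; chi-square
    rows also carry the printed value for comparison.
    """
    rows = []
    for table_id, printed in PRINTED_CHI2.items():
        res = chi_square(load_table(table_id))
        rows.append(
            {
                "table_id": table_id,
                "test": "chi_square",
                "statistic": res.statistic,
                "df": res.df,
                "p": res.p,
                "phi": res.phi,
                "printed_statistic": printed["chi2"],
                "printed_phi": printed["phi"],
            }
        )
    if fisher_tables:
        for table_id in ("eh_location_by_deficit", "eh_laterality_by_deficit_side"):
            res = fisher_exact_rxc(load_table(table_id))
            rows.append(
                {
                    "table_id": table_id,
                    "test": "fisher_exact",
                    "statistic": float("nan"),
                    "df": None,
                    "p": res.p,
                    "phi": float("nan"),
                    "printed_statistic": float("nan"),
                    "printed_phi": float("nan"),
                }
            )
    return pd.DataFrame(rows)
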