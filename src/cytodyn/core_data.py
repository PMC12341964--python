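"""Tidy measurement tables, outlier filtering and group medians.

The pipeline's universal input is a long-format table of inflammatory-mediator
concentrations, one row per (subject, condition, tissue, mediator). Solid
tissues are expressed in pg/mg protein, plasma in pg/mL; the unit is implied
by the tissue. Every downstream stage (group statistics, correlation networks,
rate-of-change / hypergraph models) consumes the filtered table produced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns every measurement table must carry.
REQUIRED_COLUMNS = ("subject_id", "condition", "tissue", "mediator", "concentration")

#: Optional column: hours since surgery (0 baseline, 168 day-7 arms, 171 LPS arms).
TIMEPOINT_COLUMN = "timepoint"

#: Experimental arms of the vagotomy study.
CONDITIONS = ("baseline", "sham", "vagotomy", "sham_lps", "vagotomy_lps")

#: Hours since surgery at which each arm is sampled (LPS given at 168 h,
#: sacrifice 3 h later).
CONDITION_TIMEPOINTS = {
    "baseline": 0.0,
    "sham": 168.0,
    "vagotomy": 168.0,
    "sham_lps": 171.0,
    "vagotomy_lps": 171.0,
}

#: Compartments sampled 7 days after surgery; LPS arms add both brain halves.
CORE_COMPARTMENTS = ("heart", "liver", "lung", "kidney", "spleen", "gut", "plasma")
LPS_COMPARTMENTS = CORE_COMPARTMENTS + ("left brain", "right brain")

#: The 20-mediator Luminex panel.
MEDIATOR_PANEL = (
    "GM-CSF", "IFNg", "IL-1a", "IL-1b", "IL-2", "IL-4", "IL-5", "IL-6",
    "IL-10", "IL-12p40", "IL-12p70", "IL-13", "IL-17A", "IP-10", "KC",
    "MCP-1", "MIP-1a", "MIG", "VEGF", "TNF",
)


def units_for_tissue(tissue: str) -> str:
    """Concentration unit implied by the compartment."""
    return "pg/mL" if tissue == "plasma" else "pg/mg"


class SchemaError(ValueError):
    """The input table violates the measurement schema."""


class MissingGroupError(KeyError):
    """A requested (tissue, mediator, condition) group has no records."""


def validate_measurements(df: pd.DataFrame, compartments=None) -> pd.DataFrame:
    """Validate a long-format measurement table and return a clean copy.

    Checks the required columns, non-negative finite concentrations, and
    uniqueness of (subject_id, tissue, mediator) within each condition.
    ``compartments``, if given, restricts the allowed tissue names.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    out = df.copy()
    conc = pd.to_numeric(out["concentration"], errors="coerce")
    bad = ~np.isfinite(conc) | (conc < 0)
    if bad.any():
        rows = out.index[bad].tolist()[:5]
        raise SchemaError(
            f"non-numeric, non-finite or negative concentration at row(s) {rows}"
        )
    out["concentration"] = conc.astype(float)

    if compartments is not None:
        unknown = set(out["tissue"]) - set(compartments)
        if unknown:
            raise SchemaError(f"unknown tissue(s): {sorted(unknown)}")

    dup = out.duplicated(subset=["condition", "subject_id", "tissue", "mediator"])
    if dup.any():
        first = out.loc[dup.idxmax(), ["condition", "subject_id", "tissue", "mediator"]]
        raise SchemaError(
            "duplicate record for (subject_id, tissue, mediator) within a "
            f"condition, first at {tuple(first)}"
        )

    if TIMEPOINT_COLUMN not in out.columns:
        out[TIMEPOINT_COLUMN] = out["condition"].map(CONDITION_TIMEPOINTS)
    return out


def load_measurements(path, compartments=None) -> pd.DataFrame:
    """Read a CSV/TSV measurement table (delimiter from the extension).

    Unknown columns are carried through untouched; the five required columns
    must be present. Raises :class:`SchemaError` on malformed input, naming
    the offending column or row.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    return validate_measurements(df, compartments=compartments)


@dataclass
class OutlierReport:
    """What :func:`remove_outliers` removed, and the cuts it used.

    ``removed`` has the measurement schema; ``group_stats`` has one row per
    (tissue, mediator, condition) group with the mean/SD used for the cut and
    the number of values removed.
    """

    removed: pd.DataFrame
    group_stats: pd.DataFrame
    k_sd: float = 2.0

    def to_json_records(self) -> list[dict]:
        recs = []
        for _, row in self.group_stats.iterrows():
            key = (row["tissue"], row["mediator"], row["condition"])
            sub = self.removed[
                (self.removed["tissue"] == key[0])
                & (self.removed["mediator"] == key[1])
                & (self.removed["condition"] == key[2])
            ]
            recs.append(
                {
                    "group": {"tissue": key[0], "mediator": key[1], "condition": key[2]},
                    "mean": row["mean"],
                    "sd": row["sd"],
                    "removed": [
                        {"subject": r["subject_id"], "value": r["concentration"]}
                        for _, r in sub.iterrows()
                    ],
                }
            )
        return recs


def remove_outliers(
    df: pd.DataFrame, k_sd: float = 2.0
) -> tuple[pd.DataFrame, OutlierReport]:
    """Drop values more than ``k_sd`` sample SDs from their group mean.

    Grouping is per (tissue, mediator, condition). The mean and SD are
    computed once on the original group (single pass; no re-filtering), the
    SD uses the n-1 denominator, and the cut is strict (boundary values are
    kept). Groups with fewer than 3 values pass through unfiltered, as their
    SD is too unstable to support an outlier rule.
    """
    if k_sd <= 0:
        raise ValueError(f"k_sd must be positive, got {k_sd}")

    keys = ["tissue", "mediator", "condition"]
    keep_mask = pd.Series(True, index=df.index)
    stats_rows = []
    for key, idx in df.groupby(keys, sort=False).groups.items():
        vals = df.loc[idx, "concentration"].to_numpy(dtype=float)
        if len(vals) < 3:
            continue
        mean = vals.mean()
        sd = vals.std(ddof=1)
        out = np.abs(vals - mean) > k_sd * sd
        if out.any():
            keep_mask.loc[np.asarray(idx)[out]] = False
        stats_rows.append(
            dict(zip(keys, key)) | {"mean": mean, "sd": sd, "n_removed": int(out.sum())}
        )

    stats = pd.DataFrame(
        stats_rows, columns=keys + ["mean", "sd", "n_removed"]
    )
    filtered = df[keep_mask].copy()
    removed = df[~keep_mask].copy()
    return filtered, OutlierReport(removed=removed, group_stats=stats, k_sd=k_sd)


def median_by_group(
    df: pd.DataFrame, tissue: str, mediator: str, condition: str
) -> float:
    """Sample median concentration of one (tissue, mediator, condition) group.

    Even group sizes take the mean of the central pair. Raises
    :class:`MissingGroupError` naming the triple if the group is empty.
    """
    sub = df[
        (df["tissue"] == tissue)
        & (df["mediator"] == mediator)
        & (df["condition"] == condition)
    ]
    if sub.empty:
        raise MissingGroupError(
            f"no records for tissue={tissue!r}, mediator={mediator!r}, "
            f"condition={condition!r}"
        )
    return float(np.median(sub["concentration"].to_numpy(dtype=float)))
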