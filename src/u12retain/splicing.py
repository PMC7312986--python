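"""PSI quantification and differential-splicing calls.

Events live in a long-format table with one row per event x sample:
``event_id, event_class, gene_id, intron_id, sample, group, inclusion_reads,
exclusion_reads`` where group is WT or MU.  PSI is the plain read ratio
100 * inclusion / (inclusion + exclusion); group PSIs are unweighted means
over samples; dPSI = mean(MU) - mean(WT).  An event is called differential
when it passes the per-sample coverage filter and |dPSI| strictly exceeds
the threshold (default 10 percentage points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_CLASSES",
    "compute_psi",
    "coverage_filter",
    "call_differential",
    "summarize_by_class",
    "read_event_counts",
    "write_calls",
]

EVENT_CLASSES = ("IR", "ES", "3SS", "5SS", "MIC")
GROUPS = ("WT", "MU")

COUNT_COLUMNS = [
    "event_id",
    "event_class",
    "gene_id",
    "intron_id",
    "sample",
    "group",
    "inclusion_reads",
    "exclusion_reads",
]


def compute_psi(inclusion, exclusion):
    """Percent spliced-in: 100*inclusion/(inclusion+exclusion); NaN when 0/0.

    Accepts scalars or arrays; negative counts raise.
    """
    inc = np.asarray(inclusion, dtype=float)
    exc = np.asarray(exclusion, dtype=float)
    if (inc < 0).any() or (exc < 0).any():
        raise ValueError("read counts must be non-negative")
    total = inc + exc
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(total > 0, 100.0 * inc / np.where(total > 0, total, 1.0), np.nan)
    if np.ndim(inclusion) == 0 and np.ndim(exclusion) == 0:
        return float(psi)
    return psi


def coverage_filter(event: pd.DataFrame, min_reads: int) -> bool:
    """True iff inclusion+exclusion >= min_reads in every sample of the event."""
    totals = event["inclusion_reads"] + event["exclusion_reads"]
    return bool((totals >= min_reads).all())


@dataclass
class DiffSpliceCall:
    event_id: str
    event_class: str
    gene_id: str
    intron_id: str | None
    mean_psi_wt: float
    mean_psi_mu: float
    delta_psi: float
    passed_coverage: bool
    call: str  # up_in_MU | down_in_MU | unchanged | low_coverage


def _validate_counts(counts: pd.DataFrame) -> None:
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns and c != "intron_id"]
    if missing:
        raise ValueError(f"counts table missing columns: {missing}")
    groups = set(counts["group"].unique())
    if not groups <= set(GROUPS):
        raise ValueError(f"unknown group labels: {sorted(groups - set(GROUPS))}")
    for g in GROUPS:
        if g not in groups:
            raise ValueError(f"group {g} has zero samples")
    dup = counts.duplicated(subset=["event_id", "sample"])
    if dup.any():
        raise ValueError("duplicate (event_id, sample) rows in counts table")


def call_differential(
    counts: pd.DataFrame,
    threshold_percent: float = 10.0,
    min_reads: int = 10,
) -> pd.DataFrame:
    """Differential-splicing calls for a long-format event-counts table.

    Returns one row per event with per-group mean PSI, dPSI (MU - WT), the
    coverage flag and the call.  Events with any zero-total sample have an
    undefined PSI there and are reported as ``low_coverage`` (no exception).
    """
    counts = counts.copy()
    _validate_counts(counts)
    counts["total"] = counts["inclusion_reads"] + counts["exclusion_reads"]
    counts["psi"] = compute_psi(
        counts["inclusion_reads"].to_numpy(), counts["exclusion_reads"].to_numpy()
    )

    meta_cols = ["event_class", "gene_id"] + (
        ["intron_id"] if "intron_id" in counts.columns else []
    )
    meta = counts.groupby("event_id", sort=True)[meta_cols].first()

    grp = counts.groupby(["event_id", "group"], sort=True)
    mean_psi = grp["psi"].mean().unstack("group")
    min_total = counts.groupby("event_id")["total"].min()
    any_undefined = counts.groupby("event_id")["psi"].apply(lambda s: s.isna().any())

    passed = min_total >= min_reads
    delta = mean_psi["MU"] - mean_psi["WT"]

    call = pd.Series("unchanged", index=meta.index, dtype=object)
    call[delta > threshold_percent] = "up_in_MU"
    call[delta < -threshold_percent] = "down_in_MU"
    low = (~passed) | any_undefined
    call[low] = "low_coverage"

    out = meta.copy()
    if "intron_id" not in out.columns:
        out["intron_id"] = None
    out["mean_psi_wt"] = mean_psi["WT"]
    out["mean_psi_mu"] = mean_psi["MU"]
    out["delta_psi"] = delta
    out["passed_coverage"] = passed & ~any_undefined
    out["call"] = call
    return out.reset_index()


def summarize_by_class(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and within-direction percentages per event class.

    Mirrors the stacked-bar view of differential events split by class and
    direction; percentages within each direction sum to 100 (for a non-empty
    direction).
    """
    rows = []
    for direction in ("up_in_MU", "down_in_MU"):
        sub = calls[calls["call"] == direction]
        total = len(sub)
        for cls in EVENT_CLASSES:
            n = int((sub["event_class"] == cls).sum())
            rows.append(
                {
                    "event_class": cls,
                    "direction": direction,
                    "count": n,
                    "percent": 100.0 * n / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows)


def read_event_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _validate_counts(df)
    return df


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)
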