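"""Per-OTU disturbance characterization: responsiveness, robustness, occurrence.

Read counts are log10(x + 1)-transformed cell-wise, then summed per treatment
across all paired samples: D_j over disturbed columns, I_j over intact ones.
Responsiveness RE = (D_j - I_j)/(D_j + I_j) in [-1, 1]; robustness
RO = 1 - |RE| in [0, 1]. Occurrence counts the paired samples (plants) in
which the OTU was detected in either member of the pair.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import CountTable, DataError, PairedDesign
from .perm_stats import LogFitResult, fit_log_model

__all__ = [
    "log_transform_counts",
    "disturbance_profiles",
    "robustness_occurrence_fit",
]

PROFILE_COLUMNS = [
    "otu_id",
    "occurrence",
    "d_total",
    "i_total",
    "responsiveness",
    "robustness",
]


def log_transform_counts(table: CountTable) -> pd.DataFrame:
    """Cell-wise log10(x + 1); zero counts map to exactly 0."""
    return pd.DataFrame(
        np.log10(table.counts.astype(float) + 1.0),
        index=table.otu_ids,
        columns=table.sample_ids,
    )


def disturbance_profiles(
    table: CountTable,
    design: PairedDesign,
    transform: str = "cellwise",
) -> pd.DataFrame:
    """Profile every OTU detected in at least one paired sample.

    Parameters
    ----------
    transform : {"cellwise", "totals"}
        ``cellwise`` (default) log-transforms each cell before summing across
        samples; ``totals`` applies log10(total + 1) to the per-treatment read
        sums instead (sensitivity variant).

    Returns a frame with columns otu_id, occurrence, d_total, i_total,
    responsiveness, robustness; OTUs absent from every paired sample are
    excluded.
    """
    if not design.pairs:
        raise DataError("empty paired design")
    intact_idx = [table.sample_index(s) for s in design.intact_ids()]
    dist_idx = [table.sample_index(s) for s in design.disturbed_ids()]
    raw = table.counts.astype(float)
    if transform == "cellwise":
        logged = np.log10(raw + 1.0)
        d_tot = logged[:, dist_idx].sum(axis=1)
        i_tot = logged[:, intact_idx].sum(axis=1)
    elif transform == "totals":
        d_tot = np.log10(raw[:, dist_idx].sum(axis=1) + 1.0)
        i_tot = np.log10(raw[:, intact_idx].sum(axis=1) + 1.0)
    else:
        raise DataError(f"unknown transform: {transform!r}")
    present_pair = (raw[:, intact_idx] > 0) | (raw[:, dist_idx] > 0)
    occurrence = present_pair.sum(axis=1)
    keep = (d_tot + i_tot) > 0
    with np.errstate(invalid="ignore"):
        re = np.where(keep, (d_tot - i_tot) / np.where(keep, d_tot + i_tot, 1.0), np.nan)
    ro = 1.0 - np.abs(re)
    rows = np.flatnonzero(keep)
    return pd.DataFrame(
        {
            "otu_id": [table.otu_ids[r] for r in rows],
            "occurrence": occurrence[rows].astype(int),
            "d_total": d_tot[rows],
            "i_total": i_tot[rows],
            "responsiveness": re[rows],
            "robustness": ro[rows],
        },
        columns=PROFILE_COLUMNS,
    )


def robustness_occurrence_fit(profiles: pd.DataFrame) -> LogFitResult:
    """OLS of robustness on ln(occurrence) across OTUs."""
    if len(profiles) < 3:
        raise DataError("need at least 3 profiled OTUs")
    occ = profiles["occurrence"].to_numpy(dtype=float)
    if len(np.unique(occ)) < 3:
        raise DataError("need at least 3 distinct occurrence values")
    return fit_log_model(occ, profiles["robustness"].to_numpy(dtype=float))
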