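"""Protein-level quality filters and replicate merging.

The quantification tables coming out of the search engine still contain
decoy (reverse) hits, contaminants and one-hit wonders.  ``basic_filter``
removes them with an explicit per-reason report so that the filtering funnel
is reconstructable (conservation: every input row is either retained or
reported removed, never silently lost).

``merge_replicates`` then combines the per-replicate tables into one ratio
profile per protein: the detection count across replicates, the arithmetic
mean of the linear +/− catalyst ratios where the control channel gave
evidence, per-replicate log2 ratios for downstream statistics, and the
summed experimental-channel intensity.  A protein seen only in the
(+)-catalyst channel has no finite ratio; it is kept and flagged
``only_in_plus`` (it behaves as infinitely ratioed downstream).  Proteins
quantified only in the control channel have an undefined enrichment and are
removed, with a report entry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: Removal reasons, in the order they are checked (one reason per row).
REASONS = ("reverse", "contaminant", "unique_peptides<2", )

PROFILE_BASE_COLUMNS = [
    "group_id",
    "gene_name",
    "n_detected",
    "mean_ratio",
    "only_in_plus",
    "total_intensity",
]


def basic_filter(
    groups: pd.DataFrame, min_unique_peptides: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove decoy, contaminant and low-evidence protein groups.

    Returns ``(retained, report)`` where ``report`` has columns
    ``group_id`` and ``reason``.  ``len(groups) == len(retained) +
    len(report)`` always holds.
    """
    reason = pd.Series("", index=groups.index, dtype=object)
    rev = groups["is_reverse"].astype(bool)
    con = groups["is_contaminant"].astype(bool) & ~rev
    low = (
        (groups["unique_peptides"] < min_unique_peptides) & ~rev & ~con
    )
    reason[rev] = "reverse"
    reason[con] = "contaminant"
    reason[low] = f"unique_peptides<{min_unique_peptides}"
    removed = reason != ""
    report = pd.DataFrame(
        {
            "group_id": groups.loc[removed, "group_id"],
            "reason": reason[removed],
        }
    ).reset_index(drop=True)
    retained = groups[~removed].reset_index(drop=True)
    return retained, report


def merge_replicates(
    per_replicate: list[pd.DataFrame], min_detections: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge filtered per-replicate tables into per-protein ratio profiles.

    Parameters
    ----------
    per_replicate : list of DataFrame
        One filtered protein-group table per biological replicate
        (generic columns; see :mod:`proxiprof.io`).
    min_detections : int
        Minimum number of replicates a protein must be detected in
        (default 2, i.e. >=2 of 3 for a triplicate design).

    Returns
    -------
    (profiles, report)
        ``profiles`` has :data:`PROFILE_BASE_COLUMNS` plus one
        ``log2_ratio_<i>`` column per replicate; ``report`` lists the
        dropped proteins with reasons (``detections<k`` or
        ``only_in_control``).

    Notes
    -----
    ``mean_ratio`` is the arithmetic mean of the *linear* per-replicate
    ratios over the replicates where the control channel was quantified;
    it is NaN for ``only_in_plus`` proteins, which are conceptually above
    any finite cutoff.  Replicate order does not affect the result beyond
    the naming of the ``log2_ratio_<i>`` columns.
    """
    if not per_replicate:
        raise ConfigurationError("need at least one replicate table")
    n_rep = len(per_replicate)
    if min_detections > n_rep:
        raise ConfigurationError(
            f"min_detections={min_detections} exceeds the number of "
            f"replicates ({n_rep})"
        )

    ids: dict[str, dict] = {}
    for r, frame in enumerate(per_replicate):
        for row in frame.itertuples(index=False):
            entry = ids.setdefault(
                row.group_id,
                {
                    "gene_name": "",
                    "ratios": [np.nan] * n_rep,
                    "detected": [False] * n_rep,
                    "exp_intensity": [np.nan] * n_rep,
                },
            )
            if not entry["gene_name"] and str(row.gene_name).strip():
                entry["gene_name"] = str(row.gene_name).strip()
            entry["detected"][r] = True
            entry["ratios"][r] = row.ratio
            entry["exp_intensity"][r] = row.intensity_experimental

    records, dropped = [], []
    for gid in sorted(ids):
        entry = ids[gid]
        n_det = int(sum(entry["detected"]))
        ratios = np.asarray(entry["ratios"], dtype=float)
        finite = np.isfinite(ratios)
        exp_int = np.asarray(entry["exp_intensity"], dtype=float)
        has_plus = np.nansum(exp_int) > 0 or np.isfinite(ratios).any()
        if n_det < min_detections:
            dropped.append((gid, f"detections<{min_detections}"))
            continue
        if not finite.any() and not has_plus:
            dropped.append((gid, "only_in_control"))
            continue
        only_in_plus = not finite.any()
        rec = {
            "group_id": gid,
            "gene_name": entry["gene_name"],
            "n_detected": n_det,
            "mean_ratio": float(ratios[finite].mean()) if finite.any() else np.nan,
            "only_in_plus": only_in_plus,
            "total_intensity": float(np.nansum(exp_int)),
        }
        for r in range(n_rep):
            rec[f"log2_ratio_{r + 1}"] = (
                float(np.log2(ratios[r])) if finite[r] else np.nan
            )
        records.append(rec)

    columns = PROFILE_BASE_COLUMNS + [
        f"log2_ratio_{r + 1}" for r in range(n_rep)
    ]
    profiles = pd.DataFrame(records, columns=columns)
    report = pd.DataFrame(dropped, columns=["group_id", "reason"])
    return profiles, report
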