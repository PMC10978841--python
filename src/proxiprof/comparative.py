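"""Triplex comparative pipeline: disease vs control vs no-catalyst.

A triplex dimethyl design labels three samples per MS run — condition A
(heavy), condition B (medium) and a no-catalyst control (light) — so every
protein carries three ratios: A/ctrl (H/L), B/ctrl (M/L) and A/B (H/M).
The comparison proceeds through a fixed funnel:

* **Filter 1** — per condition, drop proteins whose vs-control ratio falls
  below a lenient biotinylation cutoff (default 1.2, boundary-inclusive);
  this removes obvious non-enriched background while keeping weakly
  labeled proteins.
* **Filter 2** — keep only proteins biotinylated in *both* conditions, so
  the A/B ratio compares like with like.
* **Replicate intersection** — proteins must survive the funnel in every
  biologically independent experiment (default 3).
* **Differential statistics** — per protein, the mean log2(A/B) across
  experiments and an unpaired two-tailed t-test.  The default compares
  the per-experiment log2(A/ctrl) values against the log2(B/ctrl) values
  with pooled variance (Student); a one-sample test of log2(A/B) against
  zero and Welch's correction are available as options.  Raw p-values are
  reported (with Benjamini–Hochberg adjusted values as an extra column).

``normalize_external`` implements the intensity normalization used when
placing a proteome next to an external reference dataset: per sample,
log2-transform and center on the mean log2 intensity of the present
proteins; proteins missing from a sample are set to 0 on the normalized
scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError
from .io import AnnotationDB

logger = logging.getLogger(__name__)

TRIPLEX_COLUMNS = [
    "group_id",
    "unique_peptides",
    "ratio_heavy_vs_light",
    "ratio_medium_vs_light",
    "ratio_heavy_vs_medium",
    "intensity_heavy",
    "intensity_medium",
]


def check_ratio_consistency(records: pd.DataFrame) -> pd.Series:
    """Flag rows where H/L and (H/M)x(M/L) disagree by more than 2-fold."""
    hl = records["ratio_heavy_vs_light"].to_numpy(dtype=float)
    ml = records["ratio_medium_vs_light"].to_numpy(dtype=float)
    hm = records["ratio_heavy_vs_medium"].to_numpy(dtype=float)
    complete = np.isfinite(hl) & np.isfinite(ml) & np.isfinite(hm)
    disc = np.zeros(len(records), dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = hl / (hm * ml)
    disc[complete] = (fold[complete] > 2.0) | (fold[complete] < 0.5)
    if disc.any():
        logger.warning(
            "%d triplex record(s) with >2-fold ratio inconsistency",
            int(disc.sum()),
        )
    return pd.Series(disc, index=records.index, name="ratio_inconsistent")


def filter_biotinylated(
    records: pd.DataFrame, cutoff: float = 1.2
) -> dict[str, pd.DataFrame]:
    """Filter 1: drop non-biotinylated proteins per condition.

    Condition A keeps ``ratio_heavy_vs_light >= cutoff``; condition B keeps
    ``ratio_medium_vs_light >= cutoff`` (boundary-inclusive).  A protein
    with no vs-control ratio but detected condition intensity is the
    only-in-plus analog and is retained.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    out = {}
    for cond, ratio_col, int_col in (
        ("A", "ratio_heavy_vs_light", "intensity_heavy"),
        ("B", "ratio_medium_vs_light", "intensity_medium"),
    ):
        ratio = records[ratio_col].to_numpy(dtype=float)
        keep = np.isfinite(ratio) & (ratio >= cutoff)
        if int_col in records.columns:
            intensity = records[int_col].to_numpy(dtype=float)
            keep |= ~np.isfinite(ratio) & np.isfinite(intensity) & (intensity > 0)
        out[cond] = records[keep].reset_index(drop=True)
    return out


def intersect_conditions(
    list_a: pd.DataFrame | list, list_b: pd.DataFrame | list
) -> list[str]:
    """Filter 2: proteins biotinylated in both conditions (sorted ids)."""
    ids_a = set(
        list_a["group_id"] if isinstance(list_a, pd.DataFrame) else list_a
    )
    ids_b = set(
        list_b["group_id"] if isinstance(list_b, pd.DataFrame) else list_b
    )
    return sorted(ids_a & ids_b)


def intersect_replicates(per_experiment: list[list[str]]) -> list[str]:
    """Proteins surviving the funnel in every independent experiment."""
    if len(per_experiment) < 2:
        raise ConfigurationError(
            "need at least 2 experiments to intersect replicates"
        )
    final = set(per_experiment[0])
    for ids in per_experiment[1:]:
        final &= set(ids)
    return sorted(final)


def _ttest_rows(
    log2_a: np.ndarray,
    log2_b: np.ndarray,
    test: str,
    welch: bool,
) -> tuple[float, bool]:
    """One protein's p-value; returns (p, flagged_degenerate)."""
    if test == "one-sample":
        diff = log2_a - log2_b
        if np.allclose(diff.var(ddof=0), 0.0):
            return (1.0, False) if np.allclose(diff.mean(), 0.0) else (0.0, True)
        return float(stats.ttest_1samp(diff, 0.0).pvalue), False
    if (
        np.allclose(log2_a.var(ddof=0), 0.0)
        and np.allclose(log2_b.var(ddof=0), 0.0)
    ):
        if np.allclose(log2_a.mean(), log2_b.mean()):
            return 1.0, False
        return 0.0, True
    res = stats.ttest_ind(log2_a, log2_b, equal_var=not welch)
    return float(res.pvalue), False


def differential_stats(
    final_ids: list[str],
    per_experiment: list[pd.DataFrame],
    ann: AnnotationDB | None = None,
    test: str = "two-sample",
    welch: bool = False,
) -> pd.DataFrame:
    """Mean log2 fold change and t-test p-value per retained protein.

    ``per_experiment`` are the raw triplex tables (one per biological
    experiment); each contributes one log2(A/ctrl), log2(B/ctrl) and
    log2(A/B) value per protein.  Proteins with fewer than 2 complete
    experiments are flagged ``insufficient_replicates`` rather than
    silently dropped.  Degenerate zero-variance tests use the p=1
    (equal means) / p->0 (unequal, flagged) convention.
    """
    if test not in ("two-sample", "one-sample"):
        raise ConfigurationError("test must be 'two-sample' or 'one-sample'")
    indexed = [f.set_index("group_id") for f in per_experiment]
    rows = []
    for gid in sorted(final_ids):
        la, lb, lab = [], [], []
        for frame in indexed:
            if gid not in frame.index:
                continue
            rec = frame.loc[gid]
            hl = float(rec["ratio_heavy_vs_light"])
            ml = float(rec["ratio_medium_vs_light"])
            hm = float(rec["ratio_heavy_vs_medium"])
            if np.isfinite(hl) and np.isfinite(ml):
                la.append(np.log2(hl))
                lb.append(np.log2(ml))
            if np.isfinite(hm):
                lab.append(np.log2(hm))
            elif np.isfinite(hl) and np.isfinite(ml):
                lab.append(np.log2(hl) - np.log2(ml))
        row = {"group_id": gid, "n_replicates": len(lab)}
        if len(lab) < 2 or len(la) < 2:
            row.update(
                mean_log2fc=float(np.mean(lab)) if lab else np.nan,
                p_value=np.nan,
                insufficient_replicates=True,
                degenerate=False,
            )
        else:
            p, degenerate = _ttest_rows(
                np.asarray(la), np.asarray(lb), test, welch
            )
            row.update(
                mean_log2fc=float(np.mean(lab)),
                p_value=p,
                insufficient_replicates=False,
                degenerate=degenerate,
            )
        rows.append(row)
    out = pd.DataFrame(
        rows,
        columns=[
            "group_id",
            "n_replicates",
            "mean_log2fc",
            "p_value",
            "insufficient_replicates",
            "degenerate",
        ],
    )
    valid = out["p_value"].notna()
    out["p_adj"] = np.nan
    if valid.any():
        out.loc[valid, "p_adj"] = multipletests(
            out.loc[valid, "p_value"], method="fdr_bh"
        )[1]
    if ann is not None:
        out["is_mito"] = [ann.match(g).is_mito for g in out["group_id"]]
    return out


def normalize_external(
    intensity_table: pd.DataFrame, z_score: bool = False
) -> pd.DataFrame:
    """Center log2 intensities per sample; absent proteins become 0.

    Each column (sample) is log2-transformed over its present (positive,
    non-missing) proteins and centered on their mean; missing entries are
    set to 0 on the normalized scale before any downstream averaging.
    With ``z_score=True`` each column is additionally standardized
    (population sd) for heatmap-style display.
    """
    values = intensity_table.to_numpy(dtype=float)
    if (values[np.isfinite(values)] < 0).any():
        raise ValueError("intensities must be non-negative")
    out = np.zeros_like(values, dtype=float)
    for j in range(values.shape[1]):
        col = values[:, j]
        present = np.isfinite(col) & (col > 0)
        if not present.any():
            raise ValueError(
                f"sample {intensity_table.columns[j]!r} has no present proteins"
            )
        logs = np.log2(col[present])
        out[present, j] = logs - logs.mean()
    if z_score:
        sd = out.std(axis=0)
        sd[sd == 0] = 1.0
        out = (out - out.mean(axis=0)) / sd
    return pd.DataFrame(
        out, index=intensity_table.index, columns=intensity_table.columns
    )


class ExternalIntensityNormalizer(BaseEstimator):
    """Stateless transformer wrapping :func:`normalize_external`."""

    def __init__(self, z_score: bool = False):
        self.z_score = z_score

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return normalize_external(X, z_score=self.z_score)

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.transform(X)


class TriplexDifferential(BaseEstimator):
    """The full comparative funnel as an estimator.

    Parameters
    ----------
    cutoff : float
        Filter-1 biotinylation ratio cutoff (boundary-inclusive).
    test : {"two-sample", "one-sample"}
    welch : bool
        Use Welch's unequal-variance t-test instead of pooled variance.

    Attributes
    ----------
    final_ids_ : list of str      proteome after the whole funnel
    funnel_ : dict                per-stage retention counts
    results_ : DataFrame          differential table (volcano-ready)
    """

    def __init__(
        self,
        cutoff: float = 1.2,
        test: str = "two-sample",
        welch: bool = False,
    ):
        self.cutoff = cutoff
        self.test = test
        self.welch = welch

    def fit(self, X: list[pd.DataFrame], y: AnnotationDB | None = None):
        """Run the funnel on one triplex table per biological experiment."""
        per_exp_ids = []
        funnel = {"input": [], "filter1_A": [], "filter1_B": [], "filter2": []}
        for records in X:
            check_ratio_consistency(records)
            lists = filter_biotinylated(records, cutoff=self.cutoff)
            shared = intersect_conditions(lists["A"], lists["B"])
            per_exp_ids.append(shared)
            funnel["input"].append(int(len(records)))
            funnel["filter1_A"].append(int(len(lists["A"])))
            funnel["filter1_B"].append(int(len(lists["B"])))
            funnel["filter2"].append(int(len(shared)))
        self.final_ids_ = intersect_replicates(per_exp_ids)
        funnel["final"] = int(len(self.final_ids_))
        self.funnel_ = funnel
        self.results_ = differential_stats(
            self.final_ids_, X, ann=y, test=self.test, welch=self.welch
        )
        return self

    def predict(self, X=None) -> pd.DataFrame:
        if not hasattr(self, "results_"):
            raise RuntimeError("fit must be called before predict")
        return self.results_
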