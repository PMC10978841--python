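"""Annotation-guided ratiometric denoising.

The central idea: in a proximity-labeling experiment with a no-catalyst
control, true compartment residents concentrate at high +/− catalyst
ratios while background binders sit near ratio 1.  With a prior
compartment inventory (e.g. MitoCarta3.0 + UniProt for mitochondria) one
can profile the two ratio distributions, quantify their separation by a
ROC sweep over the ratio, and choose the smallest cutoff that delivers a
target specificity — maximizing coverage at a stated purity.  Proteins
detected only in the (+)-catalyst channel are treated as infinitely
ratioed: they rank above every finite ratio and survive any finite cutoff.

Conventions
-----------
* retention is boundary-inclusive: ``mean_ratio >= threshold`` is kept;
* ROC ties (equal ratios) collapse to one curve point; AUC uses
  trapezoidal integration, which gives half credit to ties and therefore
  equals the Mann–Whitney pairwise-concordance statistic;
* specificity is the fraction of the retained list with prior
  compartment annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ConfigurationError
from .io import AnnotationDB


def _annotation_flags(profiles: pd.DataFrame, ann: AnnotationDB) -> pd.Series:
    recs = [
        ann.match(g, n)
        for g, n in zip(profiles["group_id"], profiles["gene_name"])
    ]
    return pd.Series([r.is_mito for r in recs], index=profiles.index)


def _scores(profiles: pd.DataFrame) -> np.ndarray:
    """Ranking score: log2 mean ratio, +inf for only-in-plus proteins."""
    s = np.log2(profiles["mean_ratio"].to_numpy(dtype=float))
    s[profiles["only_in_plus"].to_numpy(dtype=bool)] = np.inf
    return s


@dataclass
class RatioHistogram:
    """Two-class frequency distribution of log2 mean ratios."""

    bin_edges: np.ndarray
    counts_annotated: np.ndarray
    counts_unannotated: np.ndarray
    n_only_in_plus: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count_annotated": self.counts_annotated,
                "count_unannotated": self.counts_unannotated,
            }
        )


@dataclass
class ROCCurve:
    """ROC over ratio thresholds, annotated proteins as the positive class."""

    thresholds: np.ndarray  # descending scores (log2 scale, inf first)
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class CutoffResult:
    threshold: float
    retained: pd.DataFrame
    specificity: float
    abundance_fraction: float
    submito_counts: dict[str, int]
    matrix_coverage: float

    def metrics(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_retained": int(len(self.retained)),
            "specificity": self.specificity,
            "abundance_fraction": self.abundance_fraction,
            "submito_counts": dict(self.submito_counts),
            "matrix_coverage": self.matrix_coverage,
        }


def ratio_distribution(
    profiles: pd.DataFrame, ann: AnnotationDB, n_bins: int = 30
) -> RatioHistogram:
    """Histogram log2 mean ratios by annotation class.

    Only-in-plus proteins carry no finite ratio; they are excluded from
    the bins and reported in ``n_only_in_plus``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    finite = ~profiles["only_in_plus"].astype(bool) & np.isfinite(
        profiles["mean_ratio"].to_numpy(dtype=float)
    )
    sub = profiles[finite]
    if sub.empty:
        raise ValueError("no finite-ratio profiles to histogram")
    values = np.log2(sub["mean_ratio"].to_numpy(dtype=float))
    annotated = _annotation_flags(sub, ann).to_numpy(dtype=bool)
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:  # single point: give the histogram nonzero width
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    counts_ann, _ = np.histogram(values[annotated], bins=edges)
    counts_un, _ = np.histogram(values[~annotated], bins=edges)
    return RatioHistogram(
        edges, counts_ann, counts_un, int((~finite).sum())
    )


def roc_curve(profiles: pd.DataFrame, ann: AnnotationDB) -> ROCCurve:
    """Sweep the ratio threshold and trace TPR/FPR.

    Annotated proteins are positives.  The sweep runs over the distinct
    observed scores in descending order (only-in-plus first); tied scores
    share a single point.  AUC is the trapezoidal area, equal to the
    pairwise concordance probability with half credit for ties.
    """
    labels = _annotation_flags(profiles, ann).to_numpy(dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "ROC undefined: need at least one annotated and one "
            "unannotated profile"
        )
    scores = _scores(profiles)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # distinct-threshold boundaries
    distinct = np.r_[np.flatnonzero(s[1:] != s[:-1]), s.size - 1]
    cum_tp = np.cumsum(y)[distinct]
    cum_fp = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, cum_tp / n_pos]
    fpr = np.r_[0.0, cum_fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    thresholds = np.r_[np.inf, s[distinct]]
    return ROCCurve(thresholds, tpr, fpr, auc)


def _retained_mask(profiles: pd.DataFrame, threshold: float) -> np.ndarray:
    ratio = profiles["mean_ratio"].to_numpy(dtype=float)
    plus = profiles["only_in_plus"].to_numpy(dtype=bool)
    return plus | (np.isfinite(ratio) & (ratio >= threshold))


def specificity_at(
    profiles: pd.DataFrame, ann: AnnotationDB, threshold: float
) -> float:
    """Fraction of the thresholded proteome with prior annotation."""
    mask = _retained_mask(profiles, threshold)
    if not mask.any():
        raise ValueError("specificity undefined: no profile survives the threshold")
    annotated = _annotation_flags(profiles[mask], ann)
    return float(annotated.mean())


def choose_cutoff(
    profiles: pd.DataFrame,
    ann: AnnotationDB,
    target_specificity: float = 0.8,
) -> float | None:
    """Smallest observed-ratio threshold reaching the target specificity.

    The candidate grid is the set of observed finite mean ratios; the
    smallest grid value whose retained set reaches ``target_specificity``
    is returned (maximal coverage at the stated purity).  ``None`` if the
    target is unreachable.
    """
    if not (0 < target_specificity <= 1):
        raise ConfigurationError("target_specificity must be in (0, 1]")
    ratio = profiles["mean_ratio"].to_numpy(dtype=float)
    plus = profiles["only_in_plus"].to_numpy(dtype=bool)
    labels = _annotation_flags(profiles, ann).to_numpy(dtype=bool)
    finite = np.isfinite(ratio) & ~plus
    grid = np.unique(ratio[finite])
    if grid.size == 0:
        return None
    # Descending sweep with cumulative counts; only-in-plus always retained.
    order = np.argsort(-ratio[finite], kind="stable")
    r_sorted = ratio[finite][order]
    ann_sorted = labels[finite][order]
    cum_ann = np.cumsum(ann_sorted)
    cum_tot = np.arange(1, r_sorted.size + 1)
    base_ann = int(labels[plus].sum())
    base_tot = int(plus.sum())
    # For each grid value t (ascending) the retained set is plus + all
    # sorted entries with ratio >= t; the last index with ratio >= t:
    counts_ge = np.searchsorted(-r_sorted, -grid, side="right")
    spec = (base_ann + cum_ann[counts_ge - 1]) / (base_tot + cum_tot[counts_ge - 1])
    ok = np.flatnonzero(spec >= target_specificity)
    if ok.size == 0:
        return None
    return float(grid[ok[0]])


def apply_cutoff(
    profiles: pd.DataFrame, ann: AnnotationDB, threshold: float
) -> CutoffResult:
    """Apply a ratio cutoff and summarize the retained proteome.

    Retained = {mean_ratio >= threshold} ∪ {only_in_plus}.  Summaries:
    specificity, annotated share of summed MS intensity, sub-mitochondrial
    class counts, and coverage of the annotation DB's matrix* inventory.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    mask = _retained_mask(profiles, threshold)
    if not mask.any():
        raise ValueError("specificity undefined: no profile survives the threshold")
    retained = profiles[mask].reset_index(drop=True)
    recs = [
        ann.match(g, n)
        for g, n in zip(retained["group_id"], retained["gene_name"])
    ]
    is_mito = np.array([r.is_mito for r in recs], dtype=bool)
    specificity = float(is_mito.mean())
    intensity = retained["total_intensity"].to_numpy(dtype=float)
    total = float(np.nansum(intensity))
    abundance_fraction = (
        float(np.nansum(intensity[is_mito]) / total) if total > 0 else 0.0
    )
    submito_counts = {
        k: 0 for k in ("matrix_star", "IMS", "MOM", "unassigned", "non_mito")
    }
    for rec in recs:
        key = rec.submito if rec.is_mito else "non_mito"
        submito_counts[key] += 1
    n_matrix_db = ann.n_submito("matrix_star")
    matrix_coverage = (
        submito_counts["matrix_star"] / n_matrix_db if n_matrix_db else 0.0
    )
    retained = retained.assign(is_mito=is_mito)
    return CutoffResult(
        threshold=float(threshold),
        retained=retained,
        specificity=specificity,
        abundance_fraction=abundance_fraction,
        submito_counts=submito_counts,
        matrix_coverage=float(matrix_coverage),
    )


class RatioCutoffSelector(BaseEstimator):
    """Ratiometric cutoff as a scikit-learn style estimator.

    Either fix the ratio ``threshold`` (reproducing a published setting
    such as 5.0) or set ``target_specificity`` and let ``fit`` pick the
    smallest observed ratio reaching it.  ``transform`` filters a profile
    table down to the retained proteome.

    Parameters
    ----------
    threshold : float, optional
        Fixed linear +/− catalyst ratio cutoff (boundary-inclusive).
    target_specificity : float, optional
        Desired fraction of retained proteins with prior annotation.
        Mutually exclusive with ``threshold``; if neither is given,
        0.8 is targeted.

    Attributes
    ----------
    threshold_ : float
        The cutoff in effect after ``fit``.
    result_ : CutoffResult
    roc_ : ROCCurve
    auc_ : float
    """

    def __init__(
        self,
        threshold: float | None = None,
        target_specificity: float | None = None,
    ):
        self.threshold = threshold
        self.target_specificity = target_specificity

    def fit(self, X: pd.DataFrame, y: AnnotationDB):
        """Choose/evaluate the cutoff on profiles ``X`` with annotation ``y``."""
        if self.threshold is not None and self.target_specificity is not None:
            raise ConfigurationError(
                "threshold and target_specificity are mutually exclusive"
            )
        ann = y
        if self.threshold is not None:
            thr = float(self.threshold)
        else:
            target = (
                0.8
                if self.target_specificity is None
                else float(self.target_specificity)
            )
            thr = choose_cutoff(X, ann, target)
            if thr is None:
                raise ConfigurationError(
                    f"target specificity {target} is unreachable on this data"
                )
        self.threshold_ = thr
        self.result_ = apply_cutoff(X, ann, thr)
        self.roc_ = roc_curve(X, ann)
        self.auc_ = self.roc_.auc
        self._ann = ann
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return the retained subset of a profile table."""
        if not hasattr(self, "threshold_"):
            raise RuntimeError("fit must be called before transform")
        return X[_retained_mask(X, self.threshold_)].reset_index(drop=True)

    def fit_transform(self, X: pd.DataFrame, y: AnnotationDB) -> pd.DataFrame:
        return self.fit(X, y).transform(X)
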