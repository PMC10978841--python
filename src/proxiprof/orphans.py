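"""Discovery of "orphan" compartment proteins from ratio signatures.

Proteins repeatedly enriched by the compartment-targeted catalyst share a
quantitative signature across experiments (high log2 +/− catalyst values in
every cell line and replicate).  Stacking these per-replicate log2 ratios
into a protein x column matrix, standardizing each column, and embedding the
matrix in 2D (t-SNE, perplexity 20 by default) places unannotated proteins
that behave like compartment residents inside the annotated cluster.  The
"surrounded by annotated proteins" criterion is made explicit here as a
k-nearest-neighbor vote in the embedding: a candidate must be unannotated,
must lack mitochondria-associated-ER-membrane (MAM) evidence (contact-site
contamination mimics residency), and must have at least ``min_fraction`` of
its k nearest neighbors annotated.

A deterministic PCA embedding is available as an alternative to t-SNE; the
neighborhood scoring is identical either way.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .io import AnnotationDB

logger = logging.getLogger(__name__)


def build_ratio_matrix(
    experiments: list[pd.DataFrame],
    proteins: str = "union",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack per-experiment profile tables into a standardized ratio matrix.

    Parameters
    ----------
    experiments : list of profile DataFrames
        Each as produced by :func:`proxiprof.qc.merge_replicates` (their
        ``log2_ratio_<i>`` columns are used).
    proteins : {"union", "intersection"}
        Row set across experiments.

    Returns
    -------
    (matrix, imputed)
        ``matrix`` is proteins x columns (``exp<e>_r<i>``), z-scored per
        column with the population standard deviation; constant columns
        become all zeros.  Missing entries are imputed with the column
        mean (0 after standardization).  ``imputed`` is a same-shaped
        boolean mask.  Rows missing everywhere are dropped with a warning.
    """
    if not experiments:
        raise ValueError("need at least one experiment")
    blocks = []
    for e, frame in enumerate(experiments, start=1):
        ratio_cols = [c for c in frame.columns if c.startswith("log2_ratio_")]
        block = frame.set_index("group_id")[ratio_cols]
        block.columns = [
            f"exp{e}_r{c.removeprefix('log2_ratio_')}" for c in ratio_cols
        ]
        blocks.append(block)
    if proteins == "union":
        matrix = pd.concat(blocks, axis=1, join="outer")
    elif proteins == "intersection":
        matrix = pd.concat(blocks, axis=1, join="inner")
    else:
        raise ValueError("proteins must be 'union' or 'intersection'")
    all_missing = matrix.isna().all(axis=1)
    if all_missing.any():
        logger.warning(
            "dropping %d protein(s) with no finite ratio in any column",
            int(all_missing.sum()),
        )
        matrix = matrix[~all_missing]
    values = matrix.to_numpy(dtype=float)
    mean = np.nanmean(values, axis=0)
    sd = np.nanstd(values, axis=0)  # population sd
    with np.errstate(invalid="ignore"):
        z = (values - mean) / np.where(sd == 0, 1.0, sd)
    z[:, sd == 0] = 0.0
    imputed = ~np.isfinite(z)
    z[imputed] = 0.0
    out = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    mask = pd.DataFrame(imputed, index=matrix.index, columns=matrix.columns)
    return out.sort_index(), mask.sort_index()


@dataclass
class Embedding2D:
    """2D embedding of a ratio matrix; seed is part of the provenance."""

    coords: pd.DataFrame  # index = proteins, columns = ["x", "y"]
    perplexity: float
    seed: int
    method: str


def embed_2d(
    matrix: pd.DataFrame,
    perplexity: float = 20.0,
    seed: int = 0,
    method: str = "tsne",
) -> Embedding2D:
    """Embed the standardized ratio matrix in two dimensions.

    t-SNE (PCA-initialized, fixed ``random_state``) by default; ``"pca"``
    gives a fully deterministic linear alternative.  A perplexity at or
    above n/3 is reduced with a warning; fewer than 5 proteins is an error.
    """
    n = len(matrix)
    if n < 5:
        raise ValueError("too few points to embed (need >= 5)")
    if method == "tsne":
        eff = perplexity
        if n <= 3 * perplexity:
            eff = max(2.0, (n - 1) / 3.0)
            warnings.warn(
                f"perplexity {perplexity} too large for n={n}; reduced to "
                f"{eff:.1f}",
                stacklevel=2,
            )
        tsne = TSNE(
            n_components=2,
            perplexity=eff,
            random_state=int(seed),
            init="pca",
        )
        coords = tsne.fit_transform(matrix.to_numpy(dtype=float))
        used = eff
    elif method == "pca":
        n_comp = min(2, matrix.shape[1])
        pca = PCA(n_components=n_comp, random_state=int(seed))
        coords = pca.fit_transform(matrix.to_numpy(dtype=float))
        if n_comp == 1:
            coords = np.c_[coords, np.zeros(n)]
        used = float(perplexity)
    else:
        raise ValueError("method must be 'tsne' or 'pca'")
    frame = pd.DataFrame(
        np.asarray(coords, dtype=float), index=matrix.index, columns=["x", "y"]
    )
    return Embedding2D(frame, float(used), int(seed), method)


def mito_neighborhood_score(
    emb: Embedding2D, ann: AnnotationDB, k: int = 10
) -> pd.Series:
    """Fraction of each protein's k nearest embedded neighbors annotated.

    Euclidean distances in the 2D embedding, self excluded; distance ties
    are broken by row (identifier) order for determinism.
    """
    coords = emb.coords.to_numpy(dtype=float)
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of proteins ({n})")
    ids = emb.coords.index
    is_mito = np.array([ann.match(str(i)).is_mito for i in ids], dtype=bool)
    d2 = (
        np.sum(coords**2, axis=1)[:, None]
        + np.sum(coords**2, axis=1)[None, :]
        - 2 * coords @ coords.T
    )
    np.fill_diagonal(d2, np.inf)
    fractions = np.empty(n)
    row_order = np.arange(n)
    for i in range(n):
        nearest = np.lexsort((row_order, d2[i]))[:k]
        fractions[i] = is_mito[nearest].mean()
    return pd.Series(fractions, index=ids, name="mito_neighbor_fraction")


def select_orphans(
    scores: pd.Series, ann: AnnotationDB, min_fraction: float = 0.8
) -> pd.DataFrame:
    """Apply the orphan criteria to neighborhood scores.

    A protein passes iff it is not annotated mitochondrial, carries no MAM
    evidence, and its neighbor fraction reaches ``min_fraction``.  Output
    is sorted by fraction descending (ties by identifier).
    """
    recs = [ann.match(str(i)) for i in scores.index]
    out = pd.DataFrame(
        {
            "protein": [str(i) for i in scores.index],
            "mito_neighbor_fraction": scores.to_numpy(dtype=float),
            "is_mito": [r.is_mito for r in recs],
            "is_mam": [r.is_mam for r in recs],
        }
    )
    out["passes"] = (
        ~out["is_mito"]
        & ~out["is_mam"]
        & (out["mito_neighbor_fraction"] >= min_fraction)
    )
    return out.sort_values(
        ["mito_neighbor_fraction", "protein"],
        ascending=[False, True],
        kind="stable",
    ).reset_index(drop=True)


class OrphanDetector(BaseEstimator):
    """Embedding + kNN-vote orphan discovery as an estimator.

    Parameters
    ----------
    k : int
        Neighborhood size for the annotation vote.
    min_fraction : float
        Minimum annotated-neighbor fraction for candidacy.
    perplexity : float
        t-SNE perplexity.
    seed : int
        Random state of the embedding (recorded in the output).
    method : {"tsne", "pca"}

    Attributes
    ----------
    matrix_ : DataFrame       standardized ratio matrix
    embedding_ : Embedding2D
    scores_ : Series          per-protein annotated-neighbor fraction
    candidates_ : DataFrame   all proteins with the ``passes`` flag
    """

    def __init__(
        self,
        k: int = 10,
        min_fraction: float = 0.8,
        perplexity: float = 20.0,
        seed: int = 0,
        method: str = "tsne",
    ):
        self.k = k
        self.min_fraction = min_fraction
        self.perplexity = perplexity
        self.seed = seed
        self.method = method

    def fit(self, X: list[pd.DataFrame] | pd.DataFrame, y: AnnotationDB):
        """Fit on per-experiment profile tables (or a prebuilt matrix)."""
        if isinstance(X, pd.DataFrame):
            self.matrix_ = X
            self.imputed_ = pd.DataFrame(
                False, index=X.index, columns=X.columns
            )
        else:
            self.matrix_, self.imputed_ = build_ratio_matrix(X)
        self.embedding_ = embed_2d(
            self.matrix_,
            perplexity=self.perplexity,
            seed=self.seed,
            method=self.method,
        )
        self.scores_ = mito_neighborhood_score(self.embedding_, y, k=self.k)
        self.candidates_ = select_orphans(
            self.scores_, y, min_fraction=self.min_fraction
        )
        return self

    def predict(self, X=None) -> pd.DataFrame:
        """Return the passing orphan candidates."""
        if not hasattr(self, "candidates_"):
            raise RuntimeError("fit must be called before predict")
        return self.candidates_[self.candidates_["passes"]].reset_index(
            drop=True
        )
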