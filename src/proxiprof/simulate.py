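"""Synthetic protein-group data with ground truth.

The generator emulates the statistical structure a ratiometric
proximity-labeling experiment produces, so every pipeline stage can be
exercised and validated without raw MS data:

* two protein classes with Gaussian log2 +/− catalyst ratio distributions —
  compartment targets centered well above 0, background near 0;
* a per-protein "true" log2 ratio plus per-replicate quantification noise,
  per-replicate Bernoulli detection dropout;
* a slice of the strongest targets detected only in the (+)-catalyst
  channel (no control evidence, hence no finite ratio);
* decoy (reverse) and contaminant rows plus low-peptide-count rows to
  exercise the QC filters;
* log-normal MS intensity magnitudes;
* an annotation DB covering the target class (with sub-mitochondrial
  labels) and MAM flags on part of the background — optionally hiding a
  fraction of true targets to plant discoverable "orphans";
* triplex designs with a subset of truly regulated proteins for the
  comparative pipeline.

Default parameters are chosen to echo the regime of a well-behaved
cell-line experiment: ~25% of detected proteins are true targets and a
linear ratio cutoff near 5 yields a proteome of roughly 80% specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import PROTEIN_GROUP_COLUMNS, AnnotationDB

__all__ = [
    "SimulationParams",
    "simulate_experiment",
    "simulate_panel",
    "simulate_triplex",
]

_SUBMITO_CLASSES = ("matrix_star", "IMS", "MOM")


@dataclass
class SimulationParams:
    """Generating parameters for synthetic experiments.

    Ratio parameters are on the log2 scale; intensities are log-normal
    with ``intensity_mu``/``intensity_sigma`` also on log2.  The
    ``unique_peptide_law`` is ``("poisson", lam)``; Poisson mass at 0 and
    1 supplies the sub-threshold peptide counts the QC filter removes.
    """

    n_mito: int = 400
    n_background: int = 1200
    mu_mito: float = 3.0
    sigma_mito: float = 1.1
    mu_bg: float = 0.8
    sigma_bg: float = 1.0
    detect_prob: float = 0.9
    n_replicates: int = 3
    frac_only_in_plus: float = 0.05
    frac_decoys: float = 0.05
    intensity_mu: float = 25.0
    intensity_sigma: float = 2.0
    unique_peptide_law: tuple[str, float] = ("poisson", 6.0)
    submito_mix: tuple[float, float, float] = (0.6, 0.2, 0.2)
    mam_frac_background: float = 0.05
    hidden_mito_frac: float = 0.0
    regulated_fraction: float = 0.1
    regulated_log2fc: float = 1.0
    ratio_noise_sigma: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_mito < 0 or self.n_background < 0:
            bad += ["n_mito/n_background"]
        if self.n_mito + self.n_background < 1:
            bad += ["n_mito+n_background"]
        if self.sigma_mito <= 0:
            bad += ["sigma_mito"]
        if self.sigma_bg <= 0:
            bad += ["sigma_bg"]
        if not (0 < self.detect_prob <= 1):
            bad += ["detect_prob"]
        if self.n_replicates < 1:
            bad += ["n_replicates"]
        for name in (
            "frac_only_in_plus",
            "frac_decoys",
            "mam_frac_background",
            "hidden_mito_frac",
            "regulated_fraction",
        ):
            if not (0 <= getattr(self, name) < 1):
                bad += [name]
        if self.intensity_sigma <= 0:
            bad += ["intensity_sigma"]
        if self.ratio_noise_sigma < 0:
            bad += ["ratio_noise_sigma"]
        if self.unique_peptide_law[0] != "poisson" or self.unique_peptide_law[1] <= 0:
            bad += ["unique_peptide_law"]
        if not np.isclose(sum(self.submito_mix), 1.0) or min(self.submito_mix) < 0:
            bad += ["submito_mix"]
        if bad:
            raise ParameterError(bad)

    def with_seed(self, seed: int) -> "SimulationParams":
        return replace(self, seed=int(seed))


def _protein_ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def simulate_experiment(
    params: SimulationParams,
) -> tuple[list[pd.DataFrame], AnnotationDB, pd.DataFrame]:
    """Simulate one ratiometric experiment.

    Returns ``(per_replicate_tables, annotation_db, truth)``.  Each
    replicate table uses the generic protein-group dialect; ``truth``
    has one row per emitted protein (targets + background + decoys) with
    class labels, hidden/MAM flags and the true log2 ratio.  A fixed
    seed yields byte-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_mito, n_bg = params.n_mito, params.n_background
    ids_mito = _protein_ids("MITO", n_mito)
    ids_bg = _protein_ids("BG", n_bg)
    n_decoys = int(round(params.frac_decoys * (n_mito + n_bg)))
    ids_decoy = _protein_ids("DECOY", n_decoys)

    true_log2 = np.concatenate(
        [
            rng.normal(params.mu_mito, params.sigma_mito, n_mito),
            rng.normal(params.mu_bg, params.sigma_bg, n_bg),
            rng.normal(params.mu_bg, params.sigma_bg, n_decoys),
        ]
    )
    ids = ids_mito + ids_bg + ids_decoy
    n_total = len(ids)
    classes = (
        ["mito"] * n_mito + ["background"] * n_bg + ["decoy"] * n_decoys
    )

    # highest-ratio targets lose their control-channel evidence entirely
    n_plus = int(round(params.frac_only_in_plus * n_mito))
    only_plus = np.zeros(n_total, dtype=bool)
    if n_plus:
        top = np.argsort(-true_log2[:n_mito])[:n_plus]
        only_plus[top] = True

    peptides = rng.poisson(params.unique_peptide_law[1], n_total)
    submito = rng.choice(_SUBMITO_CLASSES, size=n_mito, p=params.submito_mix)
    n_hidden = int(round(params.hidden_mito_frac * n_mito))
    hidden = np.zeros(n_total, dtype=bool)
    if n_hidden:
        hidden[rng.choice(n_mito, size=n_hidden, replace=False)] = True
    is_mam = np.zeros(n_total, dtype=bool)
    n_mam = int(round(params.mam_frac_background * n_bg))
    if n_mam:
        is_mam[n_mito + rng.choice(n_bg, size=n_mam, replace=False)] = True

    detected = rng.random((params.n_replicates, n_total)) < params.detect_prob
    noise = rng.normal(
        0.0, params.ratio_noise_sigma, (params.n_replicates, n_total)
    )
    log2_int = rng.normal(
        params.intensity_mu, params.intensity_sigma, (params.n_replicates, n_total)
    )

    tables = []
    for r in range(params.n_replicates):
        keep = detected[r]
        log2_obs = true_log2 + noise[r]
        ratio = np.exp2(log2_obs)
        intensity_exp = np.exp2(log2_int[r])
        intensity_ctrl = intensity_exp / ratio
        frame = pd.DataFrame(
            {
                "group_id": np.asarray(ids, dtype=object)[keep],
                "gene_name": np.asarray(ids, dtype=object)[keep],
                "unique_peptides": peptides[keep],
                "intensity_experimental": intensity_exp[keep],
                "intensity_control": np.where(
                    only_plus, np.nan, intensity_ctrl
                )[keep],
                "ratio": np.where(only_plus, np.nan, ratio)[keep],
                "is_reverse": [
                    c == "decoy" and i % 2 == 0
                    for i, (c, k) in enumerate(zip(classes, keep))
                    if k
                ],
                "is_contaminant": [
                    c == "decoy" and i % 2 == 1
                    for i, (c, k) in enumerate(zip(classes, keep))
                    if k
                ],
            },
            columns=PROTEIN_GROUP_COLUMNS,
        )
        tables.append(frame)

    ann_rows = []
    for i in range(n_mito):
        if hidden[i]:
            continue
        ann_rows.append(
            {
                "identifier": ids[i],
                "is_mito": True,
                "source": "MitoCarta",
                "submito": submito[i],
                "is_mam": False,
            }
        )
    for j in range(n_bg):
        i = n_mito + j
        if is_mam[i]:
            ann_rows.append(
                {
                    "identifier": ids[i],
                    "is_mito": False,
                    "source": "UniProt",
                    "submito": "unassigned",
                    "is_mam": True,
                }
            )
    ann = AnnotationDB(
        pd.DataFrame(
            ann_rows,
            columns=["identifier", "is_mito", "source", "submito", "is_mam"],
        )
    )

    truth = pd.DataFrame(
        {
            "protein": ids,
            "cls": classes,
            "submito": list(submito) + ["unassigned"] * (n_bg + n_decoys),
            "is_mam": is_mam,
            "hidden": hidden,
            "only_in_plus": only_plus,
            "true_log2_ratio": true_log2,
        }
    )
    return tables, ann, truth


def simulate_panel(
    params: SimulationParams, n_experiments: int = 3
) -> tuple[list[list[pd.DataFrame]], AnnotationDB, pd.DataFrame]:
    """Simulate a panel of independent experiments over one protein universe.

    Emulates running the same labeling protocol in several cell lines:
    the protein identities, class labels, annotation DB, hidden-orphan
    set and MAM flags are shared (taken from the first experiment), while
    each experiment redraws the per-protein enrichment from its class
    distribution (a protein's labeling extent differs between cell
    contexts) plus peptide counts, per-replicate noise and detection.
    Returns ``(experiments, ann, truth)`` where
    ``experiments[e]`` is the list of replicate tables of experiment
    ``e`` and ``truth`` carries one ``true_log2_ratio_exp<e>`` column per
    experiment.
    """
    params.validate()
    if n_experiments < 1:
        raise ParameterError(["n_experiments"])
    rng = np.random.default_rng(params.seed)
    base = None
    experiments = []
    truth = None
    for e in range(1, n_experiments + 1):
        child = params.with_seed(int(rng.integers(0, 2**31 - 1)))
        tables, ann_e, truth_e = simulate_experiment(child)
        if base is None:
            base = ann_e
            truth = truth_e.rename(
                columns={"true_log2_ratio": "true_log2_ratio_exp1"}
            )
        else:
            truth[f"true_log2_ratio_exp{e}"] = truth_e["true_log2_ratio"]
        experiments.append(tables)
    return experiments, base, truth


def simulate_triplex(
    params: SimulationParams, n_experiments: int = 3
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Simulate triplex tables for the comparative pipeline.

    Target-class ("biotinylated") proteins carry vs-control enrichment
    drawn from the target ratio distribution; background sits near ratio
    1.  Among the targets, ``regulated_fraction`` are split evenly into
    up- and down-regulated at ±``regulated_log2fc``; per experiment the
    observed log2(A/ctrl) and log2(B/ctrl) get independent Gaussian noise
    and the A/B ratio is their quotient (so the three ratios are
    consistent by construction).  Returns one table per biological
    experiment plus the ground truth.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_mito, n_bg = params.n_mito, params.n_background
    ids = _protein_ids("MITO", n_mito) + _protein_ids("BG", n_bg)
    n_total = len(ids)
    classes = ["mito"] * n_mito + ["background"] * n_bg

    base_log2 = np.concatenate(
        [
            rng.normal(params.mu_mito, params.sigma_mito, n_mito),
            rng.normal(0.0, params.sigma_bg / 4, n_bg),  # background near 1
        ]
    )
    delta = np.zeros(n_total)
    n_reg = int(round(params.regulated_fraction * n_mito))
    reg_idx = rng.choice(n_mito, size=n_reg, replace=False) if n_reg else []
    half = n_reg // 2
    regulation = np.array(["none"] * n_total, dtype=object)
    for pos, i in enumerate(reg_idx):
        if pos < half:
            delta[i] = params.regulated_log2fc
            regulation[i] = "up"
        else:
            delta[i] = -params.regulated_log2fc
            regulation[i] = "down"

    peptides = rng.poisson(params.unique_peptide_law[1], n_total)
    tables = []
    for _ in range(n_experiments):
        keep = rng.random(n_total) < params.detect_prob
        log2_ml = base_log2 + rng.normal(0, params.ratio_noise_sigma, n_total)
        log2_hl = (
            base_log2
            + delta
            + rng.normal(0, params.ratio_noise_sigma, n_total)
        )
        intensity = np.exp2(
            rng.normal(params.intensity_mu, params.intensity_sigma, (2, n_total))
        )
        frame = pd.DataFrame(
            {
                "group_id": np.asarray(ids, dtype=object)[keep],
                "unique_peptides": peptides[keep],
                "ratio_heavy_vs_light": np.exp2(log2_hl)[keep],
                "ratio_medium_vs_light": np.exp2(log2_ml)[keep],
                "ratio_heavy_vs_medium": np.exp2(log2_hl - log2_ml)[keep],
                "intensity_heavy": intensity[0, keep],
                "intensity_medium": intensity[1, keep],
            }
        )
        tables.append(frame)

    truth = pd.DataFrame(
        {
            "protein": ids,
            "cls": classes,
            "regulation": regulation,
            "true_log2fc": delta,
            "base_log2_enrichment": base_log2,
        }
    )
    return tables, truth
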