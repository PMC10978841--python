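"""Shared builders for compact test fixtures."""

from __future__ import annotations

import numpy as np
import pandas as pd

from proxiprof import AnnotationDB


def make_ann(
    mito: dict[str, str] | list[str],
    mam: list[str] = (),
) -> AnnotationDB:
    """AnnotationDB from {id: submito} (or a plain id list) plus MAM ids."""
    if not isinstance(mito, dict):
        mito = {i: "unassigned" for i in mito}
    rows = [
        {
            "identifier": i,
            "is_mito": True,
            "source": "MitoCarta",
            "submito": s,
            "is_mam": False,
        }
        for i, s in mito.items()
    ] + [
        {
            "identifier": i,
            "is_mito": False,
            "source": "UniProt",
            "submito": "unassigned",
            "is_mam": True,
        }
        for i in mam
    ]
    frame = pd.DataFrame(
        rows, columns=["identifier", "is_mito", "source", "submito", "is_mam"]
    )
    return AnnotationDB(frame)


def make_profiles(
    ratios: dict[str, float],
    only_in_plus: list[str] = (),
    intensities: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Minimal ratio-profile table; NaN ratio for only-in-plus proteins."""
    ids = sorted(set(ratios) | set(only_in_plus))
    mean_ratio = [
        np.nan if i in only_in_plus else float(ratios[i]) for i in ids
    ]
    return pd.DataFrame(
        {
            "group_id": ids,
            "gene_name": ["" for _ in ids],
            "n_detected": [3] * len(ids),
            "mean_ratio": mean_ratio,
            "only_in_plus": [i in only_in_plus for i in ids],
            "total_intensity": [
                float((intensities or {}).get(i, 1.0)) for i in ids
            ],
        }
    )


def make_group_table(rows: list[dict]) -> pd.DataFrame:
    """Protein-group table (generic dialect) from sparse row dicts."""
    defaults = {
        "gene_name": "",
        "unique_peptides": 5,
        "intensity_experimental": 100.0,
        "intensity_control": 10.0,
        "ratio": np.nan,
        "is_reverse": False,
        "is_contaminant": False,
    }
    full = [{**defaults, **row} for row in rows]
    columns = ["group_id"] + list(defaults)
    return pd.DataFrame(full, columns=columns)
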