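"""Monoisotopic mass arithmetic for stable-isotope dimethyl labels and
fixed/variable modifications.

Dimethyl labeling converts each peptide primary amine (lysine side chain and
the N-terminus) into a dimethylamine using isotopologues of formaldehyde and
cyanoborohydride.  The three channels differ only in their isotope content,
so their mass shifts follow directly from elemental composition:

* light   — CH2O  + NaBH3CN : net +C2H4 per site
* medium  — CD2O  + NaBH3CN : net +C2D4 per site
* heavy   — 13CD2O + NaBD3CN: net +(13C)2 D6 −H2 per site

An ``ElementalDelta`` is a plain mapping from isotope symbol to a signed
count; masses are sums of count x standard monoisotopic atomic mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

ElementalDelta = Mapping[str, int]

#: Standard monoisotopic atomic masses, Da (12C defines the scale exactly).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "13C": 13.0033548378,
    "H": 1.0078250319,
    "D": 2.0141017781,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}


def monoisotopic_mass(delta: ElementalDelta) -> float:
    """Monoisotopic mass of an elemental delta, in Da.

    Counts may be negative (net atom loss).  Raises ``ValueError`` naming
    the first unsupported symbol.
    """
    total = 0.0
    for symbol, count in delta.items():
        try:
            total += count * MONOISOTOPIC_MASS[symbol]
        except KeyError:
            raise ValueError(
                f"unsupported isotope symbol {symbol!r}; supported: "
                + ", ".join(sorted(MONOISOTOPIC_MASS))
            ) from None
    return total


@dataclass(frozen=True)
class LabelChannel:
    """One dimethyl channel: a name and its per-site elemental delta."""

    name: str
    per_site_delta: Mapping[str, int]

    @property
    def per_site_mass(self) -> float:
        return monoisotopic_mass(self.per_site_delta)


DIMETHYL_CHANNELS: dict[str, LabelChannel] = {
    "light": LabelChannel("light", {"C": 2, "H": 4}),
    "medium": LabelChannel("medium", {"C": 2, "D": 4}),
    "heavy": LabelChannel("heavy", {"13C": 2, "D": 6, "H": -2}),
}

#: Fixed / variable modifications used alongside the labels.
MODIFICATIONS: dict[str, ElementalDelta] = {
    "carbamidomethyl (C)": {"C": 2, "H": 3, "N": 1, "O": 1},
    "oxidation (M)": {"O": 1},
    "acetyl (N-term)": {"C": 2, "H": 2, "O": 1},
}

#: Probe-adduct modification; stored as an opaque constant because its
#: elemental composition is not part of this package's scope.
SF2_QM_IAA_DA: float = 509.2108


def label_shift(channel: LabelChannel | str, n_sites: int = 1) -> float:
    """Total mass shift of ``n_sites`` fully labeled amines, in Da."""
    if isinstance(channel, str):
        try:
            channel = DIMETHYL_CHANNELS[channel]
        except KeyError:
            raise ValueError(
                f"unknown channel {channel!r}; known: "
                + ", ".join(DIMETHYL_CHANNELS)
            ) from None
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    return n_sites * channel.per_site_mass


def _format_delta(delta: ElementalDelta) -> str:
    parts = []
    for symbol in sorted(delta, key=lambda s: (s not in ("C", "13C"), s)):
        count = delta[symbol]
        if count == 0:
            continue
        sign = "-" if count < 0 else ""
        mag = abs(count)
        parts.append(f"{sign}{symbol}{mag if mag != 1 else ''}")
    return " ".join(parts) if parts else "(none)"


def modification_table() -> pd.DataFrame:
    """Table of every label channel and modification with its mass shift."""
    rows = []
    for channel in DIMETHYL_CHANNELS.values():
        rows.append(
            {
                "name": f"dimethyl {channel.name} (per site)",
                "composition": _format_delta(channel.per_site_delta),
                "mass_da": round(channel.per_site_mass, 4),
            }
        )
    for name, delta in MODIFICATIONS.items():
        rows.append(
            {
                "name": name,
                "composition": _format_delta(delta),
                "mass_da": round(monoisotopic_mass(delta), 4),
            }
        )
    rows.append(
        {"name": "SF2-QM-IAA", "composition": "(opaque)", "mass_da": SF2_QM_IAA_DA}
    )
    return pd.DataFrame(rows, columns=["name", "composition", "mass_da"])
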