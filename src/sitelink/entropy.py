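"""Per-column Shannon entropy (natural units) and low-entropy filtering.

Entropy is the plug-in estimate over the residue frequencies of a column,
computed after discarding gaps: ``H = -sum_a p_a ln p_a`` with
``p_a = count_a / n_nongap``.  Values are in nats.  A column is "low entropy"
when its score is at or below the filter threshold; such columns are excluded
from interdependency clustering (they carry almost no pattern information)
but are reported as critically conserved sites.

The threshold scale runs from 0 to 0.25.  For a 105-row alignment a single
deviant residue gives 0.0538 nats and two deviations give 0.0943 (same
residue) or 0.1075 nats (two different residues), so a threshold of 0.1
removes sites that change at most once while 0.11 also removes double-change
sites.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msa_io import GAP, Alignment

__all__ = [
    "ColumnProfile",
    "EntropyFilterResult",
    "AllGapColumnError",
    "column_entropy",
    "entropy_profile",
    "filter_low_entropy",
    "entropy_profile_frame",
]

THRESHOLD_MAX = 0.25


class AllGapColumnError(ValueError):
    """Raised when a column contains no amino-acid characters at all."""


@dataclass
class ColumnProfile:
    """Residue counts and Shannon entropy of one alignment column."""

    position: int
    counts: dict[str, int]
    n_nongap: int
    n_gap: int
    entropy_nats: float

    @property
    def all_gap(self) -> bool:
        return self.n_nongap == 0


@dataclass
class EntropyFilterResult:
    """Partition of column profiles at an entropy threshold.

    ``removed`` holds columns with entropy at or below the threshold
    (inclusive), ``retained`` the rest.  All-gap columns, which have no
    defined entropy, are reported separately in ``excluded`` and never enter
    clustering.
    """

    threshold: float
    removed: list[ColumnProfile]
    retained: list[ColumnProfile]
    excluded: list[ColumnProfile] = field(default_factory=list)

    def removed_positions(self) -> list[int]:
        return [p.position for p in self.removed]

    def retained_positions(self) -> list[int]:
        return [p.position for p in self.retained]


def column_entropy(column) -> float:
    """Shannon entropy (nats) of a residue column, ignoring gaps."""
    residues = [c for c in column if c != GAP]
    if not residues:
        raise AllGapColumnError("column contains only gaps")
    counts = np.array(list(Counter(residues).values()), dtype=float)
    p = counts / counts.sum()
    return max(0.0, float(-(p * np.log(p)).sum()))


def _profile_column(column: np.ndarray, position: int) -> ColumnProfile:
    counter = Counter(str(c) for c in column)
    n_gap = counter.pop(GAP, 0)
    n_nongap = sum(counter.values())
    if n_nongap == 0:
        entropy = float("nan")
    else:
        counts = np.array(list(counter.values()), dtype=float)
        p = counts / n_nongap
        entropy = max(0.0, float(-(p * np.log(p)).sum()))
    return ColumnProfile(
        position=position,
        counts=dict(sorted(counter.items())),
        n_nongap=n_nongap,
        n_gap=n_gap,
        entropy_nats=entropy,
    )


def entropy_profile(aln: Alignment) -> list[ColumnProfile]:
    """One :class:`ColumnProfile` per column, in reference-position order."""
    if aln.n_cols == 0:
        raise ValueError("alignment has no columns to profile")
    positions = aln.positions()
    return [
        _profile_column(aln.residues[:, j], positions[j])
        for j in range(aln.n_cols)
    ]


def filter_low_entropy(
    profiles: list[ColumnProfile], threshold: float
) -> EntropyFilterResult:
    """Partition *profiles* at *threshold* (inclusive removal).

    A profile is removed when ``entropy_nats <= threshold``; the threshold
    must lie on the 0-0.25 scale.  All-gap profiles go to ``excluded``.
    """
    if not 0 <= threshold <= THRESHOLD_MAX:
        raise ValueError(
            f"entropy threshold must be in [0, {THRESHOLD_MAX}], got {threshold}"
        )
    removed: list[ColumnProfile] = []
    retained: list[ColumnProfile] = []
    excluded: list[ColumnProfile] = []
    for prof in profiles:
        if prof.all_gap:
            excluded.append(prof)
        elif prof.entropy_nats <= threshold:
            removed.append(prof)
        else:
            retained.append(prof)
    return EntropyFilterResult(
        threshold=threshold, removed=removed, retained=retained, excluded=excluded
    )


def entropy_profile_frame(
    profiles: list[ColumnProfile],
    aln: Alignment | None = None,
    result: EntropyFilterResult | None = None,
) -> pd.DataFrame:
    """Tabular entropy profile (position, reference residue, entropy, flag).

    Suitable for CSV export and for plotting conservation profiles along the
    reference sequence.
    """
    removed = set()
    if result is not None:
        removed = {p.position for p in result.removed} | {
            p.position for p in result.excluded
        }
    rows = []
    for prof in profiles:
        rows.append(
            {
                "position": prof.position,
                "reference_residue": (
                    aln.reference_residue(prof.position) if aln is not None else ""
                ),
                "entropy_nats": prof.entropy_nats,
                "n_nongap": prof.n_nongap,
                "n_gap": prof.n_gap,
                "removed": prof.position in removed if result is not None else None,
            }
        )
    frame = pd.DataFrame(rows)
    if result is None:
        frame = frame.drop(columns=["removed"])
    return frame
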