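"""Analysis surfaces: annotated low-entropy site tables, logo-ready
frequency matrices, and charge-pattern summaries.

These operate in reference coordinates (1-based positions in the reference
sequence).  Region annotations — domains, nuclear localization sequences,
post-translational-modification sites — are user-supplied configuration, not
hard-coded biology; a default set for human topoisomerase IIα ships with the
package presets.

Unit convention: entropy filtering upstream is in nats, while logo
information content here is in bits (``log2 20 - H2``), matching sequence-logo
convention.  The two scales are never mixed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .entropy import EntropyFilterResult
from .msa_io import GAP, Alignment

__all__ = [
    "RegionAnnotation",
    "FrequencyMatrix",
    "load_regions",
    "write_regions",
    "low_entropy_site_table",
    "frequency_logo_matrix",
    "charge_pattern_summary",
]

POSITIVE_RESIDUES = frozenset("KR")
NEGATIVE_RESIDUES = frozenset("DE")
POLAR_RESIDUES = frozenset("STNQYCH")
MAX_INFO_BITS = float(np.log2(20.0))


@dataclass(frozen=True)
class RegionAnnotation:
    """A named interval on the reference sequence (1-based, inclusive)."""

    name: str
    start: int
    end: int
    notes: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"region {self.name!r}: start {self.start} > end {self.end}"
            )

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def label(self) -> str:
        if self.start == self.end:
            core = f"{self.name} ({self.start})"
        else:
            core = f"{self.name} ({self.start}-{self.end})"
        return f"{core}: {self.notes}" if self.notes else core


def load_regions(path: str | Path) -> list[RegionAnnotation]:
    """Read region annotations from a simple text config.

    Each non-comment line is ``name, start, end[, notes]`` (comma- or
    tab-separated; notes may contain commas).
    """
    regions: list[RegionAnnotation] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        sep = "\t" if "\t" in line else ","
        parts = [p.strip() for p in line.split(sep, 3)]
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected 'name, start, end[, notes]'")
        name, start, end = parts[0], int(parts[1]), int(parts[2])
        notes = parts[3] if len(parts) > 3 else ""
        regions.append(RegionAnnotation(name=name, start=start, end=end, notes=notes))
    return regions


def write_regions(regions: Sequence[RegionAnnotation], path: str | Path) -> None:
    lines = ["# name, start, end, notes"]
    for r in regions:
        lines.append(f"{r.name}, {r.start}, {r.end}, {r.notes}")
    Path(path).write_text("\n".join(lines) + "\n")


def _check_range(aln: Alignment, start: int, end: int) -> None:
    positions = aln.positions()
    lo, hi = positions[0], positions[-1]
    if start > end:
        raise ValueError(f"empty range {start}-{end}")
    if start < lo or end > hi:
        raise ValueError(
            f"range {start}-{end} outside reference coordinates {lo}-{hi}"
        )


def low_entropy_site_table(
    result: EntropyFilterResult,
    aln: Alignment,
    regions: Sequence[RegionAnnotation] = (),
    position_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Removed (low-entropy) sites in a range, annotated by overlapping regions.

    One row per removed column, ascending position, with the reference-row
    residue and the labels of every configured region containing it.  This is
    the "critically conserved sites" report: positions invariant or nearly
    invariant across species, which carry structural/functional weight even
    though they are excluded from clustering.
    """
    if position_range is None:
        positions = aln.positions()
        position_range = (positions[0], positions[-1])
    start, end = position_range
    _check_range(aln, start, end)
    sorted_regions = sorted(regions, key=lambda r: (r.start, r.end, r.name))
    rows = []
    for prof in sorted(result.removed, key=lambda p: p.position):
        if not start <= prof.position <= end:
            continue
        notes = "; ".join(
            r.label() for r in sorted_regions if r.contains(prof.position)
        )
        rows.append(
            {
                "position": prof.position,
                "residue": aln.reference_residue(prof.position),
                "entropy_nats": prof.entropy_nats,
                "notes": notes,
            }
        )
    return pd.DataFrame(rows, columns=["position", "residue", "entropy_nats", "notes"])


@dataclass
class FrequencyMatrix:
    """Per-position residue frequencies and information content (bits)."""

    positions: list[int]
    frequencies: pd.DataFrame  # rows: positions, columns: residues, fractions
    info_bits: np.ndarray
    skipped_positions: list[int]  # all-gap columns inside the range

    def to_frame(self) -> pd.DataFrame:
        frame = self.frequencies.copy()
        frame.insert(0, "position", self.positions)
        frame["info_bits"] = self.info_bits
        return frame


def frequency_logo_matrix(
    aln: Alignment, position_range: tuple[int, int] | None = None
) -> FrequencyMatrix:
    """Logo-ready frequency matrix over a reference-position range.

    Frequencies are fractions of non-gap rows per position; information
    content is ``log2(20) - H2`` with ``H2`` the Shannon entropy in bits of
    those frequencies, so invariant positions score log2(20) ~ 4.32 bits.
    All-gap positions are excluded and listed in ``skipped_positions``.
    """
    all_positions = aln.positions()
    if position_range is None:
        position_range = (all_positions[0], all_positions[-1])
    start, end = position_range
    _check_range(aln, start, end)
    wanted = [p for p in all_positions if start <= p <= end]
    if not wanted:
        raise ValueError(f"no alignment columns inside range {start}-{end}")
    freq_rows, info, kept, skipped = [], [], [], []
    alphabet: set[str] = set()
    counters = {}
    for pos in wanted:
        col = aln.column(pos)
        counter = Counter(str(c) for c in col)
        counter.pop(GAP, None)
        n = sum(counter.values())
        if n == 0:
            skipped.append(pos)
            continue
        counters[pos] = (counter, n)
        alphabet.update(counter)
        kept.append(pos)
    if not kept:
        raise ValueError(f"all columns inside range {start}-{end} are gaps")
    letters = sorted(alphabet)
    for pos in kept:
        counter, n = counters[pos]
        freqs = {a: counter.get(a, 0) / n for a in letters}
        freq_rows.append(freqs)
        p = np.array([v for v in freqs.values() if v > 0.0])
        h2 = float(-(p * np.log2(p)).sum())
        info.append(MAX_INFO_BITS - h2)
    return FrequencyMatrix(
        positions=kept,
        frequencies=pd.DataFrame(freq_rows, columns=letters),
        info_bits=np.array(info),
        skipped_positions=skipped,
    )


def _classify(residue: str, histidine_positive: bool) -> str:
    if residue in POSITIVE_RESIDUES or (histidine_positive and residue == "H"):
        return "positive"
    if residue in NEGATIVE_RESIDUES:
        return "negative"
    if residue in POLAR_RESIDUES:
        return "polar"
    return "other"


def charge_pattern_summary(
    aln: Alignment,
    position_range: tuple[int, int] | None = None,
    histidine_positive: bool = False,
) -> pd.DataFrame:
    """Per-position charge classification with the longest alternating run.

    Each position is classified by its majority non-gap residue as positive
    (K/R, optionally H), negative (D/E), polar, or other.  The report's
    ``in_longest_run`` column marks the maximal run of consecutive positions
    whose classes strictly alternate between positive and negative — the
    charge-zipper pattern characteristic of disordered charged regions.
    Majority ties break to the alphabetically first residue; all-gap
    positions are classified "other".
    """
    all_positions = aln.positions()
    if position_range is None:
        position_range = (all_positions[0], all_positions[-1])
    start, end = position_range
    _check_range(aln, start, end)
    wanted = [p for p in all_positions if start <= p <= end]
    rows = []
    for pos in wanted:
        counter = Counter(str(c) for c in aln.column(pos))
        counter.pop(GAP, None)
        if not counter:
            majority = GAP
            cls = "other"
        else:
            # highest count, ties to alphabetically first residue
            majority = min(counter, key=lambda a: (-counter[a], a))
            cls = _classify(majority, histidine_positive)
        rows.append({"position": pos, "majority_residue": majority, "charge_class": cls})
    frame = pd.DataFrame(rows)

    # longest strictly alternating positive/negative run over consecutive positions
    best = (0, 0)  # (length, start index)
    i = 0
    classes = list(frame["charge_class"])
    positions = list(frame["position"])
    while i < len(classes):
        if classes[i] not in ("positive", "negative"):
            i += 1
            continue
        j = i
        while (
            j + 1 < len(classes)
            and positions[j + 1] == positions[j] + 1
            and classes[j + 1] in ("positive", "negative")
            and classes[j + 1] != classes[j]
        ):
            j += 1
        if j - i + 1 > best[0]:
            best = (j - i + 1, i)
        i = j + 1
    in_run = [False] * len(classes)
    if best[0] >= 2:
        for k in range(best[1], best[1] + best[0]):
            in_run[k] = True
    frame["in_longest_run"] = in_run
    frame.attrs["longest_alternating_run"] = best[0] if best[0] >= 2 else 0
    return frame
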