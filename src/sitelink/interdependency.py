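"""Pairwise normalized mutual information and greedy interdependency clusters.

Two alignment columns are *interdependent* when knowing the residue in one
narrows down the residue in the other across species.  This is quantified by
normalized mutual information (NMI): plug-in mutual information over the joint
residue table of the two columns, restricted to rows where both are non-gap,
normalized by the smaller of the two marginal entropies so that a value of 1
means one column functionally determines the other and 0 means independence.

Clusters of 2 to 10 columns are grown greedily: the best-partner pairs form
the 2nd order, and each k-cluster is the best single-column extension of a
(k-1)-cluster, producing a nested hierarchy.  A cluster's score is its
statistical redundancy mode (SRMode),

    SRMode(C) = (2 / n) * mean of pairwise NMI over the n(n-1)/2 member pairs,

which reduces to NMI for a pair and attains its maximum 2/n (0.667 at order
3, 0.50 at order 4, 0.40 at order 5, 0.20 at order 10) exactly when all
member pairs are fully redundant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .msa_io import GAP, Alignment

__all__ = [
    "NMIMatrix",
    "Cluster",
    "ClusterReport",
    "pairwise_nmi",
    "nmi_pair",
    "srmode",
    "build_clusters",
    "write_cluster_csv",
    "write_cluster_xlsx",
]

#: Pairs whose jointly non-gap row fraction falls below this are scored 0
#: rather than trusting a tiny contingency table.
DEFAULT_MIN_JOINT_FRACTION = 0.5


@dataclass
class NMIMatrix:
    """Symmetric pairwise NMI over a set of retained columns."""

    positions: list[int]
    values: np.ndarray  # (m, m), diagonal 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.positions)
        if self.values.shape != (m, m):
            raise ValueError("values shape does not match positions")
        self._index = {p: i for i, p in enumerate(self.positions)}

    def value(self, pos_a: int, pos_b: int) -> float:
        return float(self.values[self._index[pos_a], self._index[pos_b]])

    def index_of(self, position: int) -> int:
        return self._index[position]


@dataclass
class Cluster:
    """An interdependent set of 2-10 reference positions with its SRMode."""

    members: list[int]
    srmode: float
    parent: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.members = sorted(self.members)

    @property
    def order(self) -> int:
        return len(self.members)

    def key(self) -> tuple[int, ...]:
        return tuple(self.members)


@dataclass
class ClusterReport:
    """Clusters at every order, plus the run configuration that produced them."""

    clusters_by_order: dict[int, list[Cluster]]
    parameters: dict = field(default_factory=dict)

    def top(self, order: int) -> Cluster | None:
        clusters = self.clusters_by_order.get(order, [])
        return clusters[0] if clusters else None

    def column_data(self, aln: Alignment, cluster: Cluster) -> pd.DataFrame:
        """Species x member-position residue table for one cluster."""
        data = {
            pos: [str(c) for c in aln.column(pos)] for pos in cluster.members
        }
        return pd.DataFrame(data, index=aln.row_ids)

    def index_frame(self) -> pd.DataFrame:
        rows = []
        for order in sorted(self.clusters_by_order):
            for rank, cl in enumerate(self.clusters_by_order[order], start=1):
                rows.append(
                    {
                        "order": order,
                        "rank": rank,
                        "members": " ".join(map(str, cl.members)),
                        "srmode": cl.srmode,
                    }
                )
        return pd.DataFrame(rows)


def _encode_columns(aln: Alignment, positions: Sequence[int]) -> list[np.ndarray]:
    """Integer-code each column (gap -> -1, residues -> 0..k-1)."""
    codes = []
    for pos in positions:
        col = aln.column(pos)
        gap = col == GAP
        _, inv = np.unique(col, return_inverse=True)
        coded = inv.astype(np.int64)
        # reindex so residue codes are dense over non-gap symbols only
        if gap.any():
            coded = coded.copy()
            coded[gap] = -1
            nz = coded[~gap]
            uniq = np.unique(nz)
            remap = {u: i for i, u in enumerate(uniq)}
            coded[~gap] = [remap[v] for v in nz]
        codes.append(coded)
    return codes


def _plugin_entropy(counts: np.ndarray) -> float:
    counts = counts[counts > 0].astype(float)
    if counts.size == 0:
        return 0.0
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _nmi_from_codes(
    x: np.ndarray, y: np.ndarray, min_joint: int
) -> float:
    both = (x >= 0) & (y >= 0)
    n = int(both.sum())
    if n < max(min_joint, 2):
        return 0.0
    xs = x[both]
    ys = y[both]
    kx = int(xs.max()) + 1
    ky = int(ys.max()) + 1
    joint = np.bincount(xs * ky + ys, minlength=kx * ky)
    hx = _plugin_entropy(np.bincount(xs, minlength=kx))
    hy = _plugin_entropy(np.bincount(ys, minlength=ky))
    if hx == 0.0 or hy == 0.0:
        return 0.0
    hxy = _plugin_entropy(joint)
    mi = hx + hy - hxy
    nmi = mi / min(hx, hy)
    # plug-in MI can drift a hair outside [0,1] through rounding
    return float(min(max(nmi, 0.0), 1.0))


def nmi_pair(
    col_x, col_y, min_joint_fraction: float = DEFAULT_MIN_JOINT_FRACTION
) -> float:
    """NMI between two raw residue columns (lists/arrays of characters)."""
    x = np.asarray(list(col_x), dtype="<U1")
    y = np.asarray(list(col_y), dtype="<U1")
    if x.shape != y.shape:
        raise ValueError("columns must have equal length")
    aln = Alignment(row_ids=[f"r{i}" for i in range(len(x))],
                    residues=np.stack([x, y], axis=1))
    codes = _encode_columns(aln, [1, 2])
    min_joint = int(np.ceil(min_joint_fraction * len(x)))
    return _nmi_from_codes(codes[0], codes[1], min_joint)


def pairwise_nmi(
    aln: Alignment,
    retained: Sequence[int],
    min_joint_fraction: float = DEFAULT_MIN_JOINT_FRACTION,
    spread: int = 1,
) -> NMIMatrix:
    """Symmetric NMI matrix over *retained* reference positions.

    With ``spread`` > 1 only pairs whose index distance in the retained list
    is a multiple of ``spread`` are evaluated (a speed knob); unevaluated
    entries are 0.  ``spread=1`` compares every column with every other.
    """
    retained = list(retained)
    if len(retained) < 2:
        raise ValueError("need at least two retained columns")
    if spread < 1:
        raise ValueError("spread must be >= 1")
    codes = _encode_columns(aln, retained)
    m = len(retained)
    min_joint = int(np.ceil(min_joint_fraction * aln.n_rows))
    values = np.zeros((m, m), dtype=float)
    np.fill_diagonal(values, 1.0)
    for i in range(m):
        for j in range(i + 1, m):
            if (j - i) % spread != 0:
                continue
            v = _nmi_from_codes(codes[i], codes[j], min_joint)
            values[i, j] = values[j, i] = v
    return NMIMatrix(positions=retained, values=values)


def srmode(
    aln: Alignment,
    members: Sequence[int],
    nmi: NMIMatrix | None = None,
    min_joint_fraction: float = DEFAULT_MIN_JOINT_FRACTION,
) -> float:
    """SRMode of a candidate cluster: ``(2/n) * mean pairwise NMI``."""
    members = list(members)
    n = len(members)
    if not 2 <= n <= 10:
        raise ValueError(f"cluster order must be between 2 and 10, got {n}")
    if len(set(members)) != n:
        raise ValueError("duplicate cluster members")
    if nmi is None:
        nmi = pairwise_nmi(aln, members, min_joint_fraction=min_joint_fraction)
    total = 0.0
    for a, b in itertools.combinations(members, 2):
        total += nmi.value(a, b)
    mean = total / (n * (n - 1) / 2)
    return (2.0 / n) * mean


def _rank_clusters(clusters: list[Cluster]) -> list[Cluster]:
    # descending score; ties broken by ascending member tuple for determinism
    return sorted(clusters, key=lambda c: (-c.srmode, c.key()))


def build_clusters(
    aln: Alignment,
    retained: Sequence[int],
    spread: int = 1,
    max_order: int = 10,
    min_joint_fraction: float = DEFAULT_MIN_JOINT_FRACTION,
    allow_overlap: bool = True,
    nmi: NMIMatrix | None = None,
) -> ClusterReport:
    """Greedy agglomerative construction of order-2..``max_order`` clusters.

    Order 2: every column's best partner forms a candidate pair;
    deduplicated pairs are ranked by NMI.  Order k > 2: each (k-1)-cluster is
    extended by the single retained column that maximizes the resulting
    SRMode, so every k-cluster contains its parent (k-1)-cluster.  Ties are
    broken toward the lowest position number, making the report deterministic.

    With ``allow_overlap=False`` a column joins at most one cluster per
    order (assigned greedily in rank order).
    """
    retained = list(retained)
    if len(retained) < 2:
        raise ValueError("need at least two retained columns to cluster")
    if not 2 <= max_order <= 10:
        raise ValueError(f"max_order must be between 2 and 10, got {max_order}")
    if nmi is None:
        nmi = pairwise_nmi(
            aln, retained, min_joint_fraction=min_joint_fraction, spread=spread
        )
    m = len(retained)
    values = nmi.values
    off_diag = values.copy()
    np.fill_diagonal(off_diag, -np.inf)  # exclude self-pairing

    # --- order 2: best partner per column, deduplicated ------------------
    pairs: dict[tuple[int, int], Cluster] = {}
    for i in range(m):
        j = int(np.argmax(off_diag[i]))  # argmax takes lowest index on ties
        key = tuple(sorted((retained[i], retained[j])))
        if key not in pairs:
            pairs[key] = Cluster(members=list(key), srmode=float(values[i, j]))
    by_order: dict[int, list[Cluster]] = {2: _rank_clusters(list(pairs.values()))}

    # --- orders 3..max_order: best single-column extension ----------------
    pos_index = {p: i for i, p in enumerate(retained)}
    for order in range(3, max_order + 1):
        parents = by_order.get(order - 1, [])
        if not parents:
            break
        seen: dict[tuple[int, ...], Cluster] = {}
        for parent in parents:
            member_idx = [pos_index[p] for p in parent.members]
            candidates = np.ones(m, dtype=bool)
            candidates[member_idx] = False
            if not candidates.any():
                continue
            k = order
            n_pairs = k * (k - 1) / 2
            # sum of NMI over the parent's own pairs
            psum = 0.0
            for a, b in itertools.combinations(member_idx, 2):
                psum += values[a, b]
            # candidate score vector: parent pairs + links to the candidate
            link = values[member_idx, :].sum(axis=0)
            score = (2.0 / k) * (psum + link) / n_pairs
            score[~candidates] = -np.inf
            best = int(np.argmax(score))  # lowest index wins ties
            members = sorted(parent.members + [retained[best]])
            key = tuple(members)
            if key not in seen:
                seen[key] = Cluster(
                    members=members,
                    srmode=float(score[best]),
                    parent=parent.key(),
                )
        clusters = _rank_clusters(list(seen.values()))
        if not allow_overlap:
            used: set[int] = set()
            kept = []
            for cl in clusters:
                if used.isdisjoint(cl.members):
                    kept.append(cl)
                    used.update(cl.members)
            clusters = kept
        by_order[order] = clusters

    params = {
        "spread": spread,
        "max_order": max_order,
        "min_joint_fraction": min_joint_fraction,
        "allow_overlap": allow_overlap,
        "n_retained": len(retained),
    }
    return ClusterReport(clusters_by_order=by_order, parameters=params)


def write_cluster_csv(
    report: ClusterReport, aln: Alignment, out_dir: str | Path
) -> list[Path]:
    """One CSV per order (cluster blocks) plus an index CSV; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    index_path = out_dir / "clusters_index.csv"
    report.index_frame().to_csv(index_path, index=False)
    written.append(index_path)
    for order in sorted(report.clusters_by_order):
        path = out_dir / f"clusters_order{order}.csv"
        with open(path, "w") as fh:
            for rank, cl in enumerate(report.clusters_by_order[order], start=1):
                fh.write(
                    f"# cluster {rank} order {order} "
                    f"srmode {cl.srmode:.6f} members "
                    f"{' '.join(map(str, cl.members))}\n"
                )
                report.column_data(aln, cl).to_csv(fh)
        written.append(path)
    return written


def write_cluster_xlsx(
    report: ClusterReport, aln: Alignment, path: str | Path
) -> Path:
    """Workbook with an index sheet and one sheet of column data per order."""
    path = Path(path)
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        report.index_frame().to_excel(writer, sheet_name="index", index=False)
        for order in sorted(report.clusters_by_order):
            sheet = f"order{order}"
            row = 0
            for rank, cl in enumerate(report.clusters_by_order[order], start=1):
                head = pd.DataFrame(
                    {
                        "cluster": [rank],
                        "srmode": [cl.srmode],
                        "members": [" ".join(map(str, cl.members))],
                    }
                )
                head.to_excel(writer, sheet_name=sheet, startrow=row, index=False)
                row += 2
                block = report.column_data(aln, cl)
                block.to_excel(writer, sheet_name=sheet, startrow=row)
                row += len(block) + 2
    return path
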