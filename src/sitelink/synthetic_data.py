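"""Synthetic alignment generator with planted, known interdependency structure.

The generator emulates the column types seen in real protein family
alignments:

* *invariant* columns — one residue across all species;
* *near-invariant* columns — one residue with exactly 1 or 2 deviant rows
  (the sites an entropy filter at 0.1-0.11 nats is designed to remove);
* *planted coupled groups* — sets of columns driven by a shared latent state
  per species, so their pairwise NMI is 1 at zero noise and decays as the
  per-cell flip probability ``noise`` grows;
* *background* columns — i.i.d. draws from a 6-letter sub-alphabet,
  mimicking variable surface positions with no interdependency;
* gap structure — per-cell gaps at ``gap_rate`` everywhere except the
  reference row, which is kept gap-free so that first-row mapping is the
  identity and planted indices coincide with reported positions.

Latent states are drawn independently per species: like the clustering
method itself, the generator does not model phylogenetic correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .msa_io import GAP, Alignment

__all__ = ["PlantedGroup", "SyntheticSpec", "SyntheticTruth", "generate_msa",
           "write_truth", "read_truth"]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
BACKGROUND_ALPHABET = np.array(list("AEGKLS"))  # 6-letter variable background


@dataclass(frozen=True)
class PlantedGroup:
    """Columns coupled through a shared per-species latent state."""

    columns: tuple[int, ...]  # 1-based positions
    n_latent_states: int = 4
    noise: float = 0.0  # per-cell flip probability

    def __post_init__(self) -> None:
        if len(set(self.columns)) != len(self.columns) or not self.columns:
            raise ValueError("planted group columns must be unique and non-empty")
        if not 0 <= self.noise < 0.5:
            raise ValueError(f"noise must be in [0, 0.5), got {self.noise}")
        if not 2 <= self.n_latent_states <= 20:
            raise ValueError("n_latent_states must be in [2, 20]")


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic alignment.

    Default dimensions mirror a chordate protein-family alignment:
    105 species.  Column indices are 1-based and must be disjoint across
    ``planted_groups``, ``invariant_columns`` and ``near_invariant``;
    unclaimed columns become i.i.d. background.
    """

    n_species: int = 105
    n_columns: int = 50
    planted_groups: list[PlantedGroup] = field(default_factory=list)
    invariant_columns: list[int] = field(default_factory=list)
    near_invariant: list[tuple[int, int]] = field(default_factory=list)
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2 or self.n_columns < 1:
            raise ValueError("need at least 2 species and 1 column")
        if not 0 <= self.gap_rate < 0.5:
            raise ValueError(f"gap_rate must be in [0, 0.5), got {self.gap_rate}")
        claimed: set[int] = set()
        for group in self.planted_groups:
            self._claim(claimed, group.columns)
        self._claim(claimed, self.invariant_columns)
        for idx, ndev in self.near_invariant:
            self._claim(claimed, [idx])
            if ndev not in (1, 2):
                raise ValueError("near-invariant deviation count must be 1 or 2")
            if ndev >= self.n_species:
                raise ValueError("more deviations than species")

    def _claim(self, claimed: set[int], columns) -> None:
        for c in columns:
            if not 1 <= c <= self.n_columns:
                raise ValueError(f"column index {c} outside 1..{self.n_columns}")
            if c in claimed:
                raise ValueError(f"column {c} assigned to more than one role")
            claimed.add(c)


@dataclass
class SyntheticTruth:
    """Ground truth of one generated alignment (reproducible from the seed)."""

    spec: SyntheticSpec
    latent_states: dict[tuple[int, ...], np.ndarray]  # group columns -> state/species
    deviation_rows: dict[int, list[int]]  # near-invariant column -> row indices
    gap_mask: np.ndarray  # boolean, same shape as the alignment


def generate_msa(spec: SyntheticSpec) -> tuple[Alignment, SyntheticTruth]:
    """Generate an alignment and its ground truth from a :class:`SyntheticSpec`."""
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_species, spec.n_columns
    grid = np.empty((n, m), dtype="<U1")

    # background: i.i.d. uniform over the 6-letter sub-alphabet
    grid[:, :] = rng.choice(BACKGROUND_ALPHABET, size=(n, m))

    latent: dict[tuple[int, ...], np.ndarray] = {}
    for group in spec.planted_groups:
        states = rng.integers(0, group.n_latent_states, size=n)
        latent[tuple(group.columns)] = states
        for col in group.columns:
            # each member column has its own injective state -> residue code
            code = rng.choice(AMINO_ACIDS, size=group.n_latent_states, replace=False)
            residues = code[states]
            if group.noise > 0:
                flip = rng.random(n) < group.noise
                for i in np.nonzero(flip)[0]:
                    others = AMINO_ACIDS[AMINO_ACIDS != residues[i]]
                    residues[i] = rng.choice(others)
            grid[:, col - 1] = residues

    for col in spec.invariant_columns:
        grid[:, col - 1] = rng.choice(AMINO_ACIDS)

    deviations: dict[int, list[int]] = {}
    for col, ndev in spec.near_invariant:
        base = rng.choice(AMINO_ACIDS)
        grid[:, col - 1] = base
        # deviants never hit the reference row, keeping its sequence canonical
        rows = rng.choice(np.arange(1, n), size=ndev, replace=False)
        other = rng.choice(AMINO_ACIDS[AMINO_ACIDS != base])
        grid[rows, col - 1] = other
        deviations[col] = sorted(int(r) for r in rows)

    gap_mask = np.zeros((n, m), dtype=bool)
    if spec.gap_rate > 0:
        gap_mask = rng.random((n, m)) < spec.gap_rate
        gap_mask[0, :] = False  # reference row stays gap-free
        grid[gap_mask] = GAP

    row_ids = ["reference"] + [f"species_{i:03d}" for i in range(1, n)]
    aln = Alignment(
        row_ids=row_ids,
        residues=grid,
        reference_row=0,
        column_positions=list(range(1, m + 1)),
    )
    truth = SyntheticTruth(
        spec=spec, latent_states=latent, deviation_rows=deviations, gap_mask=gap_mask
    )
    return aln, truth


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Plain-text key-value sidecar describing the planted structure."""
    spec = truth.spec
    lines = [
        f"n_species = {spec.n_species}",
        f"n_columns = {spec.n_columns}",
        f"gap_rate = {spec.gap_rate}",
        f"seed = {spec.seed}",
        f"invariant_columns = {' '.join(map(str, spec.invariant_columns))}",
    ]
    for col, ndev in spec.near_invariant:
        lines.append(
            f"near_invariant = {col} deviations={ndev} "
            f"rows={' '.join(map(str, truth.deviation_rows.get(col, [])))}"
        )
    for group in spec.planted_groups:
        states = truth.latent_states[tuple(group.columns)]
        lines.append(
            f"planted_group = columns={','.join(map(str, group.columns))} "
            f"states={group.n_latent_states} noise={group.noise} "
            f"latent={','.join(map(str, states.tolist()))}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth(path: str | Path) -> dict:
    """Parse a truth sidecar into a plain dictionary (for test harnesses)."""
    out: dict = {"near_invariant": [], "planted_groups": []}
    for raw in Path(path).read_text().splitlines():
        if "=" not in raw:
            continue
        key, value = raw.split("=", 1)
        key, value = key.strip(), value.strip()
        if key == "near_invariant":
            out["near_invariant"].append(value)
        elif key == "planted_group":
            out["planted_groups"].append(value)
        else:
            out[key] = value
    return out
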