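"""Binary phage-bacteria interaction matrices: data model, I/O, filtering, summaries.

The central object is :class:`InteractionMatrix` — hosts (bacterial strains)
as rows, phages as columns, cell 1 meaning the phage lysed the host in an
agar-overlay assay.  Two on-disk dialects are supported: a wide TSV with the
host identifier in the first column and phage identifiers in the header, and
a long-format ``host,phage`` CSV edge list.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InteractionMatrix",
    "MatrixProperties",
    "read_matrix",
    "write_matrix",
    "write_edge_list",
    "compute_properties",
    "filter_to_infected_hosts",
    "singleton_pairs",
    "read_annotations",
]


@dataclass(frozen=True, eq=False)
class InteractionMatrix:
    """A binary host x phage killing matrix.

    Parameters
    ----------
    host_ids
        Ordered, unique bacterial strain identifiers (rows).
    phage_ids
        Ordered, unique phage identifiers (columns).
    cells
        ``(len(host_ids), len(phage_ids))`` array of 0/1 values.
    """

    host_ids: tuple[str, ...]
    phage_ids: tuple[str, ...]
    cells: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        hosts = tuple(str(h) for h in self.host_ids)
        phages = tuple(str(p) for p in self.phage_ids)
        if len(set(hosts)) != len(hosts):
            raise ValueError("duplicate host identifiers")
        if len(set(phages)) != len(phages):
            raise ValueError("duplicate phage identifiers")
        arr = np.asarray(self.cells)
        if arr.shape != (len(hosts), len(phages)):
            raise ValueError(
                f"cell array shape {arr.shape} does not match "
                f"{len(hosts)} hosts x {len(phages)} phages"
            )
        bad = np.argwhere((arr != 0) & (arr != 1))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"non-binary cell value {arr[i, j]!r} at "
                f"host {hosts[i]!r}, phage {phages[j]!r}"
            )
        arr = arr.astype(np.int8)
        arr.setflags(write=False)
        object.__setattr__(self, "host_ids", hosts)
        object.__setattr__(self, "phage_ids", phages)
        object.__setattr__(self, "cells", arr)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionMatrix):
            return NotImplemented
        return (
            self.host_ids == other.host_ids
            and self.phage_ids == other.phage_ids
            and np.array_equal(self.cells, other.cells)
        )

    def __hash__(self) -> int:
        return hash((self.host_ids, self.phage_ids, self.cells.tobytes()))

    @property
    def n_hosts(self) -> int:
        return len(self.host_ids)

    @property
    def n_phages(self) -> int:
        return len(self.phage_ids)

    @property
    def n_interactions(self) -> int:
        return int(self.cells.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.asarray(self.cells), index=list(self.host_ids), columns=list(self.phage_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "InteractionMatrix":
        return cls(tuple(map(str, frame.index)), tuple(map(str, frame.columns)), frame.to_numpy())

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "InteractionMatrix":
        """Build a matrix from (host, phage) pairs.

        Row/column order is first-appearance order; listed pairs become 1,
        everything else 0.
        """
        hosts: dict[str, int] = {}
        phages: dict[str, int] = {}
        pairs = []
        for h, p in edges:
            h, p = str(h), str(p)
            hosts.setdefault(h, len(hosts))
            phages.setdefault(p, len(phages))
            pairs.append((hosts[h], phages[p]))
        if not pairs:
            raise ValueError("empty edge list")
        cells = np.zeros((len(hosts), len(phages)), dtype=np.int8)
        for i, j in pairs:
            cells[i, j] = 1
        return cls(tuple(hosts), tuple(phages), cells)


@dataclass(frozen=True)
class MatrixProperties:
    """Whole-matrix summary statistics.

    ``H``/``P`` host and phage counts, ``S = H + P`` total strains,
    ``I`` interaction count, ``M = H * P`` matrix size, ``C = I/M``
    connectance, and the mean interactions per host (``L_H = I/H``) and
    per phage (``L_P = I/P``).  Values are kept at full precision;
    :meth:`rendered` applies the conventional display rounding
    (connectance to 2 decimals, means to 1 decimal, half-up).
    """

    H: int
    P: int
    S: int
    I: int
    M: int
    C: float
    L_H: float
    L_P: float

    def rendered(self) -> dict[str, str]:
        def render(x: float, places: int) -> str:
            q = decimal.Decimal(10) ** -places
            return str(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))

        return {
            "H": str(self.H),
            "P": str(self.P),
            "S": str(self.S),
            "I": str(self.I),
            "M": str(self.M),
            "C": render(self.C, 2),
            "L_H": render(self.L_H, 1),
            "L_P": render(self.L_P, 1),
        }


def read_matrix(path: str | Path, format: str = "wide-tsv") -> InteractionMatrix:
    """Read an interaction matrix from ``path``.

    ``format`` is ``"wide-tsv"`` (host ids in the first column, phage ids in
    the header, 0/1 cells) or ``"edge-list"`` (CSV with header
    ``host,phage``, one interacting pair per row).
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty file: {path}")
    if format == "wide-tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        if frame.empty and frame.columns.empty:
            raise ValueError(f"no data in {path}")
        try:
            values = frame.to_numpy(dtype=np.int64)
        except ValueError as exc:
            raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
        return InteractionMatrix(tuple(frame.index), tuple(frame.columns), values)
    if format == "edge-list":
        frame = pd.read_csv(path, dtype=str)
        if list(frame.columns[:2]) != ["host", "phage"]:
            raise ValueError(f"edge list {path} must have header 'host,phage'")
        return InteractionMatrix.from_edges(frame.itertuples(index=False))
    raise ValueError(f"unknown format {format!r}")


def write_matrix(m: InteractionMatrix, path: str | Path) -> None:
    """Write the wide-TSV dialect (round-trips through :func:`read_matrix`)."""
    m.to_frame().to_csv(path, sep="\t", index_label="host")


def write_edge_list(m: InteractionMatrix, path: str | Path) -> None:
    rows, cols = np.nonzero(np.asarray(m.cells))
    frame = pd.DataFrame(
        {"host": [m.host_ids[i] for i in rows], "phage": [m.phage_ids[j] for j in cols]}
    )
    frame.to_csv(path, index=False)


def compute_properties(m: InteractionMatrix) -> MatrixProperties:
    """Summary statistics (counts, connectance, mean interactions)."""
    H, P = m.n_hosts, m.n_phages
    if H == 0 or P == 0:
        raise ValueError("matrix has zero hosts or zero phages")
    I = m.n_interactions
    M = H * P
    return MatrixProperties(H=H, P=P, S=H + P, I=I, M=M, C=I / M, L_H=I / H, L_P=I / P)


def filter_to_infected_hosts(m: InteractionMatrix) -> InteractionMatrix:
    """Drop hosts killed by no phage; phage set and ordering are unchanged."""
    keep = np.asarray(m.cells).sum(axis=1) >= 1
    return InteractionMatrix(
        tuple(h for h, k in zip(m.host_ids, keep) if k),
        m.phage_ids,
        np.asarray(m.cells)[keep],
    )


def singleton_pairs(m: InteractionMatrix) -> list[tuple[str, str]]:
    """Exclusive one-to-one (host, phage) pairs.

    A pair qualifies when the cell is 1, the host is killed by no other
    phage, and the phage kills no other host.  These pairs form their own
    network modules under any sensible partition, so the count is
    independent of the module-detection algorithm.
    """
    cells = np.asarray(m.cells)
    row_sums = cells.sum(axis=1)
    col_sums = cells.sum(axis=0)
    out = []
    for i, j in zip(*np.nonzero(cells)):
        if row_sums[i] == 1 and col_sums[j] == 1:
            out.append((m.host_ids[i], m.phage_ids[j]))
    return out


_MORPHOTYPES = {"non-tailed", "myovirus", "podovirus", "siphovirus"}
_LIFE_HISTORIES = {"temperate", "virulent", "unknown"}


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a per-phage annotation TSV.

    Expected header: ``phage_id, species_group, genus_group, morphotype,
    life_history``.  Validates that each species maps to a single genus and
    that categorical fields use known labels.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = ["phage_id", "species_group", "genus_group", "morphotype", "life_history"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    validate_annotations(frame)
    return frame


def validate_annotations(frame: pd.DataFrame) -> None:
    if frame["phage_id"].duplicated().any():
        dupes = frame.loc[frame["phage_id"].duplicated(), "phage_id"].tolist()
        raise ValueError(f"duplicate phage_id in annotations: {dupes}")
    genera_per_species = frame.groupby("species_group")["genus_group"].nunique()
    bad = genera_per_species[genera_per_species > 1]
    if not bad.empty:
        raise ValueError(f"species mapped to multiple genera: {list(bad.index)}")
    if "morphotype" in frame:
        unknown = set(frame["morphotype"].dropna()) - _MORPHOTYPES
        if unknown:
            raise ValueError(f"unknown morphotype labels: {sorted(unknown)}")
    if "life_history" in frame:
        unknown = set(frame["life_history"].dropna()) - _LIFE_HISTORIES
        if unknown:
            raise ValueError(f"unknown life_history labels: {sorted(unknown)}")
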