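"""Genetic marker maps in centimorgans.

A :class:`GeneticMap` holds an ordered set of markers on one chromosome with
strictly increasing genetic positions.  Map distance is converted to
recombination fraction with Haldane's mapping function, which assumes no
crossover interference — the assumption that makes line origin along the
chromosome a Markov process and hence makes the forward–backward machinery
in :mod:`lineorigin.hmm` exact.

Two practical map-building helpers live here as well: linear interpolation
of genetic position from physical coordinates between anchor markers, and
the deterministic fan-out that resolves runs of markers sharing the same
genetic position (co-located markers are spread evenly over
``[x - 0.05, x + 0.049]`` cM so that every inter-marker distance is
positive before any HMM computation).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MapError

__all__ = [
    "GeneticMap",
    "haldane_r",
    "interpolate_position",
    "space_tied_markers",
    "read_map",
    "write_map",
]

# Fan-out window for co-located markers: a run of n markers at position x is
# replaced by n evenly spaced positions from x - TIE_LO to x + TIE_HI.
TIE_LO = 0.05
TIE_HI = 0.049


def haldane_r(distance_cM):
    """Recombination fraction for a map distance under Haldane's function.

    r = (1 - exp(-2 d)) / 2 with d in Morgans; ``distance_cM`` is given in
    centimorgans.  Monotone increasing, r(0) = 0, r -> 0.5 as d -> infinity.
    Accepts scalars or arrays.
    """
    d = np.asarray(distance_cM, dtype=float)
    if np.any(d < 0):
        raise MapError("map distance must be non-negative, got %r" % (distance_cM,))
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


def interpolate_position(query_bp, left_anchor, right_anchor):
    """Genetic position (cM) of a physical coordinate between two anchors.

    Each anchor is a ``(bp, cM)`` pair; the genetic position is assumed to
    vary linearly with the physical position over the interval.  Queries
    outside the anchors are rejected (extrapolation is undefined).
    """
    lb, lc = left_anchor
    rb, rc = right_anchor
    if not lb < rb:
        raise MapError(f"anchors must satisfy left.bp < right.bp, got {lb} and {rb}")
    if not (lb <= query_bp <= rb):
        raise MapError(f"query {query_bp} bp outside anchor interval [{lb}, {rb}]")
    frac = (query_bp - lb) / (rb - lb)
    return lc + frac * (rc - lc)


def space_tied_markers(positions_cM: Sequence[float], marker_ids: Sequence[str] | None = None) -> np.ndarray:
    """Resolve runs of identical genetic positions into strictly increasing ones.

    Every maximal run of n >= 2 markers at position x becomes n evenly
    spaced positions from x - 0.05 to x + 0.049 inclusive; singleton
    positions are untouched.  Raises :class:`MapError` if the fan-out would
    overlap a neighbouring distinct position (naming the offending markers).
    """
    pos = np.asarray(positions_cM, dtype=float)
    if pos.size and np.any(np.diff(pos) < 0):
        raise MapError("positions must be non-decreasing before tie resolution")
    out = pos.copy()
    i = 0
    n = pos.size
    while i < n:
        j = i
        while j + 1 < n and pos[j + 1] == pos[i]:
            j += 1
        run = j - i + 1
        if run >= 2:
            out[i : j + 1] = np.linspace(pos[i] - TIE_LO, pos[i] + TIE_HI, run)
        i = j + 1
    bad = np.nonzero(np.diff(out) <= 0)[0]
    if bad.size:
        k = int(bad[0])
        ids = list(marker_ids) if marker_ids is not None else [f"#{m}" for m in range(n)]
        raise MapError(
            "tie fan-out breaks map order between markers "
            f"{ids[k]} ({out[k]:.4f} cM) and {ids[k + 1]} ({out[k + 1]:.4f} cM); "
            "adjacent distinct positions are closer than the fan-out window"
        )
    return out


class GeneticMap:
    """Ordered marker positions on one chromosome.

    Parameters
    ----------
    marker_ids
        Marker labels, in map order.
    positions_cM
        Strictly increasing genetic positions (resolve ties first with
        :func:`space_tied_markers`).
    chromosome
        Chromosome label (single-chromosome unit of computation).
    length_cM
        Chromosome length; defaults to the last marker position.  The test
        grid used for inference spans ``[0, length_cM]``.
    """

    def __init__(self, marker_ids, positions_cM, chromosome="1", length_cM=None):
        self.marker_ids = tuple(str(m) for m in marker_ids)
        self.positions_cM = np.asarray(positions_cM, dtype=float)
        self.chromosome = str(chromosome)
        if self.positions_cM.ndim != 1 or len(self.marker_ids) != self.positions_cM.size:
            raise MapError("marker_ids and positions_cM must be 1-D and equal length")
        if self.positions_cM.size == 0:
            raise MapError("a map needs at least one marker")
        if np.any(np.diff(self.positions_cM) <= 0):
            raise MapError("positions must be strictly increasing (resolve ties first)")
        if self.positions_cM[0] < 0:
            raise MapError("positions must be non-negative")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise MapError("duplicate marker ids")
        self.length_cM = float(length_cM) if length_cM is not None else float(self.positions_cM[-1])
        if self.length_cM < self.positions_cM[-1]:
            raise MapError("length_cM must be >= last marker position")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def distances_cM(self) -> np.ndarray:
        """Inter-marker distances (length ``n_markers - 1``)."""
        return np.diff(self.positions_cM)

    def recombination_fractions(self) -> np.ndarray:
        """Haldane recombination fraction for each inter-marker interval."""
        return haldane_r(self.distances_cM())

    def grid(self, step_cM: float = 1.0) -> np.ndarray:
        """Test positions ``0, step, 2·step, ... <= length_cM``."""
        if step_cM <= 0:
            raise MapError("grid step must be positive")
        n = int(np.floor(self.length_cM / step_cM + 1e-9)) + 1
        return np.arange(n) * step_cM

    @classmethod
    def evenly_spaced(cls, n_markers: int, length_cM: float, chromosome="1"):
        """Map with ``n_markers`` evenly spaced over ``[0, length_cM]``."""
        if n_markers < 2:
            raise MapError("evenly_spaced needs at least 2 markers")
        pos = np.linspace(0.0, length_cM, n_markers)
        ids = [f"M{i + 1:04d}" for i in range(n_markers)]
        return cls(ids, pos, chromosome=chromosome, length_cM=length_cM)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "chromosome": self.chromosome,
                "position_cM": self.positions_cM,
            }
        )

    def __eq__(self, other):
        return (
            isinstance(other, GeneticMap)
            and self.marker_ids == other.marker_ids
            and self.chromosome == other.chromosome
            and self.length_cM == other.length_cM
            and np.array_equal(self.positions_cM, other.positions_cM)
        )

    def __repr__(self):
        return (
            f"GeneticMap(chromosome={self.chromosome!r}, n_markers={self.n_markers}, "
            f"length_cM={self.length_cM})"
        )


def read_map(path, resolve_ties: bool = True, length_cM=None) -> GeneticMap:
    """Read a tab-separated map file.

    Columns ``marker_id  chromosome  position_cM`` (header required); an
    optional ``position_bp`` column is accepted and ignored here (it feeds
    interpolation workflows).  Ties are resolved with
    :func:`space_tied_markers` unless ``resolve_ties=False``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str})
    required = {"marker_id", "chromosome", "position_cM"}
    if not required.issubset(df.columns):
        raise MapError(f"map file {path} must have columns {sorted(required)}, got {list(df.columns)}")
    chroms = df["chromosome"].unique()
    if len(chroms) != 1:
        raise MapError(f"map file {path} must contain a single chromosome, got {list(chroms)}")
    pos = df["position_cM"].to_numpy(dtype=float)
    if np.any(np.diff(pos) < 0):
        raise MapError(f"map file {path}: positions must be sorted non-decreasing")
    ids = df["marker_id"].tolist()
    if resolve_ties:
        pos = space_tied_markers(pos, ids)
    return GeneticMap(ids, pos, chromosome=chroms[0], length_cM=length_cM)


def write_map(gmap: GeneticMap, path) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
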