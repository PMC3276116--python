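"""Forward–backward inference of line-origin posteriors.

The hidden chain runs over the merged, sorted sequence of marker positions
and test positions.  Test positions are pseudo-observations with emission 1
in every state (all origins compatible), so they cost one transition step
each and nothing more.  The transition kernel between consecutive positions
factorises over the two meioses: each haplotype's origin switches line with
probability r = Haldane(d) independently, giving a 4x4 kernel that is the
Kronecker product of two 2x2 kernels (maternal factor first).  The initial
state distribution is uniform (1/4 per state): an F2's two haplotype
origins are a priori independent fair coins, and any flanking marker data
dominates it anyway.

Underflow is controlled by the standard per-position rescaling of the
forward and backward variables; the log of the accumulated scale is kept
so that likelihoods remain available.  A brute-force enumeration oracle
(:func:`enumerate_posteriors`) sums over all 4^n complete state sequences
and serves as the independent correctness reference on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .emission import EmissionConfig, build_emission_table
from .genetic_map import GeneticMap, haldane_r
from .pedigree_io import GenotypeMatrix, Pedigree, PosteriorGrid

__all__ = [
    "transition_matrix",
    "ForwardTable",
    "BackwardTable",
    "forward",
    "backward",
    "posterior",
    "infer",
    "enumerate_posteriors",
]

_POSITION_TOL = 1e-9


def transition_matrix(d_maternal_cM: float, d_paternal_cM: float | None = None) -> np.ndarray:
    """4x4 line-origin transition kernel over one inter-position interval.

    Separate maternal and paternal distances support sex-specific maps;
    by default both meioses use the same distance.  Rows sum to 1 and the
    kernel is the identity at zero distance.
    """
    if d_paternal_cM is None:
        d_paternal_cM = d_maternal_cM
    rm = haldane_r(d_maternal_cM)
    rp = haldane_r(d_paternal_cM)
    tm = np.array([[1 - rm, rm], [rm, 1 - rm]])
    tp = np.array([[1 - rp, rp], [rp, 1 - rp]])
    return np.kron(tm, tp)


def _merge_positions(marker_pos: np.ndarray, test_pos: np.ndarray):
    """Sorted union of marker and test positions (exact within 1e-9).

    Returns ``(all_positions, marker_slots, test_slots)`` where the slot
    arrays map each marker / test position to its index in the union.
    A test position coinciding with a marker shares the marker's slot.
    """
    marker_pos = np.asarray(marker_pos, dtype=float)
    test_pos = np.asarray(test_pos, dtype=float)
    merged = np.concatenate([marker_pos, test_pos])
    merged.sort(kind="stable")
    keep = np.ones(merged.size, dtype=bool)
    keep[1:] = np.diff(merged) > _POSITION_TOL
    all_pos = merged[keep]

    def slots(p):
        idx = np.searchsorted(all_pos, p - _POSITION_TOL, side="left")
        return np.minimum(idx, all_pos.size - 1)

    return all_pos, slots(marker_pos), slots(test_pos)


def _interval_kernels(all_pos, d_maternal=None, d_paternal=None):
    """Transition kernels for each interval of the merged position sequence."""
    dm = np.diff(all_pos) if d_maternal is None else np.asarray(d_maternal, float)
    dp = dm if d_paternal is None else np.asarray(d_paternal, float)
    return np.stack([transition_matrix(a, b) for a, b in zip(dm, dp)]) if dm.size else np.zeros((0, 4, 4))


def _expand_emissions(emissions: np.ndarray, marker_slots: np.ndarray, n_slots: int) -> np.ndarray:
    """Marker emissions placed into the merged sequence; test slots emit 1."""
    full = np.ones(emissions.shape[:-2] + (n_slots, 4), dtype=float)
    full[..., marker_slots, :] = emissions
    return full


def _run_forward(E: np.ndarray, kernels: np.ndarray):
    """Scaled forward pass, vectorised over individuals.

    ``E`` is (n_ind, n_slots, 4); returns (alpha, log_scale) with alpha
    normalised to sum 1 at every slot and log_scale the accumulated log
    normaliser (so exp(log_scale[:, -1]) is the data likelihood).
    """
    n_ind, n_slots, _ = E.shape
    alpha = np.empty_like(E)
    logc = np.empty((n_ind, n_slots))
    a = 0.25 * E[:, 0, :]
    c = a.sum(axis=1, keepdims=True)
    alpha[:, 0, :] = a / c
    logc[:, 0] = np.log(c[:, 0])
    for p in range(1, n_slots):
        a = (alpha[:, p - 1, :] @ kernels[p - 1]) * E[:, p, :]
        c = a.sum(axis=1, keepdims=True)
        alpha[:, p, :] = a / c
        logc[:, p] = logc[:, p - 1] + np.log(c[:, 0])
    return alpha, logc


def _run_backward(E: np.ndarray, kernels: np.ndarray):
    """Scaled backward pass, mirror of :func:`_run_forward` (terminal beta = 1)."""
    n_ind, n_slots, _ = E.shape
    beta = np.empty_like(E)
    logc = np.zeros((n_ind, n_slots))
    beta[:, -1, :] = 1.0
    for p in range(n_slots - 2, -1, -1):
        b = (E[:, p + 1, :] * beta[:, p + 1, :]) @ kernels[p].T
        c = b.sum(axis=1, keepdims=True)
        beta[:, p, :] = b / c
        logc[:, p] = logc[:, p + 1] + np.log(c[:, 0])
    return beta, logc


@dataclass
class ForwardTable:
    """Scaled forward variables for one individual over the merged positions."""

    positions_cM: np.ndarray
    values: np.ndarray  # (n_positions, 4), each row sums to 1
    log_scale: np.ndarray  # accumulated log normaliser per position

    @property
    def operation_count(self) -> int:
        """Multiply-accumulate count of the pass — linear in positions."""
        return 16 * max(self.positions_cM.size - 1, 0)


@dataclass
class BackwardTable:
    positions_cM: np.ndarray
    values: np.ndarray
    log_scale: np.ndarray

    @property
    def operation_count(self) -> int:
        return 16 * max(self.positions_cM.size - 1, 0)


def _prepare(emissions, gmap, test_positions):
    emissions = np.asarray(emissions, dtype=float)
    if emissions.shape != (gmap.n_markers, 4):
        raise ValueError(f"emissions must be ({gmap.n_markers}, 4), got {emissions.shape}")
    test_positions = np.asarray(test_positions, dtype=float)
    if test_positions.size and (
        test_positions.min() < -_POSITION_TOL or test_positions.max() > gmap.length_cM + _POSITION_TOL
    ):
        raise ValueError("test positions must lie within [0, length_cM]")
    all_pos, marker_slots, test_slots = _merge_positions(gmap.positions_cM, test_positions)
    E = _expand_emissions(emissions[None], marker_slots, all_pos.size)
    return E, all_pos, test_slots


def forward(emissions, gmap: GeneticMap, test_positions) -> ForwardTable:
    """Forward pass for one individual's marker emissions (n_markers x 4)."""
    E, all_pos, _ = _prepare(emissions, gmap, test_positions)
    kernels = _interval_kernels(all_pos)
    alpha, logc = _run_forward(E, kernels)
    return ForwardTable(all_pos, alpha[0], logc[0])


def backward(emissions, gmap: GeneticMap, test_positions) -> BackwardTable:
    """Backward pass for one individual's marker emissions (n_markers x 4)."""
    E, all_pos, _ = _prepare(emissions, gmap, test_positions)
    kernels = _interval_kernels(all_pos)
    beta, logc = _run_backward(E, kernels)
    return BackwardTable(all_pos, beta[0], logc[0])


def posterior(fwd: ForwardTable, bwd: BackwardTable, individual: str = "0") -> PosteriorGrid:
    """Combine forward and backward tables into normalised posteriors."""
    if fwd.positions_cM.shape != bwd.positions_cM.shape or not np.allclose(
        fwd.positions_cM, bwd.positions_cM
    ):
        raise ValueError("forward and backward tables cover different positions")
    prod = fwd.values * bwd.values
    norm = prod.sum(axis=1, keepdims=True)
    if np.any(norm <= 0) or not np.all(np.isfinite(norm)):
        raise ValueError("degenerate forward-backward product (zero likelihood at a position)")
    return PosteriorGrid((individual,), fwd.positions_cM, (prod / norm)[None])


def infer(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    gmap: GeneticMap,
    config: EmissionConfig = EmissionConfig(),
    grid_step_cM: float = 1.0,
    include_markers: bool = False,
    test_positions=None,
    parental_phase=None,
) -> PosteriorGrid:
    """Line-origin posteriors for every F2 individual at the test grid.

    The grid is ``0, step, 2·step, ... <= length`` (markers added when
    ``include_markers``); posteriors at each grid point are the four state
    probabilities in the order (1,1), (1,2), (2,1), (2,2).  Individuals are
    processed independently, so the result does not depend on their input
    order.
    """
    table = build_emission_table(genotypes, pedigree, config, parental_phase=parental_phase)
    if tuple(table.marker_ids) != tuple(gmap.marker_ids):
        raise ValueError("genotype markers do not match the map")
    if test_positions is None:
        test_positions = gmap.grid(grid_step_cM)
    test_positions = np.asarray(test_positions, dtype=float)
    out_positions = test_positions
    if include_markers:
        out_positions = np.union1d(test_positions, gmap.positions_cM)

    all_pos, marker_slots, out_slots = _merge_positions(gmap.positions_cM, out_positions)
    E = _expand_emissions(table.values, marker_slots, all_pos.size)
    kernels = _interval_kernels(all_pos)
    alpha, _ = _run_forward(E, kernels)
    beta, _ = _run_backward(E, kernels)
    prod = alpha * beta
    prod /= prod.sum(axis=2, keepdims=True)
    return PosteriorGrid(table.f2_ids, all_pos[out_slots], prod[:, out_slots, :])


def enumerate_posteriors(
    emissions, gmap: GeneticMap, test_positions, max_positions: int = 12, individual: str = "0"
) -> PosteriorGrid:
    """Exhaustive-enumeration reference posteriors (verification only).

    Sums the probability of every complete state sequence over the merged
    positions (4^n of them): weight = 1/4 x prod(transitions) x
    prod(emissions), then marginalises per position and normalises.  This
    generalises evaluating every origin combination between informative
    flanks — it enumerates over *all* positions — and must agree with the
    forward–backward posteriors exactly.
    """
    E, all_pos, _ = _prepare(emissions, gmap, test_positions)
    n = all_pos.size
    if n > max_positions:
        raise ValueError(f"enumeration over {n} positions (> {max_positions}) is intractable")
    kernels = _interval_kernels(all_pos)
    seqs = np.array(list(product(range(4), repeat=n)), dtype=np.intp)  # (4^n, n)
    weights = np.full(seqs.shape[0], 0.25)
    weights *= E[0, 0, seqs[:, 0]]
    for p in range(1, n):
        weights *= kernels[p - 1][seqs[:, p - 1], seqs[:, p]]
        weights *= E[0, p, seqs[:, p]]
    probs = np.zeros((n, 4))
    for p in range(n):
        for s in range(4):
            probs[p, s] = weights[seqs[:, p] == s].sum()
    probs /= probs.sum(axis=1, keepdims=True)
    return PosteriorGrid((individual,), all_pos, probs[None])
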