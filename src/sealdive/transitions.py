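"""Per-individual state tables over consecutive dives, aggregated
across individuals.

The primary output is the joint pair-frequency matrix: cell (i, j) is
the fraction of consecutive dive pairs whose first member is in state i
and second in state j, so all cells of a matrix sum to 1. A
row-conditional kernel (rows summing to 1) is carried alongside for
simulation-recovery checks. Matrices are built per seal and averaged
with each seal weighted equally; dispersion across seals is the sample
standard deviation by default (variance switchable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TransitionMatrix",
    "state_sequence",
    "joint_transition_matrix",
    "conditional_kernel",
    "aggregate_across_seals",
    "transition_analysis",
    "transition_long_table",
]

DIVE_TYPE_STATES = ("shallow", "pelagic", "benthic")
SEDIMENT_STATES = ("fine", "coarse", "rock", "unclassified")


@dataclass
class TransitionMatrix:
    """Joint pair-frequency matrices per seal plus cross-seal summary."""

    states: tuple[str, ...]
    per_seal: dict[str, np.ndarray]
    mean: np.ndarray
    dispersion: np.ndarray
    n_pairs: dict[str, int]
    dispersion_kind: str = "sd"


def state_sequence(dives: pd.DataFrame, attribute: str) -> list[str]:
    """Temporally ordered state labels for one seal's dives.

    Input must already be sorted by start time (unsorted input is a
    caller error, not silently fixed). Missing labels are skipped.
    """
    if attribute not in dives.columns:
        raise KeyError(f"column {attribute!r} not present")
    start = dives["start_time"].to_numpy(dtype="datetime64[ns]")
    if len(start) > 1 and np.any(np.diff(start).astype(np.int64) < 0):
        raise ValueError("dives must be sorted by start_time")
    labels = dives[attribute]
    return [str(v) for v in labels if isinstance(v, str) or not pd.isna(v)]


def joint_transition_matrix(
    seq: list[str], states: tuple[str, ...]
) -> tuple[np.ndarray, int]:
    """Joint frequency of consecutive state pairs; entries sum to 1."""
    index = {s: i for i, s in enumerate(states)}
    unknown = set(seq) - set(states)
    if unknown:
        raise ValueError(f"labels outside state set: {sorted(unknown)}")
    if len(seq) < 2:
        raise ValueError("need at least 2 labels to form a pair")
    k = len(states)
    counts = np.zeros((k, k))
    for a, b in zip(seq[:-1], seq[1:]):
        counts[index[a], index[b]] += 1.0
    n_pairs = len(seq) - 1
    return counts / n_pairs, n_pairs


def conditional_kernel(joint: np.ndarray) -> np.ndarray:
    """Row-normalised kernel from a joint matrix; zero rows stay zero."""
    row_sums = joint.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        kernel = np.where(row_sums > 0, joint / row_sums, 0.0)
    return kernel


def aggregate_across_seals(
    per_seal: dict[str, tuple[tuple[str, ...], np.ndarray]],
    dispersion: str = "sd",
    ddof: int = 1,
) -> TransitionMatrix:
    """Unweighted cross-seal mean and dispersion of joint matrices.

    Each seal counts as one unit regardless of its dive count. When
    state sets differ, the union is taken and absent states contribute
    zero cells.
    """
    if not per_seal:
        raise ValueError("no per-seal matrices to aggregate")
    if dispersion not in ("sd", "var"):
        raise ValueError("dispersion must be 'sd' or 'var'")

    all_states: list[str] = []
    for states, _ in per_seal.values():
        for s in states:
            if s not in all_states:
                all_states.append(s)
    k = len(all_states)
    pos = {s: i for i, s in enumerate(all_states)}

    aligned: dict[str, np.ndarray] = {}
    for seal_id, (states, mat) in per_seal.items():
        full = np.zeros((k, k))
        idx = [pos[s] for s in states]
        full[np.ix_(idx, idx)] = mat
        aligned[seal_id] = full

    stack = np.stack(list(aligned.values()))
    mean = stack.mean(axis=0)
    if stack.shape[0] > ddof:
        disp = stack.var(axis=0, ddof=ddof)
        if dispersion == "sd":
            disp = np.sqrt(disp)
    else:
        disp = np.zeros((k, k))
    return TransitionMatrix(
        states=tuple(all_states),
        per_seal=aligned,
        mean=mean,
        dispersion=disp,
        n_pairs={},
        dispersion_kind=dispersion,
    )


def transition_analysis(
    dives: pd.DataFrame,
    attribute: str,
    states: tuple[str, ...] | None = None,
    dispersion: str = "sd",
    ddof: int = 1,
) -> TransitionMatrix:
    """Build per-seal joint matrices for ``attribute`` and aggregate.

    Seals with fewer than two labelled dives form no pairs and are
    excluded from the aggregation with a warning.
    """
    if states is None:
        states = DIVE_TYPE_STATES if attribute == "dive_type" else SEDIMENT_STATES
    per_seal: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    n_pairs: dict[str, int] = {}
    for seal_id, seal_dives in dives.groupby("seal_id", sort=False):
        seq = state_sequence(seal_dives.sort_values("start_time"), attribute)
        if len(seq) < 2:
            warnings.warn(f"seal {seal_id}: <2 labelled dives, excluded")
            continue
        joint, n = joint_transition_matrix(seq, states)
        per_seal[str(seal_id)] = (states, joint)
        n_pairs[str(seal_id)] = n
    result = aggregate_across_seals(per_seal, dispersion=dispersion, ddof=ddof)
    result.n_pairs = n_pairs
    return result


def transition_long_table(tm: TransitionMatrix) -> pd.DataFrame:
    """Long-format export: per-seal rows plus MEAN and dispersion rows."""
    rows = []
    disp_label = tm.dispersion_kind.upper()
    for seal_id, mat in tm.per_seal.items():
        for i, a in enumerate(tm.states):
            for j, b in enumerate(tm.states):
                rows.append((seal_id, a, b, mat[i, j]))
    for label, mat in (("MEAN", tm.mean), (disp_label, tm.dispersion)):
        for i, a in enumerate(tm.states):
            for j, b in enumerate(tm.states):
                rows.append((label, a, b, mat[i, j]))
    return pd.DataFrame(rows, columns=["seal_id", "from_state", "to_state", "value"])
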