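"""Crosstalk analysis and orthogonal channel selection.

A receptor x ligand activation matrix (cognate pair i on the diagonal) is
normalized so each receptor's maximum activation is 100% and water is 0%.
Off-diagonal entries at or above a threshold (default 15%) are cross-activation
calls.  The largest set of mutually orthogonal channels is found exactly:
build a conflict graph with one node per cognate pair and an edge (i, j)
whenever ligand j activates receptor i or vice versa, then compute a maximum
independent set by branch and bound.  The returned set carries a certificate
(re-scanned against the call matrix) and a deterministic tie-break (the
lexicographically smallest optimal set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActivationMatrix",
    "CrosstalkCall",
    "ChannelSet",
    "percent_activation",
    "classify_crosstalk",
    "receptor_summary",
    "select_orthogonal_channels",
    "enumerate_optimal_sets",
]


@dataclass
class ActivationMatrix:
    """Square receptor x ligand percent-activation table.

    Row i = receptor of cognate pair i, column j = ligand of pair j; values on
    the 0-100 scale with each row's maximum at 100 after normalization (rows
    flagged unresponsive are all zero).
    """

    pair_ids: list
    values: np.ndarray
    test_dose: float = float("nan")
    unresponsive: tuple = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.pair_ids)
        if self.values.shape != (n, n):
            raise ValueError("activation matrix must be square over pair_ids")
        if np.any(self.values < 0):
            raise ValueError("activation values must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pair_ids, columns=self.pair_ids)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path, test_dose: float = float("nan")) -> "ActivationMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float), test_dose)


@dataclass
class CrosstalkCall:
    """Binary cross-activation calls (diagonal excluded)."""

    pair_ids: list
    calls: np.ndarray  # bool matrix, calls[i, j] = ligand j activates receptor i
    threshold: float
    cognate_activation: np.ndarray = field(default=None)  # diagonal, reported separately

    @property
    def n(self) -> int:
        return len(self.pair_ids)


@dataclass
class ChannelSet:
    """A mutually orthogonal set of cognate peptide-GPCR channels."""

    selected: list  # sorted pair indices
    pair_ids: list
    certificate: bool  # independently re-verified against the call matrix
    optimal: bool  # proven maximum cardinality

    @property
    def size(self) -> int:
        return len(self.selected)


def percent_activation(
    raw: np.ndarray | pd.DataFrame,
    water: Sequence[float],
    pair_ids: Sequence | None = None,
    test_dose: float = float("nan"),
) -> ActivationMatrix:
    """Normalize a raw fluorescence matrix to percent activation.

    Per receptor row: (raw - water) / (row max - water) x 100, negatives
    clamped to 0.  Rows whose maximum does not exceed the water baseline are
    flagged unresponsive and zeroed.
    """
    if isinstance(raw, pd.DataFrame):
        pair_ids = pair_ids or list(raw.index)
        raw = raw.to_numpy(dtype=float)
    raw = np.asarray(raw, dtype=float)
    water = np.asarray(water, dtype=float)
    n = raw.shape[0]
    if pair_ids is None:
        pair_ids = list(range(n))
    values = np.zeros_like(raw)
    unresponsive = []
    for i in range(n):
        span = raw[i].max() - water[i]
        if span <= 0:
            unresponsive.append(pair_ids[i])
            continue
        values[i] = np.clip((raw[i] - water[i]) / span * 100.0, 0.0, None)
    if unresponsive:
        warnings.warn(f"unresponsive rows zeroed: {unresponsive}")
    return ActivationMatrix(list(pair_ids), values, test_dose, tuple(unresponsive))


def classify_crosstalk(m: ActivationMatrix, threshold: float = 15.0) -> CrosstalkCall:
    """Call cross-activation for every off-diagonal cell >= threshold (inclusive)."""
    calls = m.values >= threshold
    np.fill_diagonal(calls, False)
    return CrosstalkCall(
        pair_ids=list(m.pair_ids),
        calls=calls,
        threshold=threshold,
        cognate_activation=np.diagonal(m.values).copy(),
    )


def receptor_summary(call: CrosstalkCall) -> dict:
    """Bin receptors by how many non-cognate ligands activate them."""
    counts = call.calls.sum(axis=1)
    return {
        "fully_orthogonal": int(np.sum(counts == 0)),
        "one_cross": int(np.sum(counts == 1)),
        "several": int(np.sum(counts >= 2)),
        "per_receptor": {pid: int(c) for pid, c in zip(call.pair_ids, counts)},
    }


# ---------------------------------------------------------------------------
# Exact maximum independent set (branch and bound on vertex bitmasks)
# ---------------------------------------------------------------------------

def _conflict_masks(call: CrosstalkCall) -> list[int]:
    """Neighbor bitmask per pair in the (undirected) conflict graph."""
    n = call.n
    sym = call.calls | call.calls.T
    masks = []
    for i in range(n):
        m = 0
        for j in range(n):
            if j != i and sym[i, j]:
                m |= 1 << j
        masks.append(m)
    return masks


def _greedy_independent(masks: list[int], candidates: int) -> int:
    """Greedy min-degree independent set (lower bound); returns a bitmask."""
    chosen = 0
    p = candidates
    while p:
        verts = _bits(p)
        v = min(verts, key=lambda u: _popcount(masks[u] & p))
        chosen |= 1 << v
        p &= ~(masks[v] | (1 << v))
    return chosen


def _popcount(x: int) -> int:
    return x.bit_count()


def _bits(x: int):
    while x:
        b = x & -x
        yield b.bit_length() - 1
        x ^= b


def _mis_size(masks: list[int], candidates: int, best: int = 0) -> int:
    """Exact maximum-independent-set size within the candidate bitmask."""
    if candidates == 0:
        return 0
    greedy = _popcount(_greedy_independent(masks, candidates))
    best = max(best, greedy)

    def bb(p: int, current: int, best: int) -> int:
        if current + _popcount(p) <= best:
            return best  # prune: cannot beat incumbent
        if p == 0:
            return max(best, current)
        # pick the candidate vertex with most candidate neighbors
        v = max(_bits(p), key=lambda u: _popcount(masks[u] & p))
        if masks[v] & p == 0:
            # isolated within p: always take it
            return bb(p & ~(1 << v), current + 1, best)
        # branch 1: include v
        best = bb(p & ~(masks[v] | (1 << v)), current + 1, best)
        # branch 2: exclude v
        return bb(p & ~(1 << v), current, best)

    return bb(candidates, 0, best)


def select_orthogonal_channels(call: CrosstalkCall) -> ChannelSet:
    """Exact maximum set of mutually orthogonal channels.

    Among all maximum-cardinality solutions the lexicographically smallest
    index set is returned, so the result is deterministic.  The certificate is
    computed by independently re-scanning the call matrix over the selection.
    """
    masks = _conflict_masks(call)
    n = call.n
    full = (1 << n) - 1
    k = _mis_size(masks, full)

    selected: list[int] = []
    p = full
    need = k
    for i in range(n):
        if not (p >> i) & 1:
            continue
        # can we still reach `need` picks if we commit to i?
        rest = p & ~(masks[i] | (1 << i))
        if 1 + _mis_size(masks, rest) >= need:
            selected.append(i)
            p = rest
            need -= 1
            if need == 0:
                break
        else:
            p &= ~(1 << i)

    certificate = _verify_channel_set(call, selected)
    return ChannelSet(selected=selected, pair_ids=[call.pair_ids[i] for i in selected],
                      certificate=certificate, optimal=True)


def _verify_channel_set(call: CrosstalkCall, selected: Sequence[int]) -> bool:
    """Independent check: no within-set cross-activation in either direction."""
    for i in selected:
        for j in selected:
            if i != j and (call.calls[i, j] or call.calls[j, i]):
                return False
    return True


def enumerate_optimal_sets(call: CrosstalkCall, cap: int = 100) -> list[list[int]]:
    """All maximum-cardinality orthogonal sets, up to ``cap`` of them."""
    masks = _conflict_masks(call)
    n = call.n
    k = _mis_size(masks, (1 << n) - 1)
    out: list[list[int]] = []

    def extend(start: int, chosen: list[int], p: int) -> None:
        if len(out) >= cap:
            return
        if len(chosen) == k:
            out.append(list(chosen))
            return
        for v in range(start, n):
            if not (p >> v) & 1:
                continue
            rest = p & ~(masks[v] | (1 << v))
            if len(chosen) + 1 + _mis_size(masks, rest & ~((1 << (v + 1)) - 1)) >= k:
                chosen.append(v)
                extend(v + 1, chosen, rest)
                chosen.pop()
            if len(out) >= cap:
                return

    extend(0, [], (1 << n) - 1)
    return out
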