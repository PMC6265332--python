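"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own algorithms: maximum
independent set by full subset enumeration, and global alignment by
exhaustive recursion, so solver results can be checked against ground truth.
"""

import numpy as np
import pytest

from matelang.curves import DetectorModel, FourPL


@pytest.fixture
def detector():
    return DetectorModel(a_sat=2.0, k=1.0)


@pytest.fixture
def sc_ste2_like():
    """A 4PL parameter set with the printed Sc.Ste2-level sensitivity."""
    return FourPL(basal=100.0, maximal=1700.0, ec50=1.25, hill=1.3)


def brute_force_mis_size(calls: np.ndarray) -> int:
    """Maximum orthogonal-set size by enumerating all 2^n subsets."""
    n = calls.shape[0]
    sym = calls | calls.T
    masks = []
    for i in range(n):
        m = 0
        for j in range(n):
            if j != i and sym[i, j]:
                m |= 1 << j
        masks.append(m)
    best = 0
    for s in range(1 << n):
        size = s.bit_count()
        if size <= best:
            continue
        if all(not (s >> i) & 1 or (masks[i] & s) == 0 for i in range(n)):
            best = size
    return best


def brute_force_identity(a: str, b: str, gap_open=2.0, gap_extend=0.5):
    """All-alignments enumeration: returns the set of percent identities among
    maximum-score global alignments (match +1, mismatch -1, affine gaps)."""
    best: dict = {"score": -np.inf, "idents": set()}

    def rec(i, j, score, matches, cols, last):
        # bound: remaining best score is all matches
        if score + (min(len(a) - i, len(b) - j)) < best["score"] - 1e-9:
            pass  # cheap bound is unsafe with negative scores ahead; skip pruning
        if i == len(a) and j == len(b):
            if score > best["score"] + 1e-9:
                best["score"] = score
                best["idents"] = {100.0 * matches / cols}
            elif abs(score - best["score"]) <= 1e-9:
                best["idents"].add(100.0 * matches / cols)
            return
        if i < len(a) and j < len(b):
            s = 1.0 if a[i] == b[j] else -1.0
            rec(i + 1, j + 1, score + s, matches + (a[i] == b[j]), cols + 1, "m")
        if i < len(a):
            g = -gap_extend if last == "ga" else -gap_open
            rec(i + 1, j, score + g, matches, cols + 1, "ga")
        if j < len(b):
            g = -gap_extend if last == "gb" else -gap_open
            rec(i, j + 1, score + g, matches, cols + 1, "gb")

    rec(0, 0, 0.0, 0, 0, "")
    return best["score"], best["idents"]
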