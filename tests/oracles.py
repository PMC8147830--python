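"""Independent brute-force oracles used to cross-check the fast paths.

These deliberately avoid scipy.signal and the package's own detector: local
maxima, prominences and the taller-peak-wins separation rule are evaluated
directly from their definitions by explicit scans.
"""

from __future__ import annotations

import numpy as np


def brute_force_peaks(
    x: np.ndarray, min_prominence: float, min_separation_px: float
) -> list[int]:
    """All retained peaks (plateau-left-edge indices), sorted by depth.

    Rules, applied in order:
    1. a candidate is a sample (or flat plateau) strictly above both
       neighbours; interior plateaus count once, at their first sample;
    2. prominence: height minus the higher of the two lowest valleys
       separating the candidate from the nearest taller terrain (or the
       signal edge) must reach ``min_prominence``;
    3. separation: walking survivors from tallest to shortest (equal
       heights: shallowest first), each kept peak discards every other
       survivor closer than ``min_separation_px``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    mids: list[int] = []
    lefts: list[int] = []
    i = 1
    while i < n - 1:
        if x[i - 1] < x[i]:
            j = i
            while j < n - 1 and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                mids.append((i + j) // 2)
                lefts.append(i)
            i = j + 1
        else:
            i += 1

    survivors: list[tuple[int, int]] = []  # (left, mid)
    for left, m in zip(lefts, mids):
        # prominence by definition
        left_min = x[m]
        i = m
        while i > 0 and x[i - 1] <= x[m]:
            i -= 1
            left_min = min(left_min, x[i])
        right_min = x[m]
        i = m
        while i < n - 1 and x[i + 1] <= x[m]:
            i += 1
            right_min = min(right_min, x[i])
        if x[m] - max(left_min, right_min) >= min_prominence:
            survivors.append((left, m))

    order = sorted(range(len(survivors)), key=lambda k: (-x[survivors[k][1]], survivors[k][0]))
    keep = [True] * len(survivors)
    for k in order:
        if not keep[k]:
            continue
        for j in range(len(survivors)):
            if (
                j != k
                and keep[j]
                and abs(survivors[j][0] - survivors[k][0]) < min_separation_px
            ):
                keep[j] = False
    return sorted(left for (left, _), kp in zip(survivors, keep) if kp)


def count_line_classification(labels) -> dict:
    """Integer-counting oracle for per-class percentages."""
    from earoct.labels import PRIMARY_CLASSES, ClassLabel

    n_invalid = sum(1 for lab in labels if lab is ClassLabel.INVALID)
    n_valid = len(labels) - n_invalid
    out = {"n_valid": n_valid, "n_excluded": n_invalid}
    if n_valid:
        for c in PRIMARY_CLASSES:
            out[c] = 100.0 * sum(1 for lab in labels if lab is c) / n_valid
    return out
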