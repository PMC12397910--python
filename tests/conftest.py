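"""Shared fixtures and independent brute-force oracles."""

import numpy as np
import pytest

from g4condense.enrichment import ScaledRankCurve


def brute_force_tangent(curve: ScaledRankCurve) -> int:
    """Independent oracle: plain-python argmin of (y - x), ties to the
    larger index."""
    best_i, best_d = 0, float("inf")
    for i in range(len(curve.x)):
        d = curve.y[i] - curve.x[i]
        if d <= best_d + 1e-15:
            if d < best_d - 1e-15 or i > best_i:
                best_i, best_d = i, min(d, best_d)
    return best_i


def brute_force_qgrs(seq: str, max_len: int = 30, min_tract: int = 2):
    """Independent oracle: quadruple nested loop over tract start positions.

    Returns the set of (start, tract_length, loops) tuples for all four-
    tract motifs with equal tract length, loops >= 0, total <= max_len.
    """
    s = seq.upper().replace("U", "T")
    n = len(s)
    found = set()
    for x in range(min_tract, n // 4 + 1):
        if 4 * x > max_len:
            break
        for s1 in range(n):
            if s[s1:s1 + x] != "G" * x:
                continue
            for s2 in range(s1 + x, n):
                if s[s2:s2 + x] != "G" * x:
                    continue
                for s3 in range(s2 + x, n):
                    if s[s3:s3 + x] != "G" * x:
                        continue
                    for s4 in range(s3 + x, n):
                        if s[s4:s4 + x] != "G" * x:
                            continue
                        if s4 + x - s1 > max_len:
                            break
                        found.add((s1, x, (s2 - s1 - x, s3 - s2 - x,
                                           s4 - s3 - x)))
    return found


def make_curve(y_values) -> ScaledRankCurve:
    """Wrap a non-decreasing array into a scaled rank curve for tests."""
    y = np.asarray(y_values, dtype=float)
    y = (y - y[0]) / (y[-1] - y[0])
    x = np.linspace(0.0, 1.0, y.size)
    return ScaledRankCurve(x=x, y=y, order=list(range(y.size)), raw=y)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
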