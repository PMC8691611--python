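"""Independent scalar-loop oracles for the activity metrics.

Deliberately naive: explicit Python loops and two-pass formulas, no numpy
vectorization, so they share no code path with the package implementation.
"""

from __future__ import annotations

import math


def pim_riemann(epoch, ts):
    total = 0.0
    for v in epoch:
        total += float(v)
    return ts * total


def zcm_loop(epoch, level):
    """Crossing count with explicit previous-side bookkeeping."""
    count = 0
    prev_side = 0  # -1 below, +1 above, 0 unknown (leading on-level run)
    for v in epoch:
        d = float(v) - level
        if d > 0:
            side = 1
        elif d < 0:
            side = -1
        else:
            side = prev_side  # inherit previous strictly-off-level side
        if prev_side != 0 and side != 0 and side != prev_side:
            count += 1
        if side != 0:
            prev_side = side
    return count


def tat_loop(epoch, level, ts):
    n_above = 0
    for v in epoch:
        if float(v) > level:
            n_above += 1
    return ts * n_above


def mad_loop(epoch):
    n = len(epoch)
    mean = sum(float(v) for v in epoch) / n
    return sum(abs(float(v) - mean) for v in epoch) / n


def enmo_loop(epoch):
    n = len(epoch)
    total = 0.0
    for v in epoch:
        d = float(v) - 1.0
        if d > 0:
            total += d
    return total / n


def hfen_loop(epoch):
    return sum(float(v) for v in epoch) / len(epoch)


def _var_two_pass(epoch):
    n = len(epoch)
    mean = sum(float(v) for v in epoch) / n
    return sum((float(v) - mean) ** 2 for v in epoch) / n


def ai_loop(ex, ey, ez, noise_var, variant="linear"):
    core = sum(_var_two_pass(e) - noise_var for e in (ex, ey, ez)) / 3.0
    core = max(core, 0.0)
    return math.sqrt(core) if variant == "sqrt" else core


def pearson_two_pass(a, b):
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    return cov / math.sqrt(va * vb)
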