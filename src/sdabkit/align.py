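"""Approximate substring search (Myers bit-parallel algorithm).

Used to anchor framework segments inside sequencing reads with a small
edit-distance tolerance.  Python's arbitrary-precision integers make the
bit-vector recurrence exact for patterns of any length.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Match:
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    distance: int


def edit_distance(a: str, b: str) -> int:
    """Plain Levenshtein distance (small-input oracle / utility)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _myers_best_end(pattern: str, text: str, max_dist: int) -> tuple[int, int] | None:
    """Best (distance, end) of an occurrence of ``pattern`` in ``text``.

    Semi-global: the occurrence may start anywhere in ``text``.  Returns the
    leftmost end achieving the minimal distance <= max_dist, or None.
    """
    m = len(pattern)
    if m == 0:
        return (0, 0)
    mask = (1 << m) - 1
    high = 1 << (m - 1)
    peq: dict[str, int] = {}
    for i, c in enumerate(pattern):
        peq[c] = peq.get(c, 0) | (1 << i)
    pv = mask
    mv = 0
    score = m
    best: tuple[int, int] | None = None
    for j, c in enumerate(text):
        eq = peq.get(c, 0)
        xv = eq | mv
        xh = ((((eq & pv) + pv) ^ pv) | eq) & mask
        ph = mv | (~(xh | pv) & mask)
        mh = pv & xh
        if ph & high:
            score += 1
        elif mh & high:
            score -= 1
        # search variant: top boundary row is all zeros, so no carry-in on Ph
        ph = (ph << 1) & mask
        mh = (mh << 1) & mask
        pv = mh | (~(xv | ph) & mask)
        mv = ph & xv
        if score <= max_dist and (best is None or score <= best[0]):
            # prefer the rightmost end among minimal-distance candidates:
            # breaks the terminal-substitution vs deletion tie toward the
            # full-length match, keeping anchor boundaries exact
            best = (score, j + 1)
    return best


def approx_search(pattern: str, text: str, max_dist: int) -> Match | None:
    """Find the best approximate occurrence of ``pattern`` in ``text``.

    Returns the leftmost minimal-distance :class:`Match` with edit distance
    <= ``max_dist``, or ``None``.  Exact hits short-circuit via ``str.find``.
    """
    if not pattern:
        return Match(0, 0, 0)
    exact = text.find(pattern)
    if exact >= 0:
        return Match(exact, exact + len(pattern), 0)
    if max_dist <= 0:
        return None
    found = _myers_best_end(pattern, text, max_dist)
    if found is None:
        return None
    dist, end = found
    # Recover the start by searching the reversed pattern in the reversed
    # window ending at `end`.
    window_start = max(0, end - len(pattern) - max_dist)
    window = text[window_start:end][::-1]
    back = _myers_best_end(pattern[::-1], window, dist)
    assert back is not None, "forward hit must be recoverable backwards"
    start = end - back[1]
    return Match(start, end, dist)
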