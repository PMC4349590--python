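"""Independent brute-force oracles used to cross-check the package.

Deliberately naive and separate from the implementation: a recursive
tract/loop string parser, an all-substrings PQS enumerator, a substring-set
longest-common-substring scan, a cumulative-sum N50, and an exhaustive
(frame, ATG, next-stop) ORF enumerator.
"""

from __future__ import annotations

from functools import lru_cache

STOPS = {"TAA", "TAG", "TGA"}


def parses_as_pqs(s: str, base: str = "G", g: int = 3, lmin: int = 1,
                  lmax: int = 7, units: int = 3) -> bool:
    """Can the *whole* string be segmented as tract (loop tract)^(>=units)?"""
    need = units + 1
    n = len(s)
    if n == 0:
        return False

    @lru_cache(maxsize=None)
    def ok(pos: int, done: int) -> bool:
        run = 0
        while pos + run < n and s[pos + run] == base:
            run += 1
        if run < g:
            return False
        for t in range(g, run + 1):
            e = pos + t
            if e == n:
                if done + 1 >= need:
                    return True
                continue
            for l in range(lmin, lmax + 1):
                if e + l < n and ok(e + l, min(done + 1, need)):
                    return True
        return False

    return ok(0, 0)


def brute_force_pqs_intervals(seq: str, base: str = "G", g: int = 3,
                              lmin: int = 1, lmax: int = 7,
                              units: int = 3) -> set[tuple[int, int]]:
    """Every (start, end) whose substring parses; start/end prefilters only
    skip substrings the parser would reject on its first/last character."""
    n = len(seq)
    out = set()
    min_len = (units + 1) * g + units * lmin
    for i in range(n):
        if seq[i : i + g] != base * g:
            continue
        for j in range(i + min_len, n + 1):
            if seq[j - 1] == base and parses_as_pqs(seq[i:j], base, g, lmin, lmax, units):
                out.add((i, j))
    return out


def lcs_by_substring_sets(a: str, b: str) -> int:
    """Longest common substring via explicit substring-set intersection."""
    best = 0
    subs_b = {b[i : j] for i in range(len(b)) for j in range(i + 1, len(b) + 1)}
    for i in range(len(a)):
        for j in range(i + 1, len(a) + 1):
            if j - i > best and a[i:j] in subs_b:
                best = j - i
    return best


def naive_n50(lengths: list[int]) -> int:
    ls = sorted(lengths, reverse=True)
    half = sum(ls) / 2
    cum = 0
    for x in ls:
        cum += x
        if cum >= half:
            return x
    raise AssertionError


def enumerate_longest_orf(seq: str, min_codons: int = 50):
    """Triple loop over (frame, ATG, next in-frame stop); returns the best
    (start, end, frame) by longest, then smallest start, then smallest frame,
    or None."""
    n = len(seq)
    best = None
    for frame in range(3):
        codon_pos = range(frame, n - 2, 3)
        atgs = [i for i in codon_pos if seq[i : i + 3] == "ATG"]
        stops = sorted(i for i in codon_pos if seq[i : i + 3] in STOPS)
        for a in atgs:
            nxt = [t for t in stops if t >= a + 3]
            if not nxt:
                continue
            end = nxt[0] + 3
            if (end - a) // 3 >= min_codons:
                key = (-(end - a), a, frame)
                if best is None or key < best:
                    best = key
    if best is None:
        return None
    return best[1], best[1] - best[0], best[2]
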