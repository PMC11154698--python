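"""Independent naive oracles used to cross-check the implementation.

Deliberately written as plain, slow, dictionary-based dynamic
programming with no shared code with the package's alignment core.
"""

from __future__ import annotations


def naive_local_score(
    s1: str, s2: str, match: int = 1, mismatch: int = 0, gap: int = -1
) -> int:
    """Maximum local alignment score by a direct dictionary DP."""
    best = 0
    H: dict[tuple[int, int], int] = {}
    for i in range(len(s1) + 1):
        for j in range(len(s2) + 1):
            if i == 0 or j == 0:
                H[(i, j)] = 0
                continue
            if s1[i - 1] == s2[j - 1] and s1[i - 1] != "N":
                sub = match
            else:
                sub = mismatch
            H[(i, j)] = max(
                0,
                H[(i - 1, j - 1)] + sub,
                H[(i - 1, j)] + gap,
                H[(i, j - 1)] + gap,
            )
            best = max(best, H[(i, j)])
    return best


def naive_mean_ok(bases: str, quals, min_length: int, min_q: float, errprob: bool) -> bool:
    """One-line re-statement of the quality-filter predicate."""
    if len(bases) < min_length:
        return False
    if errprob:
        import math

        mean_p = sum(10 ** (-q / 10) for q in quals) / len(quals)
        eff = -10 * math.log10(mean_p)
    else:
        eff = sum(int(q) for q in quals) / len(quals)
    return eff >= min_q
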