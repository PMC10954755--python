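"""Independent oracle implementations used to cross-check the package.

Each oracle is deliberately written from the definition (brute force,
enumeration, closed form) and shares no code with the implementation it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata

STOPS = ("UAA", "UAG", "UGA")


def brute_force_extension(sequence: str, stop_offset: int) -> tuple[int, int, bool]:
    """Scan codon-by-codon after the stop; return (start, end, found_stop)."""
    start = stop_offset + 3
    pos = start
    while pos + 3 <= len(sequence):
        codon = sequence[pos], sequence[pos + 1], sequence[pos + 2]
        if "".join(codon) in STOPS:
            return start, pos, True
        pos += 3
    return start, pos, False


def allpairs_auroc(scores, labels, positive="high") -> float:
    """AUROC as explicit all-pairs concordance with half-credit ties."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def enumerate_ranksum_p(x, y) -> float:
    """Exact two-tailed rank-sum p by enumerating all rank assignments."""
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    m = len(x)
    ranks = rankdata(pooled)
    w_obs = ranks[:m].sum()
    ws = np.array([sum(c) for c in itertools.combinations(ranks, m)])
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


def enumerate_structures_mfe(seq: str, pair_e, stack_e: float,
                             min_hairpin: int = 3) -> float:
    """Optimal energy over all CLOSED nested structures of a short RNA.

    A structure is a set of non-crossing pairs with one exterior pair
    enclosing all others (a single fold).  Energy: sum of pair energies
    plus a stacking bonus whenever pair (i+1, j-1) sits directly inside
    (i, j).  Returns the lowest structure energy, 0 if nothing folds.
    """
    codes = ["ACGU".index(c) for c in seq]
    n = len(seq)
    candidates = [
        (i, j) for i in range(n) for j in range(i + min_hairpin + 1, n)
        if pair_e[codes[i], codes[j]] <= 0
    ]
    best = 0.0

    def energy(chosen: list) -> float:
        chosen_set = set(chosen)
        total = 0.0
        for (i, j) in chosen:
            total += pair_e[codes[i], codes[j]]
            if (i + 1, j - 1) in chosen_set:
                total += stack_e
        return total

    def is_closed(chosen: list) -> bool:
        lo = min(i for i, _ in chosen)
        hi = max(j for _, j in chosen)
        return (lo, hi) in chosen

    def extend(chosen: list, cand: list) -> None:
        nonlocal best
        if chosen and is_closed(chosen):
            e = energy(chosen)
            if e < best:
                best = e
        for idx, (i, j) in enumerate(cand):
            rem = [
                (a, b) for (a, b) in cand[idx + 1:]
                if len({a, b} & {i, j}) == 0
                and not (a < i < b < j) and not (i < a < j < b)
            ]
            extend(chosen + [(i, j)], rem)

    extend([], candidates)
    return best


def random_record(rng: np.random.Generator, max_utr3_codons: int = 40):
    """A random valid transcript for round-trip / scan tests."""
    from readthru.catalog import MrnaRecord

    bases = "ACGU"
    utr5 = "".join(rng.choice(list(bases), size=int(rng.integers(0, 30))))
    n_codons = int(rng.integers(1, 40))
    sense = [c for c in _sense_codons()]
    cds = "".join(sense[i] for i in rng.integers(0, len(sense), size=n_codons))
    stop = STOPS[int(rng.integers(0, 3))]
    tail_len = int(rng.integers(0, 3 * max_utr3_codons))
    tail = "".join(rng.choice(list(bases), size=tail_len))
    seq = utr5 + cds + stop + tail
    return MrnaRecord(
        transcript_id=f"R{rng.integers(0, 10**9):09d}",
        sequence=seq,
        utr5_len=len(utr5),
        cds_len=len(cds),
        utr3_len=3 + tail_len,
    )


def _sense_codons():
    from readthru.genetics import SENSE_CODONS

    return SENSE_CODONS
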