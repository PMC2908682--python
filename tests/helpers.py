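"""Independent oracles used to cross-check the aligner and the partitioner.

The scoring oracle enumerates every legal loop placement and prices each one
directly from the pairing rules, sharing no code with the package's aligner.
The partition oracle enumerates every set partition of a family and reports
the smallest number of feasible parts.
"""

from __future__ import annotations

from mimdesign.duplex import ScoringParams

WC = {("A", "T"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "T"), ("U", "G")}


def pair_penalty(mirna_base: str, site_base: str, p: ScoringParams) -> float:
    if (mirna_base, site_base) in WC:
        return 0.0
    if (mirna_base, site_base) in WOBBLE:
        return p.wobble_penalty
    return p.mismatch_penalty


def oracle_placement_score(
    mirna: str, site: str, gap: int, skip: int, p: ScoringParams
) -> float:
    """Score of the alignment whose loop sits after miRNA position ``gap``."""
    L, S = len(mirna), len(site)
    b = S - L + skip
    core_lo, core_hi = p.core_region
    core_hi = min(core_hi, L)

    def weight(i: int) -> float:
        return p.core_weight if core_lo <= i <= core_hi else 1.0

    total = 0.0
    for i in range(1, gap + 1):
        total += pair_penalty(mirna[i - 1], site[S - i], p) * weight(i)
    left, right = gap, gap + skip + 1
    for k in range(b):
        if left >= 1 and right <= L:
            eff = left if k < (b + 1) // 2 else right
        elif left >= 1:
            eff = left
        else:
            eff = right
        total += p.bulge_penalty_per_nt * weight(eff)
    for i in range(gap + skip + 1, L + 1):
        sp = S - b - i + skip + 1
        total += pair_penalty(mirna[i - 1], site[sp - 1], p) * weight(i)
    return total


def oracle_min_score(mirna: str, site: str, p: ScoringParams) -> float:
    """Exhaustive minimum over every legal loop placement."""
    L, S = len(mirna), len(site)
    assert L <= S <= L + p.max_site_bulge
    if S == L:
        return oracle_placement_score(mirna, site, 0, 0, p)
    best = None
    for skip in range(0, p.max_unpaired_mirna + 1):
        if S - L + skip > p.max_site_bulge:
            break
        for gap in range(0, L - skip + 1):
            score = oracle_placement_score(mirna, site, gap, skip, p)
            if best is None or score < best:
                best = score
    assert best is not None
    return best


def set_partitions(items: list):
    """All partitions of ``items`` into unordered nonempty parts."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def optimal_partition_size(members, feasible) -> int:
    """Smallest number of parts over all partitions whose parts all pass
    ``feasible`` (memoised on the member-id frozenset)."""
    cache: dict[frozenset, bool] = {}

    def ok(part) -> bool:
        key = frozenset(m.id for m in part)
        if key not in cache:
            cache[key] = feasible(part)
        return cache[key]

    best = len(members)
    for partition in set_partitions(list(members)):
        if len(partition) < best and all(ok(part) for part in partition):
            best = len(partition)
    return best
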