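"""Independent brute-force transcription of the ACMG/AMP combining table.

Kept deliberately separate from the package: the table below is written as
literal rule rows (one per published combination), evaluated by scanning,
so that the package's count-based combiner can be checked against an
independently derived answer for every evidence multiset.
"""

from itertools import product

from usherspect.acmg import DEFAULT_STRENGTHS, Evidence, EvidenceSet

# each row: (required very-strong, strong, moderate, supporting) minima with
# exact-match semantics where the published table is exact
_PATHOGENIC_ROWS = [
    # (i) one very strong AND ...
    lambda vs, s, m, p: vs >= 1 and s >= 1,
    lambda vs, s, m, p: vs >= 1 and m >= 2,
    lambda vs, s, m, p: vs >= 1 and m == 1 and p >= 1,
    lambda vs, s, m, p: vs >= 1 and p >= 2,
    lambda vs, s, m, p: vs >= 2,
    # (ii) two strong
    lambda vs, s, m, p: s >= 2,
    # (iii) one strong AND ...
    lambda vs, s, m, p: s == 1 and m >= 3,
    lambda vs, s, m, p: s == 1 and m == 2 and p >= 2,
    lambda vs, s, m, p: s == 1 and m == 1 and p >= 4,
]
_LIKELY_PATHOGENIC_ROWS = [
    lambda vs, s, m, p: vs == 1 and m == 1,
    lambda vs, s, m, p: s == 1 and m in (1, 2),
    lambda vs, s, m, p: s == 1 and p >= 2,
    lambda vs, s, m, p: m >= 3,
    lambda vs, s, m, p: m == 2 and p >= 2,
    lambda vs, s, m, p: m == 1 and p >= 4,
]
_BENIGN_ROWS = [
    lambda ba, bs, bp: ba >= 1,
    lambda ba, bs, bp: bs >= 2,
]
_LIKELY_BENIGN_ROWS = [
    lambda ba, bs, bp: bs == 1 and bp >= 1,
    lambda ba, bs, bp: bp >= 2,
]


def oracle_class(vs: int, s: int, m: int, p: int, ba: int, bs: int, bp: int) -> str:
    """Five-class verdict for strength counts, by scanning the literal table."""
    pathogenic_present = (vs + s + m + p) > 0
    benign_present = (ba + bs + bp) > 0
    if pathogenic_present and benign_present:
        return "VUS"
    if any(rule(vs, s, m, p) for rule in _PATHOGENIC_ROWS):
        return "P"
    if any(rule(vs, s, m, p) for rule in _LIKELY_PATHOGENIC_ROWS):
        return "LP"
    if any(rule(ba, bs, bp) for rule in _BENIGN_ROWS):
        return "B"
    if any(rule(ba, bs, bp) for rule in _LIKELY_BENIGN_ROWS):
        return "LB"
    return "VUS"


# representative codes per strength bucket (combination verdicts depend only
# on strengths; determinism across code identities is tested separately)
_REPRESENTATIVES = {
    "very_strong": ["PVS1"],
    "strong": ["PS1", "PS2", "PS3", "PS4"],
    "moderate": ["PM1", "PM2", "PM3", "PM4", "PM5", "PM6"],
    "supporting": ["PP1", "PP2", "PP3", "PP4", "PP5"],
    "stand_alone": ["BA1"],
    "benign_strong": ["BS1", "BS2", "BS3", "BS4"],
    "benign_supporting": ["BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7"],
}


def enumerate_count_vectors(max_total: int = 6):
    """All achievable strength-count vectors for multisets of <= max_total
    distinct evidence codes (each code may appear at most once)."""
    limits = {k: len(v) for k, v in _REPRESENTATIVES.items()}
    names = list(_REPRESENTATIVES)
    ranges = [range(min(limits[n], max_total) + 1) for n in names]
    for counts in product(*ranges):
        if sum(counts) <= max_total:
            yield dict(zip(names, counts))


def build_evidence_set(counts: dict) -> EvidenceSet:
    ev = EvidenceSet()
    for bucket, n in counts.items():
        for code in _REPRESENTATIVES[bucket][:n]:
            ev.add(Evidence(code, DEFAULT_STRENGTHS[code]))
    return ev
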