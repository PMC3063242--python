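"""Independent brute-force rule checker used as a test oracle.

Written directly from the textual description of the site rules, with no
imports from the package under test: its own complement table, its own
consensus table, and a straight-line check per rule.  Deliberately slow
and simple.
"""

COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}

# Allowed bases, positions -13..-1 then 1..13 of the consensus:
# wild-type FRT elements, with A/G tolerated at +1 (so C/T at -1) and
# A/T at -2/+2.
ORACLE_ALLOWED = {
    -13: "G", -12: "A", -11: "A", -10: "G", -9: "T", -8: "T", -7: "C",
    -6: "C", -5: "T", -4: "A", -3: "T", -2: "AT", -1: "CT",
    1: "AG", 2: "AT", 3: "A", 4: "T", 5: "A", 6: "G", 7: "G",
    8: "A", 9: "A", 10: "C", 11: "T", 12: "T", 13: "C",
}


def oracle_revcomp(seq):
    return "".join(COMP[b] for b in reversed(seq))


def oracle_base(seq34, pos):
    """Base at element position pos of a 34-mer (left 13 | spacer 8 | right 13)."""
    if pos < 0:
        return seq34[13 + pos]
    return seq34[20 + pos]


def oracle_accepts(seq34):
    """Full rule cascade, re-derived from scratch."""
    seq34 = seq34.upper()
    if len(seq34) != 34 or any(b not in "ACGT" for b in seq34):
        return False
    spacer = seq34[13:21]
    if spacer[0] != "T" or spacer[-1] != "A":
        return False
    if sum(1 for b in spacer if b in "GC") > 4:
        return False
    # homopolymer: any run of 5 identical bases anywhere
    for i in range(len(seq34) - 4):
        if len(set(seq34[i:i + 5])) == 1:
            return False
    matched = {p: oracle_base(seq34, p) in ORACLE_ALLOWED[p] for p in ORACLE_ALLOWED}
    # proximal-8 rules
    prox = [-4, -3, -2, -1, 1, 2, 3, 4]
    if sum(matched[p] for p in prox) < 5:
        return False
    for seg in ([-4, -3, -2, -1], [1, 2, 3, 4]):
        for a, b in zip(seg, seg[1:]):
            if not matched[a] and not matched[b]:
                return False
    if not matched[-1] and not matched[1]:
        return False
    if oracle_base(seq34, -1) == "G" or oracle_base(seq34, 1) == "C":
        return False
    # element rules
    if not (matched[-7] or matched[7]):
        return False
    left = [matched[p] for p in range(-13, 0)]
    right = [matched[p] for p in range(1, 14)]
    if sum(left) < 5 and sum(right) < 5:
        return False

    def longest(bools):
        best = run = 0
        for b in bools:
            run = run + 1 if b else 0
            best = max(best, run)
        return best

    if max(longest(left), longest(right)) < 6:
        return False
    return True


def oracle_class(seq34):
    """Number of proximal-8 matches (call only on accepted windows)."""
    seq34 = seq34.upper()
    return sum(
        oracle_base(seq34, p) in ORACLE_ALLOWED[p]
        for p in (-4, -3, -2, -1, 1, 2, 3, 4)
    )


def oracle_scan(seq):
    """Accepted window offsets of a sequence, by exhaustive sliding."""
    seq = seq.upper()
    return [o for o in range(len(seq) - 33) if oracle_accepts(seq[o:o + 34])]


DIGIT = {"A": "1", "T": "2", "G": "3", "C": "4"}


def oracle_code(left4, right4):
    return int("".join(DIGIT[b] for b in left4 + right4))


def oracle_canonical_code(seq34):
    """Min of the proximal-8 codes of the site and its reverse complement."""
    fwd = oracle_code(seq34[9:13], seq34[21:25])
    rc = oracle_revcomp(seq34)
    rev = oracle_code(rc[9:13], rc[21:25])
    return min(fwd, rev)


def oracle_enumerate(k):
    """Theoretical class-k subclass count by direct filtering of all
    4^8 proximal-8 sequences."""
    from itertools import product

    prox_allowed = {p: ORACLE_ALLOWED[p] for p in (-4, -3, -2, -1, 1, 2, 3, 4)}
    order = (-4, -3, -2, -1, 1, 2, 3, 4)
    seen = set()
    for combo in product("ACGT", repeat=8):
        m = {p: combo[i] in prox_allowed[p] for i, p in enumerate(order)}
        if sum(m.values()) != k:
            continue
        bad = False
        for seg in ([-4, -3, -2, -1], [1, 2, 3, 4]):
            for a, b in zip(seg, seg[1:]):
                if not m[a] and not m[b]:
                    bad = True
        if bad or (not m[-1] and not m[1]):
            continue
        if combo[3] == "G" or combo[4] == "C":
            continue
        left4, right4 = "".join(combo[:4]), "".join(combo[4:])
        flipped = oracle_revcomp(right4) + oracle_revcomp(left4)
        code = min(oracle_code(left4, right4),
                   oracle_code(flipped[:4], flipped[4:]))
        seen.add(code)
    return sorted(seen)
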