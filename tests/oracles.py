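"""Independent brute-force oracles used by the test suite.

Everything here is deliberately self-contained: no imports from the
package under test, and the genetic code is written out by hand, so
agreement between these implementations and the pipeline is meaningful.
"""

from itertools import permutations

_B = "TCAG"
# mold/protozoan mitochondrial code: standard code with TGA -> Trp
_AA = "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODE4 = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_B)
    for j, b in enumerate(_B)
    for k, c in enumerate(_B)
}
STOPS4 = {c for c, aa in CODE4.items() if aa == "*"}


def brute_sites(codon):
    """NG86 site counts by direct neighbor enumeration."""
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOPS4:
                continue
            tot += 1
            syn += CODE4[mut] == CODE4[codon]
        s += syn / tot if tot else 0.0
    return s, 3.0 - s


def brute_differences(ca, cb):
    """Pathway-averaged difference counts, stop-crossing pathways excluded."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    ok = []
    for order in permutations(diff):
        cur = ca
        sd = nd = 0
        valid = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOPS4:
                valid = False
                break
            if CODE4[cur] == CODE4[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if valid:
            ok.append((sd, nd))
    if not ok:
        for order in permutations(diff):
            cur = ca
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                same = cur not in STOPS4 and nxt not in STOPS4 and CODE4[cur] == CODE4[nxt]
                sd += same
                nd += not same
                cur = nxt
            ok.append((sd, nd))
    return (
        sum(x for x, _ in ok) / len(ok),
        sum(y for _, y in ok) / len(ok),
    )


def brute_kaks(columns):
    """Full NG86 Ka/Ks from a list of (codon_a, codon_b) columns."""
    import math

    sa = na = sb = nb = 0.0
    sd = nd = 0.0
    for ca, cb in columns:
        s1, n1 = brute_sites(ca)
        s2, n2 = brute_sites(cb)
        sa += s1
        na += n1
        sb += s2
        nb += n2
        d_s, d_n = brute_differences(ca, cb)
        sd += d_s
        nd += d_n
    s_sites = (sa + sb) / 2
    n_sites = (na + nb) / 2
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0

    def jc(p):
        if p == 0.0:
            return 0.0
        arg = 1 - 4 * p / 3
        return None if arg <= 0 else -0.75 * math.log(arg)

    return {
        "S": s_sites, "N": n_sites, "Sd": sd, "Nd": nd,
        "Ks": jc(ps), "Ka": jc(pn),
    }


def brute_k2p(a, b):
    """K2P by direct counting over canonical-base columns."""
    import math

    pairs = [
        (x, y)
        for x, y in zip(a.upper(), b.upper())
        if x in "ACGT" and y in "ACGT"
    ]
    n = len(pairs)
    ts = sum(1 for x, y in pairs if x != y and {x, y} in ({"A", "G"}, {"C", "T"}))
    tv = sum(1 for x, y in pairs if x != y and {x, y} not in ({"A", "G"}, {"C", "T"}))
    p, q = ts / n, tv / n
    arg = (1 - 2 * p - q) * math.sqrt(1 - 2 * q)
    return None if arg <= 0 else -0.5 * math.log(arg)


def brute_adjacencies(order):
    """Signed circular adjacency set with reflection-invariant keys."""

    def flip(s):
        return "-" if s == "+" else "+"

    n = len(order)
    out = set()
    for k in range(n):
        (a, sa), (b, sb) = order[k], order[(k + 1) % n]
        out.add(min((a, sa, b, sb), (b, flip(sb), a, flip(sa))))
    return out


def brute_breakpoints(order_a, order_b):
    return len(brute_adjacencies(order_a) - brute_adjacencies(order_b))


def brute_union_pct(intervals, length):
    """Covered percent by per-base marking (no interval arithmetic)."""
    covered = [False] * length
    for s, e in intervals:
        for i in range(s - 1, e):
            covered[i] = True
    return 100.0 * sum(covered) / length
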