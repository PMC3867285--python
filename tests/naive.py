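"""Independent naive re-implementations of every scorer, used as oracles.

Everything here is written with direct loops and plain dicts, sharing no
code with the package under test (the BLOSUM62 table is read straight
from Biopython). Tree partitions are taken as explicit inputs so the tree
itself is held fixed while the scorers are checked.
"""

import math

from Bio.Align import substitution_matrices

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def freqs(symbols):
    counts = {}
    for c in symbols:
        if c in AA20:
            counts[c] = counts.get(c, 0) + 1
    n = sum(counts.values())
    return {a: k / n for a, k in counts.items()}, n


def naive_entropy(symbols):
    f, n = freqs(symbols)
    assert n > 0
    return -sum(p * math.log(p) for p in f.values())


def naive_majority(symbols):
    f, n = freqs(symbols)
    return max(f.values()) if n else 0.0


def _blosum_rescaled():
    m = substitution_matrices.load("BLOSUM62")
    vals = [m[a, b] for a in AA20 for b in AA20]
    lo, hi = min(vals), max(vals)
    return {(a, b): (m[a, b] - lo) / (hi - lo) for a in AA20 for b in AA20}


def naive_valdar_weights(ids, seqs):
    n = len(ids)
    w = {}
    for j in range(n):
        total = 0.0
        for k in range(n):
            if k == j:
                continue
            both = [(a, b) for a, b in zip(seqs[j], seqs[k])
                    if a != "-" and b != "-"]
            ident = (sum(1 for a, b in both if a == b) / len(both)
                     if both else 0.0)
            total += 1.0 - ident
        w[ids[j]] = total / (n - 1) + 1e-6
    mean = sum(w.values()) / n
    return {i: v / mean for i, v in w.items()}


def naive_valdar(ids, seqs, col):
    sim = _blosum_rescaled()
    w = naive_valdar_weights(ids, seqs)
    contrib = [(w[i], s[col - 1]) for i, s in zip(ids, seqs)
               if s[col - 1] in AA20]
    if len(contrib) < 2:
        return 0.0
    num = den = 0.0
    for j in range(len(contrib)):
        for k in range(j + 1, len(contrib)):
            ww = contrib[j][0] * contrib[k][0]
            num += ww * sim[(contrib[j][1], contrib[k][1])]
            den += ww
    return num / den


def naive_rvet(ids, seqs, col, cuts):
    """cuts[n] is the partition into n groups (lists of ids), n = 1..N-1."""
    by_id = dict(zip(ids, seqs))
    total = 1.0
    for n in range(1, len(ids)):
        level = 0.0
        for group in cuts[n]:
            symbols = [by_id[i][col - 1] for i in group]
            if any(c in AA20 for c in symbols):
                level += naive_entropy([c for c in symbols if c in AA20])
        total += level / n
    return total


def naive_ivet(ids, seqs, col, cuts):
    by_id = dict(zip(ids, seqs))
    N = len(ids)
    for n in range(1, N + 1):
        ok = True
        for group in cuts[n]:
            types = {by_id[i][col - 1] for i in group} & set(AA20)
            if len(types) > 1:
                ok = False
                break
        if ok:
            return n
    return N


def naive_overlap(symbols_a, symbols_b):
    fa, _ = freqs(symbols_a)
    fb, _ = freqs(symbols_b)
    return sum(min(fa.get(a, 0.0), fb.get(a, 0.0)) for a in AA20)


def naive_discriminant(group_symbols):
    """Plain variant: per-group d_g = c_g (1 - max_h o_gh); pooled max."""
    k = len(group_symbols)
    d = []
    for g in range(k):
        worst = max(naive_overlap(group_symbols[g], group_symbols[h])
                    for h in range(k) if h != g)
        d.append(naive_majority(group_symbols[g]) * (1.0 - worst))
    return d, max(d)


def naive_determinant(group_symbols):
    k = len(group_symbols)
    worst = max(naive_overlap(group_symbols[g], group_symbols[h])
                for g in range(k) for h in range(g + 1, k))
    c_min = min(naive_majority(s) for s in group_symbols)
    return c_min * (1.0 - worst)
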