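"""Independent brute-force oracles the implementation is checked against.

These deliberately share no code with the package: plain Python loops and
string comparison only.
"""

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq):
    return "".join(_COMP[c] for c in reversed(seq))


def naive_hamming(a, b):
    """Hamming distance; an N in either string never matches."""
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def naive_primer_sites(target, primer, max_mm):
    """All (pos, strand, mismatches) matches, both strands, position-sorted."""
    hits = []
    rc = naive_revcomp(primer)
    n, k = len(target), len(primer)
    for pos in range(n - k + 1):
        window = target[pos : pos + k]
        mm = naive_hamming(window, primer)
        if mm <= max_mm:
            hits.append((pos, "+", mm))
        mm = naive_hamming(window, rc)
        if mm <= max_mm:
            hits.append((pos, "-", mm))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def brute_force_validation_pair(template, win_start, win_end, min_prod, max_prod,
                                weights=(1.0, 2.0, 0.5, 2.0)):
    """Exhaustive enumeration of all feasible validation primer pairs.

    Returns (penalty, f_start, product_len, f_len, r_start) of the optimum,
    or None. Uses the same published Tm routine as the package (the Tm model
    itself is not under test here, the optimizer is) but enumerates and
    scores independently.
    """
    from Bio.SeqUtils import MeltingTemp as mt

    def tm(seq):
        return float(mt.Tm_NN(seq, Na=50, dnac1=250, dnac2=0))

    def gc(seq):
        return 100.0 * sum(c in "GC" for c in seq) / len(seq)

    def candidates(lo, hi, forward):
        out = []
        for length in range(20, 29):
            for start in range(lo, hi - length + 1):
                window = template[start : start + length]
                if set(window) - set("ACGT"):
                    continue
                seq = window if forward else naive_revcomp(window)
                if seq[-1] not in "GC":
                    continue
                g = gc(seq)
                if not 30 <= g <= 70:
                    continue
                t = tm(seq)
                if not 60 <= t <= 65:
                    continue
                out.append((start, length, seq, t, g))
        return out

    w1, w2, w3, w4 = weights
    best = None
    for fs, fl, fseq, ftm, fgc in candidates(0, win_start, True):
        for rs, rl, rseq, rtm, rgc in candidates(win_end, len(template), False):
            prod = rs + rl - fs
            if not min_prod <= prod <= max_prod:
                continue
            pen = (w1 * (abs(fl - 23) + abs(rl - 23))
                   + w2 * (abs(ftm - 63) + abs(rtm - 63))
                   + w3 * (abs(fgc - 50) + abs(rgc - 50))
                   + w4 * abs(ftm - rtm))
            key = (pen, fs, prod, fl, rs)
            if best is None or key < best:
                best = key
    return best
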