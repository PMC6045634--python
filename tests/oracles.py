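"""Independent brute-force oracles.

Everything here is written as plain loops over codon strings, deliberately
separate from the package's vectorised code paths, so tests can compare the
two routes.  Oracles take the genetic-code family structure as data but
share no computation with the implementation.
"""

import math


def tally_codons(orfs):
    """Pooled codon counts over a list of DNA strings (upper/U->T applied)."""
    counts = {}
    for orf in orfs:
        seq = orf.upper().replace("U", "T")
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            counts[codon] = counts.get(codon, 0) + 1
    return counts


def per_thousand(counts):
    total = sum(counts.values())
    return {c: 1000.0 * n / total for c, n in counts.items()}


def family_scan(freq, families):
    """Per-amino-acid (max, min, mean) of frequencies, by direct scan."""
    out = {}
    for aa, fam in families.items():
        vals = [freq[c] for c in fam]
        out[aa] = (max(vals), min(vals), sum(vals) / len(vals))
    return out


def naive_w(freq, families):
    w = {}
    for aa, fam in families.items():
        fmax = max(freq[c] for c in fam)
        for c in fam:
            w[c] = freq[c] / fmax
    return w


def codons_of(cds):
    seq = cds.upper().replace("U", "T")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def naive_minmax(cds, freq, families, window):
    """Window-by-window %MinMax, one loop per window, no vectorisation."""
    aa_of = {c: aa for aa, fam in families.items() for c in fam}
    stats = family_scan(freq, families)
    cods = codons_of(cds)
    values = []
    for start in range(len(cods) - window + 1):
        win = cods[start : start + window]
        a = sum(freq[c] for c in win) / window
        mx = sum(stats[aa_of[c]][0] for c in win) / window
        mn = sum(stats[aa_of[c]][1] for c in win) / window
        av = sum(stats[aa_of[c]][2] for c in win) / window
        if mx == av:  # all-singleton window
            values.append(0.0)
        elif a >= av:
            values.append(100.0 * (a - av) / (mx - av))
        else:
            values.append(-100.0 * (av - a) / (av - mn))
    return values


def naive_mean_abs_diff(x, y):
    assert len(x) == len(y)
    return sum(abs(a - b) for a, b in zip(x, y)) / len(x)


def naive_pearson_r(x, y):
    """Direct product-moment formula, plain loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def naive_cai(cds, w):
    cods = codons_of(cds)
    return math.exp(sum(math.log(w[c]) for c in cods) / len(cods))


def naive_pa(tp, tn, fp, fn):
    return (tn + tp) / (tn + fp + fn + tp)


def naive_mcc(tp, tn, fp, fn):
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def naive_modal_class(window_states, order="HEC"):
    counts = {c: window_states.count(c) for c in order}
    best = max(counts.values())
    for c in order:
        if counts[c] == best:
            return c
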