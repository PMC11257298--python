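"""Independent brute-force oracles for the feature encoders and metrics.

Every function here recomputes a quantity from its direct definition with
plain Python loops, sharing only the pinned residue tables (which *are*
the definitions) with the package — no encoder code paths.
"""

from __future__ import annotations

import math

from encap.tables import (
    AMINO_ACIDS,
    CODON_COUNTS,
    CTD_PROPERTIES,
    CTRIAD_GROUPS,
    GAAC_GROUPS,
    OVPC_CLASSES,
    SEP_PARTITIONS,
)
from encap.tables.scales_builtin import (
    APAAC_HYDROPHILICITY,
    APAAC_HYDROPHOBICITY,
    BOMAN_SCALE,
)
from encap.tables.scales_synthetic import SCALE_TABLES

AA = AMINO_ACIDS
GROUPS = list(GAAC_GROUPS)


def aac(seq):
    return [seq.count(a) / len(seq) for a in AA]


def dpc(seq):
    out = []
    pairs = [seq[i : i + 2] for i in range(len(seq) - 1)]
    for a in AA:
        for b in AA:
            out.append(pairs.count(a + b) / len(pairs))
    return out


def gaac(seq):
    return [sum(c in GAAC_GROUPS[g] for c in seq) / len(seq) for g in GROUPS]


def gdpc(seq):
    def grp(c):
        return next(g for g in GROUPS if c in GAAC_GROUPS[g])

    pairs = [(grp(seq[i]), grp(seq[i + 1])) for i in range(len(seq) - 1)]
    return [pairs.count((g1, g2)) / len(pairs) for g1 in GROUPS for g2 in GROUPS]


def cksaap(seq, gap):
    windows = [
        (seq[i], seq[i + gap + 1]) for i in range(len(seq) - gap - 1)
    ]
    return [windows.count((a, b)) / len(windows) for a in AA for b in AA]


def cksaagp(seq, gap):
    def grp(c):
        return next(g for g in GROUPS if c in GAAC_GROUPS[g])

    windows = [
        (grp(seq[i]), grp(seq[i + gap + 1])) for i in range(len(seq) - gap - 1)
    ]
    return [windows.count((g1, g2)) / len(windows) for g1 in GROUPS for g2 in GROUPS]


def ctriad(seq):
    def grp(c):
        return next(i for i, g in enumerate(CTRIAD_GROUPS) if c in g)

    triads = [
        (grp(seq[i]), grp(seq[i + 1]), grp(seq[i + 2]))
        for i in range(len(seq) - 2)
    ]
    out = []
    for a in range(7):
        for b in range(7):
            for c in range(7):
                out.append(triads.count((a, b, c)) / len(triads))
    return out


def dde(seq):
    n = len(seq) - 1
    pairs = [seq[i : i + 2] for i in range(n)]
    out = []
    for a in AA:
        for b in AA:
            dc = pairs.count(a + b) / n
            tm = (CODON_COUNTS[a] / 61) * (CODON_COUNTS[b] / 61)
            tv = tm * (1 - tm) / n
            out.append((dc - tm) / math.sqrt(tv))
    return out


def ctdc(seq):
    out = []
    for groups in CTD_PROPERTIES.values():
        for grp in groups:
            out.append(sum(c in grp for c in seq) / len(seq))
    return out


def ctdt(seq):
    out = []
    for groups in CTD_PROPERTIES.values():
        def cls(c):
            return next(i for i, g in enumerate(groups) if c in g)

        pairs = [(cls(seq[i]), cls(seq[i + 1])) for i in range(len(seq) - 1)]
        for lo, hi in ((0, 1), (0, 2), (1, 2)):
            out.append(
                sum(p in ((lo, hi), (hi, lo)) for p in pairs) / len(pairs)
            )
    return out


def ctdd(seq):
    out = []
    for groups in CTD_PROPERTIES.values():
        for grp in groups:
            pos = [i + 1 for i, c in enumerate(seq) if c in grp]
            if not pos:
                out.extend([0.0] * 5)
                continue
            for q in (0.0, 0.25, 0.5, 0.75, 1.0):
                k = max(1, math.ceil(q * len(pos)))
                out.append(100.0 * pos[k - 1] / len(seq))
    return out


def _standardize(scale):
    vals = [scale[a] for a in AA]
    mean = sum(vals) / 20
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 20)
    return {a: (scale[a] - mean) / sd for a in AA}


def apaac(seq, lam, weight=0.05):
    h1 = _standardize(APAAC_HYDROPHOBICITY)
    h2 = _standardize(APAAC_HYDROPHILICITY)
    taus = []
    for j in range(1, lam + 1):
        taus.append(
            sum(h1[seq[i]] * h1[seq[i + j]] for i in range(len(seq) - j))
            / (len(seq) - j)
        )
        taus.append(
            sum(h2[seq[i]] * h2[seq[i + j]] for i in range(len(seq) - j))
            / (len(seq) - j)
        )
    denom = len(seq) + weight * sum(taus)
    return [seq.count(a) / denom for a in AA] + [weight * t / denom for t in taus]


def qso(seq, nlag, weight=0.1):
    from encap.tables import grantham_distance_matrix
    from encap.tables.scales_synthetic import sequence_order_distance_matrix

    idx = {a: i for i, a in enumerate(AA)}
    out = []
    for dist in (sequence_order_distance_matrix(), grantham_distance_matrix()):
        taus = []
        for d in range(1, nlag + 1):
            total = 0.0
            for i in range(len(seq) - d):
                total += dist[idx[seq[i]], idx[seq[i + d]]] ** 2
            taus.append(total)
        denom = len(seq) + weight * sum(taus)
        out += [seq.count(a) / denom for a in AA]
        out += [weight * t / denom for t in taus]
    return out


def ddr(seq):
    out = []
    for a in AA:
        pos = [i for i, c in enumerate(seq) if c == a]
        if len(pos) < 2:
            out.append(0.0)
        else:
            gaps = [pos[i + 1] - pos[i] for i in range(len(pos) - 1)]
            out.append(sum(gaps) / len(gaps) / len(seq))
    return out


def rri(seq):
    best = 1
    for i in range(len(seq)):
        run = 1
        while i + run < len(seq) and seq[i + run] == seq[i]:
            run += 1
        best = max(best, run)
    return [best / len(seq)]


def _entropy(counts):
    total = sum(counts)
    return -sum(
        (c / total) * math.log2(c / total) for c in counts if c > 0
    )


def ser(seq):
    return [_entropy([seq.count(a) for a in AA])]


def sep(seq):
    out = []
    for groups in SEP_PARTITIONS.values():
        out.append(_entropy([sum(c in g for c in seq) for g in groups]))
    return out


def aliphatic_index(seq):
    L = len(seq)
    xa = 100 * seq.count("A") / L
    xv = 100 * seq.count("V") / L
    xil = 100 * (seq.count("I") + seq.count("L")) / L
    return xa + 2.9 * xv + 3.9 * xil


def boman(seq):
    return -sum(BOMAN_SCALE[c] for c in seq) / len(seq)


def ovpc(seq, cls):
    members = OVPC_CLASSES[cls]
    return sum(c in members for c in seq) / len(seq)


def _quantile(sorted_vals, q):
    # linear interpolation between order statistics
    n = len(sorted_vals)
    h = (n - 1) * q
    lo = int(math.floor(h))
    hi = min(lo + 1, n - 1)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


def scale_descriptor(seq, scale_name, stats):
    table = SCALE_TABLES[scale_name]
    dims = len(table[AA[0]])
    out = []
    for d in range(dims):
        prof = [table[c][d] for c in seq]
        mean = sum(prof) / len(prof)
        var = sum((v - mean) ** 2 for v in prof) / len(prof)
        srt = sorted(prof)
        vals = [
            mean,
            math.sqrt(var),
            min(prof),
            max(prof),
            _quantile(srt, 0.5),
            _quantile(srt, 0.25),
            _quantile(srt, 0.75),
            prof[0],
            prof[-1],
            max(prof) - min(prof),
        ]
        if stats == 15:
            win3 = [
                sum(prof[i : i + 3]) / 3 for i in range(len(prof) - 2)
            ]
            vals += [
                sum(prof[:3]) / 3,
                sum(prof[-3:]) / 3,
                max(win3),
                min(win3),
                sum(abs(prof[i + 1] - prof[i]) for i in range(len(prof) - 1))
                / (len(prof) - 1),
            ]
        out.extend(vals)
    return out


def abhprk(seq):
    table = SCALE_TABLES["ABHPRK"]
    return [
        sum(table[c][d] for c in seq) / len(seq) for d in range(6)
    ]


def pi_bisection(seq, tol=1e-4):
    """Isoelectric point by bisection on a Henderson-Hasselbalch net-charge
    sum with the Bjellqvist pKa set (the basis of the ProtParam value)."""
    pka_pos = {"K": 10.0, "R": 12.0, "H": 5.98}
    pka_neg = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
    nterm_pka = {
        "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44,
        "E": 7.7,
    }.get(seq[0], 7.5)
    cterm_pka = {"D": 4.55, "E": 4.75}.get(seq[-1], 3.55)

    def charge(ph):
        c = 1.0 / (1.0 + 10 ** (ph - nterm_pka))
        c -= 1.0 / (1.0 + 10 ** (cterm_pka - ph))
        for res in seq:
            if res in pka_pos:
                c += 1.0 / (1.0 + 10 ** (ph - pka_pos[res]))
            elif res in pka_neg:
                c -= 1.0 / (1.0 + 10 ** (pka_neg[res] - ph))
        return c

    lo, hi = 0.0, 14.0
    while hi - lo > tol / 10:
        mid = (lo + hi) / 2
        if charge(mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


# ---- metric oracles --------------------------------------------------------


def confusion_counts(labels, preds):
    tp = sum(1 for y, p in zip(labels, preds) if y == 1 and p == 1)
    tn = sum(1 for y, p in zip(labels, preds) if y == 0 and p == 0)
    fp = sum(1 for y, p in zip(labels, preds) if y == 0 and p == 1)
    fn = sum(1 for y, p in zip(labels, preds) if y == 1 and p == 0)
    return tp, tn, fp, fn


def metric_formulas(tp, tn, fp, fn):
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return acc, prec, rec, spec, f1, mcc


def auc_pairs(labels, scores):
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
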