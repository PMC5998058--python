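"""Independent brute-force oracles for the descriptor families.

Deliberately written with plain Python loops and dictionaries — no shared
code with the package implementation beyond the physicochemical data tables
(which are inputs, not algorithm).
"""

from __future__ import annotations

from math import ceil, sqrt

from fertpred._tables import (
    AMINO_ACIDS,
    AUTOCORR_SCALES,
    CTD_PROPERTIES,
    CTRIAD_CLASSES,
    GRANTHAM,
    PSEAAC_HYDROPHILICITY,
    PSEAAC_HYDROPHOBICITY,
    PSEAAC_MASS,
    SCHNEIDER_WREDE,
    AA_INDEX,
)


def _standardized(scale: dict[str, float]) -> dict[str, float]:
    vals = [scale[aa] for aa in AMINO_ACIDS]
    mean = sum(vals) / 20.0
    sd = sqrt(sum((v - mean) ** 2 for v in vals) / 20.0)
    return {aa: (scale[aa] - mean) / sd for aa in AMINO_ACIDS}


def oracle_aac_dc(seq: str) -> list[float]:
    L = len(seq)
    aac = [seq.count(aa) / L for aa in AMINO_ACIDS]
    dc = []
    pairs = [seq[i:i + 2] for i in range(L - 1)]
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            dc.append(pairs.count(a + b) / (L - 1))
    return aac + dc


def oracle_autocorrelation(seq: str, nlag: int = 30,
                           properties=tuple(AUTOCORR_SCALES)) -> list[float]:
    L = len(seq)
    out = []
    series = []
    for prop in properties:
        std = _standardized(AUTOCORR_SCALES[prop])
        series.append([std[c] for c in seq])
    for kind in ("mb", "moran", "geary"):
        for p in series:
            pbar = sum(p) / L
            ss = 0.0 if max(p) == min(p) else sum((x - pbar) ** 2 for x in p)
            for d in range(1, nlag + 1):
                if kind == "mb":
                    out.append(sum(p[i] * p[i + d] for i in range(L - d)) / (L - d))
                elif kind == "moran":
                    if ss == 0:
                        out.append(0.0)
                    else:
                        num = sum((p[i] - pbar) * (p[i + d] - pbar)
                                  for i in range(L - d)) / (L - d)
                        out.append(num / (ss / L))
                else:
                    if ss == 0:
                        out.append(0.0)
                    else:
                        num = sum((p[i] - p[i + d]) ** 2
                                  for i in range(L - d)) / (2 * (L - d))
                        out.append(num / (ss / (L - 1)))
    return out


def oracle_ctd(seq: str) -> list[float]:
    L = len(seq)
    comp, tran, dist = [], [], []
    for _, groups in CTD_PROPERTIES:
        lut = {}
        for gi, members in enumerate(groups, start=1):
            for aa in members:
                lut[aa] = gi
        g = [lut[c] for c in seq]
        for k in (1, 2, 3):
            comp.append(g.count(k) / L)
        for x, y in ((1, 2), (1, 3), (2, 3)):
            n = sum(
                1 for i in range(L - 1)
                if (g[i] == x and g[i + 1] == y) or (g[i] == y and g[i + 1] == x)
            )
            tran.append(n / (L - 1))
        for k in (1, 2, 3):
            positions = [i + 1 for i, gi in enumerate(g) if gi == k]
            if not positions:
                dist.extend([0.0] * 5)
                continue
            n = len(positions)
            for q in (0.0, 0.25, 0.5, 0.75, 1.0):
                idx = max(1, ceil(q * n))
                dist.append(100.0 * positions[idx - 1] / L)
    return comp + tran + dist


def oracle_order(seq: str, nlag: int = 30, w: float = 0.1) -> list[float]:
    L = len(seq)
    socn, qso = [], []
    for mat in (SCHNEIDER_WREDE, GRANTHAM):
        taus = []
        for d in range(1, nlag + 1):
            taus.append(sum(
                mat[AA_INDEX[seq[i]], AA_INDEX[seq[i + d]]] ** 2
                for i in range(L - d)
            ))
        socn.extend(taus)
        f = [seq.count(aa) / L for aa in AMINO_ACIDS]
        denom = sum(f) + w * sum(taus)
        qso.extend(x / denom for x in f)
        qso.extend(w * t / denom for t in taus)
    return socn + qso


def oracle_pseaac(seq: str, lam: int = 30, w: float = 0.05) -> list[float]:
    L = len(seq)
    h1 = _standardized(PSEAAC_HYDROPHOBICITY)
    h2 = _standardized(PSEAAC_HYDROPHILICITY)
    m = _standardized(PSEAAC_MASS)
    f = [seq.count(aa) / L for aa in AMINO_ACIDS]

    thetas = []
    for j in range(1, lam + 1):
        total = 0.0
        for i in range(L - j):
            a, b = seq[i], seq[i + j]
            total += ((h1[a] - h1[b]) ** 2 + (h2[a] - h2[b]) ** 2
                      + (m[a] - m[b]) ** 2) / 3.0
        thetas.append(total / (L - j))
    denom = sum(f) + w * sum(thetas)
    type1 = [x / denom for x in f] + [w * t / denom for t in thetas]

    taus = []
    for j in range(1, lam + 1):
        taus.append(sum(h1[seq[i]] * h1[seq[i + j]] for i in range(L - j)) / (L - j))
        taus.append(sum(h2[seq[i]] * h2[seq[i + j]] for i in range(L - j)) / (L - j))
    denom2 = sum(f) + w * sum(taus)
    type2 = [x / denom2 for x in f] + [w * t / denom2 for t in taus]
    return type1 + type2


def oracle_ctriad(seq: str) -> list[float]:
    lut = {}
    for k, cls in enumerate(CTRIAD_CLASSES, start=1):
        for aa in cls:
            lut[aa] = k
    counts: dict[tuple[int, int, int], int] = {}
    for i in range(len(seq) - 2):
        key = (lut[seq[i]], lut[seq[i + 1]], lut[seq[i + 2]])
        counts[key] = counts.get(key, 0) + 1
    flat = []
    for a in range(1, 8):
        for b in range(1, 8):
            for c in range(1, 8):
                flat.append(counts.get((a, b, c), 0))
    fmin, fmax = min(flat), max(flat)
    if fmax == 0:
        return [0.0] * 343
    return [(x - fmin) / fmax for x in flat]


ORACLES = {
    "aac_dc": oracle_aac_dc,
    "autocorr": oracle_autocorrelation,
    "ctd": oracle_ctd,
    "order": oracle_order,
    "pseaac": oracle_pseaac,
    "ctriad": oracle_ctriad,
}
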