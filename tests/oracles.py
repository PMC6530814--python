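"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain Python loops straight from the score
definitions, with no shared code paths with the package internals.
"""

import math

import numpy as np


def rc(seq: str) -> str:
    return seq[::-1].translate(str.maketrans("ACGT", "TGCA"))


def brute_site_probability(E: float, lambda_param: float, ln_r0: float) -> float:
    x = math.exp(ln_r0) * math.exp(-E / lambda_param)
    return x / (1.0 + x)


def brute_affinity(seq: str, matrix) -> float:
    """Window-by-window enumeration of the TRAP affinity on both strands."""
    w = matrix.width
    total = 0.0
    for strand_seq in (seq, rc(seq)):
        for i in range(len(strand_seq) - w + 1):
            win = strand_seq[i : i + w]
            if "N" in win:
                continue
            E = sum(matrix.energies[j, "ACGT".index(b)] for j, b in enumerate(win))
            total += brute_site_probability(E, matrix.lambda_param, matrix.ln_r0)
    return total


def brute_window(gene, peaks, window: int, d0: float):
    """Peaks overlapping the TSS-centred window, with decay weights."""
    tss0 = gene.tss - 1
    lo, hi = tss0 - window / 2, tss0 + window / 2
    hits = []
    for p in peaks:
        if p.start < hi and p.end > lo:
            d = abs((p.start + p.end) // 2 - tss0)
            hits.append((p, math.exp(-d / d0)))
    return hits


def brute_chip_C(genes, chip_by_tf, window, d0):
    out = {}
    for g in genes:
        row = {}
        for tf, peaks in chip_by_tf.items():
            row[tf] = sum(p.score * w for p, w in brute_window(g, peaks, window, d0))
        out[g.gene_id] = row
    return out


def brute_chip_cl(genes, chip_by_tf, window, d0):
    c, l = {}, {}
    for g in genes:
        cv = lv = 0.0
        for peaks in chip_by_tf.values():
            for p, w in brute_window(g, peaks, window, d0):
                cv += w
                lv += (p.end - p.start) * w
        c[g.gene_id], l[g.gene_id] = cv, lv
    return c, l


def brute_dnase(genes, peaks, aff, widths, window, d0, variant):
    """aff: dict (peak key, tf) -> affinity; returns dict gene -> dict col -> value."""
    tfs = sorted({t for _, t in aff}) if aff else []
    out = {}
    for g in genes:
        hits = brute_window(g, peaks, window, d0)
        row = {}
        cv = sum(w for _, w in hits)
        lv = sum((p.end - p.start) * w for p, w in hits)
        fv = sum(p.signal * w for p, w in hits)
        for t in tfs:
            val = 0.0
            for p, w in hits:
                a = aff[(f"{p.chrom}:{p.start}-{p.end}", t)]
                if variant == "D":
                    val += a * w
                elif variant == "DS":
                    val += a * p.signal * w
                elif variant in ("DN", "DSN"):
                    sites = max((p.end - p.start) - widths[t] + 1, 1)
                    val += a / sites * w
            row[t] = val
        if variant in ("D", "DS"):
            out[g.gene_id] = row
            continue
        if variant in ("DN", "DSN"):
            row["Peak_Count"] = cv
            row["Peak_Length"] = lv
            if variant == "DSN":
                row["Peak_Signal"] = fv
        if variant in ("DPF", "DPFS"):
            row = {"Peak_Count": cv, "Peak_Length": lv}
            if variant == "DPFS":
                row["Peak_Signal"] = fv
        out[g.gene_id] = row
    return out


def brute_aupr(is_positive: list[bool], grid: int = 20001) -> float:
    """AUPR by dense numeric integration of the interpolated PR curve.

    TP and FP counts are interpolated linearly between consecutive
    ranking depths; precision = tp/(tp+fp) is integrated over recall on a
    fine grid by trapezoid.
    """
    tp = np.cumsum(is_positive).astype(float)
    fp = np.cumsum([not b for b in is_positive]).astype(float)
    n_pos = tp[-1]
    if n_pos == 0:
        return 0.0
    tp = np.concatenate([[0.0], tp])
    fp = np.concatenate([[0.0], fp])
    depth = np.linspace(0, len(is_positive), grid)
    tpi = np.interp(depth, np.arange(len(tp)), tp)
    fpi = np.interp(depth, np.arange(len(fp)), fp)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tpi + fpi > 0, tpi / (tpi + fpi), np.nan)
    rec = tpi / n_pos
    # drop the leading undefined point at depth 0
    ok = ~np.isnan(prec)
    return float(np.trapezoid(prec[ok], rec[ok]))
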