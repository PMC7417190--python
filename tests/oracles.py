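"""Independent brute-force oracles used to cross-check the library.

Everything here is deliberately naive (python loops, quadratic scans, boolean
masks) and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from chromtrace.genome_io import Interval


def naive_merge(intervals, chrom_length=10_000):
    """Merge via an explicit per-base boolean mask."""
    by_chrom = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, np.zeros(chrom_length, dtype=bool))
        by_chrom[iv.chrom][iv.start : iv.end] = True
    out = []
    for chrom in sorted(by_chrom):
        mask = by_chrom[chrom]
        start = None
        for i in range(chrom_length + 1):
            on = i < chrom_length and mask[i]
            if on and start is None:
                start = i
            elif not on and start is not None:
                out.append(Interval(chrom, start, i))
                start = None
    return out


def naive_call_peaks(signal, background, genome, params):
    """Exhaustive re-scoring of every candidate window, naive BH and greedy.

    Returns a list of (chrom, start, end, count) tuples plus parallel p/q lists.
    """
    mids = {}
    for f in signal.fragments:
        mids.setdefault(f.chrom, []).append((f.start + f.end) // 2)
    bg_mids = {}
    if background is not None:
        for f in background.fragments:
            bg_mids.setdefault(f.chrom, []).append((f.start + f.end) // 2)
    w = params.window
    total = len(signal.fragments)
    cands = []  # (chrom, start, k, lam, p)
    for chrom in genome.chrom_names:
        L = genome.length(chrom)
        m = sorted(mids.get(chrom, []))
        bm = sorted(bg_mids.get(chrom, []))
        s = 0
        while s <= L - w:
            k = sum(1 for x in m if s <= x < s + w)
            center = s + w // 2
            lo = max(0, center - params.local_size // 2)
            hi = min(L, center + params.local_size // 2)
            local_k = sum(1 for x in m if lo <= x < hi)
            lam = (local_k - k) / max((hi - lo) - w, 1) * w
            lam = max(lam, total / genome.total_length * w)
            if background is not None:
                bk = sum(1 for x in bm if s <= x < s + w)
                lam = max(lam, bk * total / len(background.fragments))
            lam = max(lam, 1e-9)
            p = float(stats.poisson.sf(k - 1, lam))
            cands.append((chrom, s, k, lam, p))
            s += w // 2
    # naive BH
    n = len(cands)
    order = sorted(range(n), key=lambda i: cands[i][4])
    q = [0.0] * n
    prev = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, cands[i][4] * n / (rank_idx + 1))
        q[i] = val
        prev = val
    # keep + greedy
    keep = [
        i
        for i in range(n)
        if q[i] <= params.q_threshold
        and cands[i][2] / cands[i][3] >= params.min_fold
        and cands[i][2] > 0
    ]
    keep.sort(key=lambda i: (cands[i][4], cands[i][0], cands[i][1]))
    accepted = []
    for i in keep:
        chrom, s = cands[i][0], cands[i][1]
        center = s + w // 2
        if any(
            c2 == chrom and abs(center - (s2 + w // 2)) < params.min_dist
            for (c2, s2, *_ ) in accepted
        ):
            continue
        accepted.append(cands[i])
    accepted.sort(key=lambda c: (c[0], c[1]))
    return [(c[0], c[1], c[1] + w, c[2]) for c in accepted]


def naive_scan(sequences, consensus, max_mismatch):
    """Character-by-character scan of both strands with the dedup rule."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    cons = consensus.upper()
    rc = "".join(comp[b] for b in reversed(cons))
    w = len(cons)
    hits = []
    for chrom, seq in sequences.items():
        seq = seq.upper()
        for i in range(len(seq) - w + 1):
            win = seq[i : i + w]
            if any(b not in "ACGT" for b in win):
                continue
            mf = sum(a != b for a, b in zip(win, cons))
            mr = sum(a != b for a, b in zip(win, rc))
            if min(mf, mr) <= max_mismatch:
                strand = "+" if mf <= mr else "-"
                hits.append((chrom, i, strand, min(mf, mr)))
    return hits


def naive_classify(peaks_a, peaks_b, chrom_length=10_000):
    """Quadratic region classification on a merged mask."""
    merged = naive_merge(list(peaks_a) + list(peaks_b), chrom_length)
    labels = []
    for r in merged:
        in_a = any(r.overlaps(p) for p in peaks_a)
        in_b = any(r.overlaps(p) for p in peaks_b)
        labels.append(
            "AB_overlap" if (in_a and in_b) else ("A_only" if in_a else "B_only")
        )
    return merged, labels


def naive_nearest_tss(region, tss_rows):
    """Linear scan for the nearest TSS with lexicographic tie-break."""
    c = region.center
    best = None
    for gene, chrom, pos, strand in tss_rows:
        if chrom != region.chrom:
            continue
        d = abs(c - pos)
        key = (d, gene)
        if best is None or key < best[0]:
            best = (key, gene, c - pos)
    return None if best is None else (best[1], best[2])
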