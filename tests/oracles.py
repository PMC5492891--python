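"""Brute-force per-base oracles, independent of the library's interval code.

Each oracle works by painting bases on a dense array (or by all-pairs
scans), so coordinates must stay small (< ~10,000).
"""

from __future__ import annotations

import numpy as np


def paint_merge(spans, max_gap=0, limit=12_000):
    """Merge (start, end) spans by painting bases and closing small gaps.

    Returns a list of (start, end, count) runs, where count is the number
    of input spans assigned to each run (every input lands in exactly one
    run because runs cover all painted bases).
    """
    if not spans:
        return []
    occupied = np.zeros(limit, dtype=bool)
    for start, end in spans:
        occupied[start:end] = True
    runs = []
    pos = 0
    while pos < limit:
        if occupied[pos]:
            start = pos
            while pos < limit and occupied[pos]:
                pos += 1
            runs.append([start, pos])
        else:
            pos += 1
    # book-ended spans already form one run; close gaps <= max_gap
    closed = []
    for run in runs:
        if closed and run[0] - closed[-1][1] <= max_gap:
            closed[-1][1] = run[1]
        else:
            closed.append(run)
    out = []
    for start, end in closed:
        count = sum(1 for s, e in spans if s >= start and e <= end)
        out.append((start, end, count))
    assert sum(c for _, _, c in out) == len(spans)
    return out


def spans_overlap(a, b):
    """Half-open overlap of two (start, end) spans via painted bases."""
    limit = max(a[1], b[1])
    pa = np.zeros(limit, dtype=bool)
    pb = np.zeros(limit, dtype=bool)
    pa[a[0] : a[1]] = True
    pb[b[0] : b[1]] = True
    return bool((pa & pb).any())


def classify_region(span, exon_spans, gene_spans):
    """Exonic / intronic / intergenic by scanning every feature."""
    if any(spans_overlap(span, e) for e in exon_spans):
        return "exonic"
    if any(spans_overlap(span, g) for g in gene_spans):
        return "intronic"
    return "intergenic"
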