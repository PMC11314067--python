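"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit coordinate sets, all-pairs
scans, textbook dynamic programming) and shares no code with the package.
"""

from __future__ import annotations


def brute_interval_distance(a, b) -> int | None:
    """Gap via explicit base-coordinate reasoning, not the gap formula."""
    if a.chrom != b.chrom:
        return None
    pos_a = set(range(a.start, a.end))
    pos_b = set(range(b.start, b.end))
    if pos_a & pos_b:
        return 0
    # number of bases strictly between the two closest covered positions
    best = min(abs(x - y) for x in (a.start, a.end - 1) for y in (b.start, b.end - 1))
    return best - 1


def brute_valid_insertions(genes, tes, window_bp, families):
    """All-pairs scan with the brute-force distance."""
    calls = set()
    for g in genes:
        for t in tes:
            if families and t.family not in families:
                continue
            d = brute_interval_distance(g.interval, t.interval)
            if d is not None and d <= window_bp:
                calls.add((g.gene_id, t.te_id, d))
    return calls


def brute_modified(gene, peaks, window_bp):
    """Per-(mark, replicate) modification states via coordinate sets."""
    if gene.interval.strand == "-":
        tss = gene.interval.end - 1
    else:
        tss = gene.interval.start
    win = set(range(max(tss - window_bp, 0), tss + window_bp + 1))
    states = {}
    for p in peaks:
        key = (p.mark, p.replicate)
        states.setdefault(key, False)
        if p.interval.chrom != gene.interval.chrom:
            continue
        if win & set(range(p.interval.start, p.interval.end)):
            states[key] = True
    return states


def brute_longest(transcripts):
    """Winner per gene: max summed exon length, then smallest transcript_id."""
    by_gene = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    return {
        gid: sorted(
            ts, key=lambda t: (-sum(e.end - e.start for e in t.exons), t.transcript_id)
        )[0]
        for gid, ts in by_gene.items()
    }


def nw_identity(a: str, b: str, tie: int):
    """Needleman-Wunsch with match +1 / mismatch −1 / gap −2 (linear).

    Maximizes (score, tie*matches, tie*diagonal_steps) lexicographically, so
    ``tie=+1`` yields a near-maximal and ``tie=-1`` a near-minimal identity
    among optimal-score alignments. Returns (score, identity) with
    identity = matches / aligned columns (columns = len(a)+len(b)−diagonals).
    """
    la, lb = len(a), len(b)
    NEG = (-10**9, 0, 0)
    prev = [(-2 * j, 0, 0) for j in range(lb + 1)]
    for i in range(1, la + 1):
        cur = [NEG] * (lb + 1)
        cur[0] = (-2 * i, 0, 0)
        for j in range(1, lb + 1):
            m = 1 if a[i - 1] == b[j - 1] else -1
            ps, pm, pd = prev[j - 1]
            diag = (ps + m, pm + (1 if m == 1 else 0), pd + 1)
            us, um, ud = prev[j]
            up = (us - 2, um, ud)
            ls, lm, ld = cur[j - 1]
            left = (ls - 2, lm, ld)
            cur[j] = max(
                diag, up, left,
                key=lambda t: (t[0], tie * t[1], tie * t[2]),
            )
        prev = cur
    score, matches, diagonals = prev[lb]
    columns = la + lb - diagonals
    return score, matches / columns
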