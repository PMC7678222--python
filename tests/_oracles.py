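"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most transparent method available
(full dynamic programs, exhaustive scans, direct summation) without
touching the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np


def sw_score_python(q: str, s: str, match: int = 1, mismatch: int = -2, gap: int = 2) -> int:
    """Plain O(mn) Smith-Waterman best score, linear gap penalty."""
    m, n = len(q), len(s)
    prev = [0] * (n + 1)
    best = 0
    for i in range(1, m + 1):
        cur = [0] * (n + 1)
        qc = q[i - 1]
        for j in range(1, n + 1):
            sub = match if qc == s[j - 1] else mismatch
            h = max(0, prev[j - 1] + sub, prev[j] - gap, cur[j - 1] - gap)
            cur[j] = h
            if h > best:
                best = h
        prev = cur
    return best


def avq_bruteforce(matches: list[tuple[str, float, float]], n_proteins: int) -> tuple[float, float]:
    """(fraction, avq) by exhaustive per-protein best-hit selection.

    ``matches`` holds (protein_id, evalue, viral_quotient).
    """
    proteins = sorted({p for p, _, _ in matches})
    avq = 0.0
    for p in proteins:
        rows = [(e, vq) for pp, e, vq in matches if pp == p]
        best_e = min(e for e, _ in rows)
        best_vq = max(vq for e, vq in rows if e == best_e)
        avq += best_vq
    return len(proteins) / n_proteins, avq


def taxonomy_vote_bruteforce(
    hits: list[tuple[str, str, float, float]],
) -> tuple[str, int, float]:
    """(taxon, n_proteins, mean_identity) by exhaustive per-taxon counting.

    ``hits`` holds (protein_id, taxon, identity, bitscore); per protein and
    taxon only the top-bitscore hit counts.
    """
    taxa = sorted({t for _, t, _, _ in hits})
    scored = []
    for taxon in taxa:
        rows = [(p, i, b) for p, t, i, b in hits if t == taxon]
        per_protein = {}
        for p, ident, bits in rows:
            if p not in per_protein or bits > per_protein[p][1]:
                per_protein[p] = (ident, bits)
        idents = [v[0] for v in per_protein.values()]
        scored.append((len(per_protein), float(np.mean(idents)), taxon))
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    n, mean_id, taxon = scored[0]
    return taxon, n, mean_id


def six_frame_orf_intervals(seq: str, min_len: int) -> list[tuple[int, int, int]]:
    """All stop-free maximal regions >= min_len per frame and strand, as
    (start, end, strand) on the forward strand, without ATG trimming."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    stops = {"TAA", "TAG", "TGA"}
    out = []
    n = len(seq)
    for strand in (1, -1):
        s = seq if strand == 1 else "".join(comp[c] for c in reversed(seq))
        for frame in range(3):
            start = frame
            pos = frame
            while pos + 3 <= n:
                if s[pos : pos + 3] in stops:
                    if pos - start >= min_len:
                        out.append((start, pos, strand))
                    start = pos + 3
                pos += 3
            if pos - start >= min_len:
                out.append((start, pos, strand))
    return out


def trna_hits_windowed(genome: str, trna: str, min_identity: float) -> list[int]:
    """Start positions where the tRNA matches a same-length window at
    >= min_identity percent (substitution-only model, forward strand)."""
    L = len(trna)
    out = []
    for i in range(len(genome) - L + 1):
        window = genome[i : i + L]
        matches = sum(a == b for a, b in zip(window, trna))
        if 100.0 * matches / L >= min_identity:
            out.append(i)
    return out


def crispr_bruteforce(
    seq: str,
    min_repeats: int = 3,
    rep_range: tuple[int, int] = (23, 47),
    sp_range: tuple[int, int] = (21, 72),
) -> list[tuple[int, int, int]]:
    """Exhaustive tandem exact-repeat arrays as (first_start, repeat_len,
    n_repeats), maximal in repeat count for each (start, length)."""
    n = len(seq)
    found = []
    for L in range(rep_range[0], rep_range[1] + 1):
        for start in range(0, n - L + 1):
            rep = seq[start : start + L]
            starts = [start]
            pos = start
            while True:
                lo = pos + L + sp_range[0]
                hi = min(pos + L + sp_range[1], n - L)
                nxt = None
                for cand in range(lo, hi + 1):
                    if seq[cand : cand + L] == rep:
                        nxt = cand
                        break
                if nxt is None:
                    break
                starts.append(nxt)
                pos = nxt
            if len(starts) >= min_repeats:
                found.append((start, L, len(starts), starts[-1] + L))
    # drop arrays whose genomic span lies inside that of a dominant array
    # (more copies, then longer repeat); also drop repeat sub-windows
    maximal = []
    for s, L, r, end in found:
        dominated = any(
            (s2, L2, r2, e2) != (s, L, r, end)
            and s2 <= s
            and end <= e2
            and (r2, L2) > (r, L)
            for s2, L2, r2, e2 in found
        )
        if not dominated:
            maximal.append((s, L, r))
    return maximal


def ks_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    """Sup-distance between empirical CDFs by sweeping all data points."""
    pts = np.concatenate([a, b])
    best = 0.0
    for x in pts:
        fa = (a <= x).mean()
        fb = (b <= x).mean()
        best = max(best, abs(fa - fb))
    return best


def pi_grid_scan(charge_fn, step: float = 1e-5) -> float:
    """Zero crossing of a monotone-decreasing charge function by fine grid."""
    grid = np.arange(0.0, 14.0 + step, step)
    vals = np.array([charge_fn(ph) for ph in grid])
    idx = int(np.argmax(vals <= 0))
    if idx == 0:
        return float(grid[0])
    # linear interpolation between bracketing grid points
    x0, x1 = grid[idx - 1], grid[idx]
    y0, y1 = vals[idx - 1], vals[idx]
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))


def pi_grid_vectorized(seq: str, bases: dict, acids: dict, step: float = 1e-5) -> float:
    """Isoelectric point by exhaustive fine-grid zero-crossing scan of the
    Henderson-Hasselbalch net charge (vectorised over the pH grid)."""
    ph = np.arange(0.0, 14.0 + step, step)
    charge = 1.0 / (1.0 + 10.0 ** (ph - bases["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (acids["Cterm"] - ph))
    for aa, pka in bases.items():
        if aa == "Nterm":
            continue
        n = seq.count(aa)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka))
    for aa, pka in acids.items():
        if aa == "Cterm":
            continue
        n = seq.count(aa)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka - ph))
    idx = int(np.argmax(charge <= 0))
    x0, x1 = ph[idx - 1], ph[idx]
    y0, y1 = charge[idx - 1], charge[idx]
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))


def average_linkage_heights(D: np.ndarray) -> list[float]:
    """Merge heights of naive average-linkage agglomeration (UPGMA on a
    dissimilarity matrix), smallest-pair-first with index tie-breaks."""
    clusters = [[i] for i in range(D.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = float(
                    np.mean([D[a, b] for a in clusters[i] for b in clusters[j]])
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
    return heights
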