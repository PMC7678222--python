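"""Internal sequence-comparison engine.

Desk-scale replacements for the external search tools of a viral
metagenomics pipeline: a scoring local aligner (exact Smith-Waterman
dynamic programming for small problems, seed-and-extend for large ones),
average nucleotide identity (ANI), a six-frame ORF caller, homology-based
tRNA detection against a bundled canonical set, and a minimal exact-repeat
CRISPR-array detector.

Conventions
-----------
Coordinates are 0-based half-open internally; emitted tables use 1-based
inclusive coordinates (BLAST convention).  E-values follow Karlin-Altschul
statistics with fixed constants documented on each scoring scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import edlib
import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "ScoringScheme",
    "NUCLEOTIDE",
    "PROTEIN",
    "LocalAlignment",
    "AniResult",
    "GeneCall",
    "TrnaHit",
    "CrisprArray",
    "SearchHit",
    "local_align",
    "compute_ani",
    "find_orfs",
    "find_trnas",
    "find_crispr_arrays",
    "search_all",
]

LN2 = math.log(2.0)

_NT_LETTERS = "ACGT"
# code 4 = ambiguous (N etc.), codes 5/6 = mask sentinels (never match anything)
_NT_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(_NT_LETTERS):
    _NT_CODES[ord(_c)] = _i
    _NT_CODES[ord(_c.lower())] = _i
_NT_CODES[ord("U")] = 3
_NT_CODES[ord("u")] = 3

_AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_CODES = np.full(256, _AA_ALPHABET.index("X"), dtype=np.uint8)
for _i, _c in enumerate(_AA_ALPHABET):
    _AA_CODES[ord(_c)] = _i
    _AA_CODES[ord(_c.lower())] = _i

_MASK_SCORE = -(10 ** 6)


def _nt_submat(match: int, mismatch: int) -> np.ndarray:
    m = np.full((7, 7), mismatch, dtype=np.int64)
    for i in range(4):
        m[i, i] = match
    # ambiguous bases and masks never produce a positive score
    m[4, :] = mismatch
    m[:, 4] = mismatch
    m[4, 4] = mismatch
    m[5:, :] = _MASK_SCORE
    m[:, 5:] = _MASK_SCORE
    return m


def _aa_submat() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(_AA_ALPHABET)
    m = np.zeros((n + 2, n + 2), dtype=np.int64)
    for i, a in enumerate(_AA_ALPHABET):
        for j, b in enumerate(_AA_ALPHABET):
            m[i, j] = int(blosum[a][b])
    m[n:, :] = _MASK_SCORE
    m[:, n:] = _MASK_SCORE
    return m


@dataclass(frozen=True)
class ScoringScheme:
    """A scoring scheme with linear gap costs and Karlin-Altschul constants.

    ``gap`` is the positive per-residue gap penalty.  ``lam`` and ``k`` are
    the Karlin-Altschul parameters used for bit-score and e-value
    conversion; the nucleotide defaults correspond to the classic +1/-2
    ungapped parameters, the protein scheme to BLOSUM62 defaults.
    """

    name: str
    alphabet: str  # "nt" or "aa"
    submat: np.ndarray
    codes: np.ndarray
    mask_code: int
    gap: int
    lam: float
    k: float

    def encode(self, seq: str) -> np.ndarray:
        return self.codes[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]

    def validate(self, seq: str, role: str) -> None:
        if not seq:
            raise ValueError(f"empty {role} sequence")
        letters = set(seq.upper())
        if self.alphabet == "nt":
            bad = letters - set("ACGTUN")
            if bad:
                raise ValueError(
                    f"{role} sequence contains non-nucleotide letters {sorted(bad)!r} "
                    f"inconsistent with scoring scheme {self.name!r}"
                )
        else:
            bad = letters - set(_AA_ALPHABET)
            if bad:
                raise ValueError(
                    f"{role} sequence contains letters {sorted(bad)!r} "
                    f"inconsistent with scoring scheme {self.name!r}"
                )

    def bitscore(self, score: float) -> float:
        return (self.lam * score - math.log(self.k)) / LN2

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.k * m * n * math.exp(-self.lam * score)


NUCLEOTIDE = ScoringScheme(
    name="nt+1/-2",
    alphabet="nt",
    submat=_nt_submat(1, -2),
    codes=_NT_CODES,
    mask_code=5,
    gap=2,
    lam=0.625,
    k=0.41,
)

PROTEIN = ScoringScheme(
    name="blosum62",
    alphabet="aa",
    submat=_aa_submat(),
    codes=_AA_CODES,
    mask_code=len(_AA_ALPHABET),
    gap=11,
    lam=0.267,
    k=0.041,
)


@dataclass
class LocalAlignment:
    """One local alignment, coordinates 1-based inclusive on both sequences."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float
    score: int = 0
    matches: int = 0
    gaps: int = 0

    @property
    def query_span(self) -> tuple[int, int]:
        """0-based half-open query interval."""
        return self.query_start - 1, self.query_end


@dataclass
class AniResult:
    """Average nucleotide identity between two sequences.

    ``ani`` is the alignment-length-weighted mean percent identity over
    retained local alignments; undefined (``defined=False``, ``ani=None``)
    when no alignment qualifies.
    """

    ani: float | None
    aligned_fraction: float
    defined: bool
    n_alignments: int = 0


@dataclass
class GeneCall:
    gene_id: str
    start: int  # 0-based half-open on the forward strand
    end: int
    strand: int  # +1 / -1
    nucleotide: str
    protein: str


@dataclass
class TrnaHit:
    name: str
    start: int
    end: int
    strand: int
    identity: float
    length: int
    sequence: str


@dataclass
class CrisprArray:
    genome_id: str
    repeat_sequence: str
    repeat_count: int
    repeat_starts: list[int]
    spacers: list[str]
    spacer_starts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.repeat_count < 3:
            raise ValueError("CRISPR array requires at least 3 repeat copies")
        if len(self.spacers) != self.repeat_count - 1:
            raise ValueError("spacer count must equal repeat_count - 1")


@dataclass
class SearchHit:
    """Semi-global (full query) hit of a short query inside a subject."""

    start: int  # 0-based half-open on subject forward strand
    end: int
    strand: int
    matches: int
    mismatches: int
    gaps: int
    alignment_length: int

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.alignment_length


# ---------------------------------------------------------------------------
# Smith-Waterman dynamic programming (exact, linear gap penalty)
# ---------------------------------------------------------------------------

def _sw_matrix(q: np.ndarray, s: np.ndarray, scoring: ScoringScheme) -> np.ndarray:
    """Full Smith-Waterman H matrix with linear gap penalty, vectorised by row.

    The in-row (left-gap) dependency is resolved with a running-max
    transform: H[i,j] = max(cand[j], H[i,j-1]-g) is equivalent to a prefix
    maximum over cand[j] + g*j.
    """
    m, n = len(q), len(s)
    g = scoring.gap
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    jg = g * np.arange(1, n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        sub = scoring.submat[q[i - 1], s]
        cand = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] - g)
        np.maximum(cand, 0, out=cand)
        t = np.maximum.accumulate(cand + jg)
        H[i, 1:] = np.maximum(cand, t - jg)
    return H


def _sw_traceback(
    H: np.ndarray, q: np.ndarray, s: np.ndarray, scoring: ScoringScheme
) -> tuple[int, int, int, int, int, int, int, int, int]:
    """Best local alignment from an H matrix.

    Returns (score, qstart, qend, sstart, send, matches, mismatches, gaps,
    gap_opens) with 0-based half-open coordinates.  Ties on the maximal
    cell are broken toward the smallest (i, j); moves prefer diagonal,
    then up (gap in subject), then left.
    """
    g = scoring.gap
    flat = int(np.argmax(H))
    i, j = divmod(flat, H.shape[1])
    score = int(H[i, j])
    matches = mismatches = gaps = gap_opens = 0
    qend, send = i, j
    last_move = "d"
    while i > 0 and j > 0 and H[i, j] > 0:
        sub = scoring.submat[q[i - 1], s[j - 1]]
        if H[i, j] == H[i - 1, j - 1] + sub:
            if q[i - 1] == s[j - 1] and sub > 0:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
            last_move = "d"
        elif H[i, j] == H[i - 1, j] - g:
            gaps += 1
            if last_move != "u":
                gap_opens += 1
            i -= 1
            last_move = "u"
        elif H[i, j] == H[i, j - 1] - g:
            gaps += 1
            if last_move != "l":
                gap_opens += 1
            j -= 1
            last_move = "l"
        else:  # pragma: no cover - defensive
            break
    return score, i, qend, j, send, matches, mismatches, gaps, gap_opens


def _dp_local_align(
    qcodes: np.ndarray,
    scodes: np.ndarray,
    scoring: ScoringScheme,
    min_score: int,
    max_alignments: int,
    m_len: int,
    n_len: int,
    query_id: str,
    subject_id: str,
) -> list[LocalAlignment]:
    """Exact DP route: repeatedly extract the best alignment and mask the
    aligned query interval so reported alignments never overlap on the query."""
    q = qcodes.copy()
    out: list[LocalAlignment] = []
    for _ in range(max_alignments):
        H = _sw_matrix(q, scodes, scoring)
        score, qs, qe, ss, se, mat, mis, gaps, go = _sw_traceback(H, q, scodes, scoring)
        if score < min_score or qe == qs:
            break
        alen = mat + mis + gaps
        out.append(
            LocalAlignment(
                query_id=query_id,
                subject_id=subject_id,
                percent_identity=100.0 * mat / alen,
                alignment_length=alen,
                mismatches=mis,
                gap_opens=go,
                query_start=qs + 1,
                query_end=qe,
                subject_start=ss + 1,
                subject_end=se,
                evalue=scoring.evalue(score, m_len, n_len),
                bitscore=scoring.bitscore(score),
                score=score,
                matches=mat,
                gaps=gaps,
            )
        )
        q[qs:qe] = scoring.mask_code
    return out


# ---------------------------------------------------------------------------
# Seed-and-extend route for large nucleotide comparisons
# ---------------------------------------------------------------------------

def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed 2-bit k-mer codes and their start positions (unambiguous only)."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    valid = codes < 4
    packed = np.zeros(n - k + 1, dtype=np.int64)
    ok = np.ones(n - k + 1, dtype=bool)
    for off in range(k):
        window = codes[off : off + n - k + 1].astype(np.int64)
        packed = (packed << 2) | np.where(window < 4, window, 0)
        ok &= valid[off : off + n - k + 1]
    pos = np.nonzero(ok)[0]
    return packed[pos], pos


def _seed_matches(
    qcodes: np.ndarray, scodes: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    qk, qpos = _kmer_codes(qcodes, k)
    sk, spos = _kmer_codes(scodes, k)
    if len(qk) == 0 or len(sk) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.argsort(sk, kind="stable")
    sk_sorted = sk[order]
    spos_sorted = spos[order]
    left = np.searchsorted(sk_sorted, qk, side="left")
    right = np.searchsorted(sk_sorted, qk, side="right")
    counts = right - left
    # ignore hyper-repetitive seeds
    counts = np.where(counts > 64, 0, counts)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    qm = np.repeat(qpos, counts)
    sm = np.concatenate(
        [spos_sorted[l:r] for l, r, c in zip(left, right, counts) if c > 0]
    )
    return qm, sm


def _chain_seeds(
    qm: np.ndarray, sm: np.ndarray, diag_tol: int = 32, gap_tol: int = 200
) -> list[tuple[int, int, int, int]]:
    """Group seed matches into colinear chains.

    Returns (qmin, qmax, smin, smax) per chain (start positions of seeds).
    Seeds join a chain when their diagonal is within ``diag_tol`` and the
    query-position gap within ``gap_tol`` of the chain's last seed.
    """
    if len(qm) == 0:
        return []
    diag = sm - qm
    order = np.lexsort((qm, diag))
    chains: list[tuple[int, int, int, int]] = []
    cq0 = cq1 = int(qm[order[0]])
    cs0 = cs1 = int(sm[order[0]])
    cdiag = int(diag[order[0]])
    for idx in order[1:]:
        q, s, d = int(qm[idx]), int(sm[idx]), int(diag[idx])
        if abs(d - cdiag) <= diag_tol and 0 <= q - cq1 <= gap_tol:
            cq1, cs1 = q, s
            cdiag = d
        else:
            chains.append((cq0, cq1, cs0, cs1))
            cq0 = cq1 = q
            cs0 = cs1 = s
            cdiag = d
    chains.append((cq0, cq1, cs0, cs1))
    return chains


def _cigar_columns(cigar: str) -> list[tuple[str, int]]:
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return out


def _extend_chain(
    query: str,
    subject: str,
    chain: tuple[int, int, int, int],
    k: int,
    scoring: ScoringScheme,
    margin: int = 64,
) -> tuple[int, int, int, int, int, int, int, int, int] | None:
    """Globally align the chained region with edlib, then trim to the
    maximum-scoring local segment (Kadane over alignment columns)."""
    qmin, qmax, smin, smax = chain
    qa, qb = max(0, qmin - margin), min(len(query), qmax + k + margin)
    sa, sb = max(0, smin - margin), min(len(subject), smax + k + margin)
    res = edlib.align(query[qa:qb], subject[sa:sb], mode="NW", task="path")
    if res["cigar"] is None:
        return None
    ops = _cigar_columns(res["cigar"])
    # per-column scores; '=': match, 'X': mismatch, 'I': query insertion
    # (consumes query), 'D': deletion (consumes subject)
    match = int(scoring.submat[0, 0])
    mismatch = int(scoring.submat[0, 1])
    gap = -scoring.gap
    cols: list[tuple[str, int]] = []  # expanded op per column
    for op, ln in ops:
        cols.extend([(op, 1)] * ln)
    # Kadane: best-scoring contiguous run of columns
    best_sum = cur_sum = 0
    best = (0, 0)
    cur_start = 0
    for idx, (op, _) in enumerate(cols):
        val = match if op == "=" else (mismatch if op == "X" else gap)
        if cur_sum <= 0:
            cur_sum = val
            cur_start = idx
        else:
            cur_sum += val
        if cur_sum > best_sum:
            best_sum = cur_sum
            best = (cur_start, idx + 1)
    if best_sum <= 0:
        return None
    c0, c1 = best
    # walk columns to recover coordinates and counts
    qpos, spos = qa, sa
    qs = ss = None
    mat = mis = gaps = gap_opens = 0
    prev_gap_op = ""
    for idx, (op, _) in enumerate(cols[:c1]):
        inside = idx >= c0
        if inside and qs is None:
            qs, ss = qpos, spos
        if op == "=" or op == "X":
            if inside:
                if op == "=":
                    mat += 1
                else:
                    mis += 1
                prev_gap_op = ""
            qpos += 1
            spos += 1
        elif op == "I":
            if inside:
                gaps += 1
                if prev_gap_op != "I":
                    gap_opens += 1
                prev_gap_op = "I"
            qpos += 1
        else:  # 'D'
            if inside:
                gaps += 1
                if prev_gap_op != "D":
                    gap_opens += 1
                prev_gap_op = "D"
            spos += 1
    if qs is None:
        return None
    return best_sum, qs, qpos, ss, spos, mat, mis, gaps, gap_opens


def _seed_extend_align(
    query: str,
    subject: str,
    scoring: ScoringScheme,
    min_score: int,
    seed_k: int,
    query_id: str,
    subject_id: str,
) -> list[LocalAlignment]:
    qcodes = scoring.encode(query)
    scodes = scoring.encode(subject)
    qm, sm = _seed_matches(qcodes, scodes, seed_k)
    raw: list[LocalAlignment] = []
    for chain in _chain_seeds(qm, sm):
        ext = _extend_chain(query, subject, chain, seed_k, scoring)
        if ext is None:
            continue
        score, qs, qe, ss, se, mat, mis, gaps, go = ext
        if score < min_score or mat + mis + gaps == 0:
            continue
        alen = mat + mis + gaps
        raw.append(
            LocalAlignment(
                query_id=query_id,
                subject_id=subject_id,
                percent_identity=100.0 * mat / alen,
                alignment_length=alen,
                mismatches=mis,
                gap_opens=go,
                query_start=qs + 1,
                query_end=qe,
                subject_start=ss + 1,
                subject_end=se,
                evalue=scoring.evalue(score, len(query), len(subject)),
                bitscore=scoring.bitscore(score),
                score=score,
                matches=mat,
                gaps=gaps,
            )
        )
    # keep best-scoring, drop alignments mostly overlapping a kept one
    raw.sort(key=lambda a: (-a.score, a.query_start))
    kept: list[LocalAlignment] = []
    for aln in raw:
        a0, a1 = aln.query_span
        redundant = False
        for other in kept:
            b0, b1 = other.query_span
            ov = min(a1, b1) - max(a0, b0)
            if ov > 0.5 * (a1 - a0):
                redundant = True
                break
        if not redundant:
            kept.append(aln)
    kept.sort(key=lambda a: a.query_start)
    return kept


def local_align(
    query: str,
    subject: str,
    scoring: ScoringScheme = NUCLEOTIDE,
    *,
    min_score: int = 25,
    max_alignments: int = 50,
    max_dp_cells: int = 400_000,
    seed_k: int = 13,
    query_id: str = "query",
    subject_id: str = "subject",
) -> list[LocalAlignment]:
    """Maximal non-overlapping local alignments between two sequences.

    Pairs whose DP matrix fits in ``max_dp_cells`` are solved with the
    exact Smith-Waterman recurrence (linear gap penalty); larger pairs go
    through k-mer seeding, colinear chaining and edlib-based extension with
    local trimming.  Alignments scoring below ``min_score`` are dropped and
    reported alignments never overlap by more than half on the query.
    """
    scoring.validate(query, "query")
    scoring.validate(subject, "subject")
    if len(query) * len(subject) <= max_dp_cells:
        return _dp_local_align(
            scoring.encode(query),
            scoring.encode(subject),
            scoring,
            min_score,
            max_alignments,
            len(query),
            len(subject),
            query_id,
            subject_id,
        )
    if scoring.alphabet != "nt":
        raise ValueError(
            "seed-and-extend route supports nucleotide sequences only; "
            "protein pair exceeds max_dp_cells"
        )
    return _seed_extend_align(
        query, subject, scoring, min_score, seed_k, query_id, subject_id
    )


# ---------------------------------------------------------------------------
# ANI
# ---------------------------------------------------------------------------

def compute_ani(
    seq_a: str,
    seq_b: str,
    *,
    min_len: int = 500,
    min_aln_len: int = 100,
    min_identity: float = 30.0,
    min_score: int = 25,
) -> AniResult:
    """Average nucleotide identity between two sequences.

    ANI is the alignment-length-weighted mean identity over local
    alignments of at least ``min_aln_len`` bp and ``min_identity`` percent
    identity; ``aligned_fraction`` is the covered fraction of the shorter
    sequence.  The shorter sequence is always used as the query, which
    makes the result symmetric in its arguments.
    """
    if len(seq_a) < min_len or len(seq_b) < min_len:
        raise ValueError(f"ANI requires sequences of at least {min_len} bp")
    if (len(seq_a), seq_a) <= (len(seq_b), seq_b):
        q, s = seq_a, seq_b
    else:
        q, s = seq_b, seq_a
    alns = [
        a
        for a in local_align(q, s, NUCLEOTIDE, min_score=min_score)
        if a.alignment_length >= min_aln_len and a.percent_identity >= min_identity
    ]
    if not alns:
        return AniResult(ani=None, aligned_fraction=0.0, defined=False)
    total = sum(a.alignment_length for a in alns)
    ani = sum(a.percent_identity * a.alignment_length for a in alns) / total
    intervals = sorted(a.query_span for a in alns)
    covered = 0
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo > cur_hi:
            covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    covered += cur_hi - cur_lo
    return AniResult(
        ani=ani,
        aligned_fraction=min(1.0, covered / len(q)),
        defined=True,
        n_alignments=len(alns),
    )


# ---------------------------------------------------------------------------
# ORF calling
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}  # translation table 11


def find_orfs(scaffold: str, min_len: int = 150, scaffold_id: str = "scaffold") -> list[GeneCall]:
    """Six-frame stop-to-stop ORF calls of at least ``min_len`` nt.

    Open regions are delimited by stop codons (or the sequence ends); when
    a region contains an in-frame ATG the call starts at the first ATG,
    otherwise the full open region is reported.  Translation uses table 11;
    coordinates are 0-based half-open on the forward strand.
    """
    seq = scaffold.upper()
    n = len(seq)
    calls: list[GeneCall] = []
    for strand, s in ((1, seq), (-1, str(Seq(seq).reverse_complement()))):
        for frame in range(3):
            region_start = frame
            pos = frame
            while pos + 3 <= n:
                codon = s[pos : pos + 3]
                if codon in _STOPS:
                    _emit_orf(calls, s, region_start, pos, strand, n, min_len, scaffold_id)
                    region_start = pos + 3
                pos += 3
            _emit_orf(calls, s, region_start, pos, strand, n, min_len, scaffold_id)
    calls.sort(key=lambda c: (c.start, c.end, -c.strand))
    for i, c in enumerate(calls):
        c.gene_id = f"{scaffold_id}_g{i + 1}"
    return calls


def _emit_orf(
    calls: list[GeneCall],
    s: str,
    start: int,
    end: int,
    strand: int,
    n: int,
    min_len: int,
    scaffold_id: str,
) -> None:
    if end - start < min_len:
        return
    sub = s[start:end]
    atg = -1
    for i in range(0, len(sub) - 2, 3):
        if sub[i : i + 3] == "ATG":
            atg = i
            break
    if atg >= 0:
        start = start + atg
        sub = s[start:end]
    if end - start < min_len:
        return
    protein = str(Seq(sub).translate(table=11))
    if strand == 1:
        fwd_start, fwd_end = start, end
    else:
        fwd_start, fwd_end = n - end, n - start
    calls.append(
        GeneCall(
            gene_id="",
            start=fwd_start,
            end=fwd_end,
            strand=strand,
            nucleotide=sub,
            protein=protein,
        )
    )


# ---------------------------------------------------------------------------
# Semi-global search of short queries (edlib inner loop)
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _hit_stats(query: str, subject_region: str) -> tuple[int, int, int, int]:
    res = edlib.align(query, subject_region, mode="NW", task="path")
    mat = mis = gaps = 0
    for op, ln in _cigar_columns(res["cigar"]):
        if op == "=":
            mat += ln
        elif op == "X":
            mis += ln
        else:
            gaps += ln
    return mat, mis, gaps, mat + mis + gaps


def search_all(
    query: str,
    subject: str,
    *,
    max_edit_fraction: float = 0.25,
    both_strands: bool = True,
    max_hits: int = 64,
) -> list[SearchHit]:
    """All semi-global occurrences of ``query`` in ``subject``.

    Edlib HW alignments within ``max_edit_fraction * len(query)`` edits;
    found regions are masked and the search repeated so suboptimal distinct
    occurrences are also reported.
    """
    if not query or not subject:
        return []
    k = int(max_edit_fraction * len(query))
    hits: list[SearchHit] = []
    for strand in (1, -1) if both_strands else (1,):
        q = query if strand == 1 else _revcomp(query)
        work = subject
        for _ in range(max_hits):
            res = edlib.align(q, work, mode="HW", task="locations", k=k)
            if res["editDistance"] < 0 or not res["locations"]:
                break
            seen_spans: list[tuple[int, int]] = []
            for lo, hi in res["locations"]:
                if lo is None:
                    lo = 0
                span = (lo, hi + 1)
                if any(min(span[1], b) - max(span[0], a) > 0 for a, b in seen_spans):
                    continue
                seen_spans.append(span)
                mat, mis, gaps, alen = _hit_stats(q, work[lo : hi + 1])
                hits.append(
                    SearchHit(
                        start=lo,
                        end=hi + 1,
                        strand=strand,
                        matches=mat,
                        mismatches=mis,
                        gaps=gaps,
                        alignment_length=alen,
                    )
                )
            masked = list(work)
            for lo, hi2 in seen_spans:
                masked[lo:hi2] = "N" * (hi2 - lo)
            work = "".join(masked)
    hits.sort(key=lambda h: (h.start, h.end, -h.strand))
    return hits


# ---------------------------------------------------------------------------
# tRNA detection (homology to a bundled canonical set)
# ---------------------------------------------------------------------------

def find_trnas(
    genome: str,
    library: dict[str, str] | None = None,
    *,
    min_identity: float = 90.0,
    min_len: int = 60,
) -> list[TrnaHit]:
    """tRNA loci detected by homology to the bundled canonical tRNA set.

    A locus is reported where a library tRNA aligns at ``min_identity``
    percent identity over at least ``min_len`` bp (either strand).
    """
    if not genome:
        raise ValueError("empty genome sequence")
    if library is None:
        from .trna_library import CANONICAL_TRNAS

        library = CANONICAL_TRNAS
    out: list[TrnaHit] = []
    for name, trna in library.items():
        for hit in search_all(trna, genome, max_edit_fraction=0.15):
            if hit.alignment_length < min_len or hit.identity < min_identity:
                continue
            out.append(
                TrnaHit(
                    name=name,
                    start=hit.start,
                    end=hit.end,
                    strand=hit.strand,
                    identity=hit.identity,
                    length=hit.alignment_length,
                    sequence=genome[hit.start : hit.end],
                )
            )
    out.sort(key=lambda t: (t.start, t.end, t.name))
    return out


# ---------------------------------------------------------------------------
# CRISPR array detection (exact repeats)
# ---------------------------------------------------------------------------

def find_crispr_arrays(
    genome: str,
    genome_id: str = "genome",
    *,
    min_repeats: int = 3,
    repeat_len_range: tuple[int, int] = (23, 47),
    spacer_len_range: tuple[int, int] = (21, 72),
) -> list[CrisprArray]:
    """Maximal arrays of >= ``min_repeats`` exact repeat copies.

    Candidate arrays are seeded from k-mers (k = minimum repeat length)
    occurring in regularly spaced chains, then the repeat is extended to
    its maximal exact common length subject to the configured repeat and
    spacer length bounds.  Spacers are returned in genomic order.
    """
    if not genome:
        raise ValueError("empty genome sequence")
    rep_min, rep_max = repeat_len_range
    sp_min, sp_max = spacer_len_range
    seq = genome.upper()
    n = len(seq)
    k = rep_min
    positions: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        positions.setdefault(kmer, []).append(i)
    gap_lo, gap_hi = rep_min + sp_min, rep_max + sp_max
    seen: set[tuple[int, ...]] = set()
    arrays: list[CrisprArray] = []
    for kmer, pos in positions.items():
        if len(pos) < min_repeats or len(pos) > 200:
            continue
        # maximal runs of regularly spaced occurrences
        run = [pos[0]]
        for p in pos[1:]:
            if gap_lo <= p - run[-1] <= gap_hi:
                run.append(p)
            else:
                if len(run) >= min_repeats:
                    arr = _extend_array(seq, run, k, rep_max, sp_min, sp_max, genome_id)
                    if arr is not None:
                        key = tuple(arr.repeat_starts)
                        if key not in seen:
                            seen.add(key)
                            arrays.append(arr)
                run = [p]
        if len(run) >= min_repeats:
            arr = _extend_array(seq, run, k, rep_max, sp_min, sp_max, genome_id)
            if arr is not None:
                key = tuple(arr.repeat_starts)
                if key not in seen:
                    seen.add(key)
                    arrays.append(arr)
    arrays.sort(key=lambda a: a.repeat_starts[0])
    # offset seeds inside repeats (or chance-shared spacer boundary bases)
    # yield sub-arrays nested in the true array's span: keep the dominant
    # array (more copies, then longer repeat) for each spanned region
    def _span(a: CrisprArray) -> tuple[int, int]:
        return a.repeat_starts[0], a.repeat_starts[-1] + len(a.repeat_sequence)

    def _rank(a: CrisprArray) -> tuple[int, int]:
        return a.repeat_count, len(a.repeat_sequence)

    pruned: list[CrisprArray] = []
    for arr in arrays:
        lo, hi = _span(arr)
        dominated = any(
            other is not arr
            and _span(other)[0] <= lo
            and hi <= _span(other)[1]
            and _rank(other) > _rank(arr)
            for other in arrays
        )
        if not dominated:
            pruned.append(arr)
    return pruned


def _extend_array(
    seq: str,
    starts: list[int],
    k: int,
    rep_max: int,
    sp_min: int,
    sp_max: int,
    genome_id: str,
) -> CrisprArray | None:
    starts = list(starts)
    rep_len = k
    # extend left while all copies agree and spacers stay long enough
    while rep_len < rep_max:
        prev_gaps = [b - (a + rep_len) for a, b in zip(starts, starts[1:])]
        if starts[0] == 0:
            break
        chars = {seq[s - 1] for s in starts}
        if len(chars) != 1:
            break
        if any(g - 1 < sp_min for g in prev_gaps):
            break
        starts = [s - 1 for s in starts]
        rep_len += 1
    # extend right
    while rep_len < rep_max:
        ends = [s + rep_len for s in starts]
        if ends[-1] >= len(seq):
            break
        chars = {seq[e] for e in ends}
        if len(chars) != 1:
            break
        gaps = [b - (a + rep_len + 1) for a, b in zip(starts, starts[1:])]
        if any(g < sp_min for g in gaps):
            break
        rep_len += 1
    gaps = [b - (a + rep_len) for a, b in zip(starts, starts[1:])]
    if any(g < sp_min or g > sp_max for g in gaps):
        return None
    spacers = [seq[a + rep_len : b] for a, b in zip(starts, starts[1:])]
    return CrisprArray(
        genome_id=genome_id,
        repeat_sequence=seq[starts[0] : starts[0] + rep_len],
        repeat_count=len(starts),
        repeat_starts=starts,
        spacers=spacers,
        spacer_starts=[a + rep_len for a in starts[:-1]],
    )
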