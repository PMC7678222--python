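"""Virus-host assignment from three genetic signals with per-rank consensus.

Signals: (i) homology matches of viral scaffolds against host genomes
(>= 300 bp, >= 50% identity, e <= 1e-3); (ii) shared tRNAs, viral tRNA
loci matched to host genomes (>= 60 bp, >= 90% identity, >= 95% query
coverage, <= 10 mismatches, e <= 1e-3); (iii) CRISPR spacers from host
arrays matched against viral scaffolds (>= 95% identity, >= 95% query
coverage, <= 1 mismatch, e <= 1).  All cutoffs inclusive.

Consensus walks the 7 GTDB ranks from domain to species: a rank is
assigned when every implicated host lineage agrees there; the first
conflicting rank and everything deeper is marked ``ambiguous-removed``
(shallower consistent ranks are retained).  An advisory quality ranking of
the competing hosts (by bit-score, identity, mismatches) is available for
manual-style refinement but never overrides consensus by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment_core import (
    NUCLEOTIDE,
    TrnaHit,
    CrisprArray,
    local_align,
    search_all,
)
from .synthetic_community import RANKS, HostGenome

__all__ = [
    "HostSignal",
    "HostPrediction",
    "AMBIGUOUS",
    "homology_host_signal",
    "trna_host_signal",
    "crispr_host_signal",
    "consensus_host",
    "refine_ambiguous_by_quality",
    "predict_hosts",
]

AMBIGUOUS = "ambiguous-removed"

HOMOLOGY_MIN_LENGTH = 300
HOMOLOGY_MIN_IDENTITY = 50.0
HOMOLOGY_MAX_EVALUE = 1e-3

TRNA_MIN_LENGTH = 60
TRNA_MIN_IDENTITY = 90.0
TRNA_MIN_QCOV = 95.0
TRNA_MAX_MISMATCHES = 10
TRNA_MAX_EVALUE = 1e-3

CRISPR_MIN_IDENTITY = 95.0
CRISPR_MIN_QCOV = 95.0
CRISPR_MAX_MISMATCHES = 1
CRISPR_MAX_EVALUE = 1.0


@dataclass
class HostSignal:
    virus_id: str
    host_genome_id: str
    signal_type: str  # homology / trna / crispr
    identity: float
    length: int
    coverage: float  # query coverage, percent
    mismatches: int
    evalue: float
    bitscore: float


@dataclass
class HostPrediction:
    virus_id: str
    ranks: dict[str, str | None] = field(default_factory=dict)
    supporting: dict[str, list[HostSignal]] = field(default_factory=dict)

    @property
    def deepest_assigned(self) -> str | None:
        last = None
        for r in RANKS:
            v = self.ranks.get(r)
            if v is None or v == AMBIGUOUS:
                break
            last = r
        return last


def _nt_score(matches: int, mismatches: int, gaps: int) -> int:
    return matches - 2 * mismatches - 2 * gaps


def homology_host_signal(
    viruses: dict[str, str], hosts: list[HostGenome]
) -> list[HostSignal]:
    """Nucleotide homology matches of viral scaffolds to host genomes."""
    out: list[HostSignal] = []
    for vid, vseq in viruses.items():
        for host in hosts:
            for aln in local_align(
                vseq, host.sequence, NUCLEOTIDE, min_score=50,
                query_id=vid, subject_id=host.genome_id,
            ):
                if (
                    aln.alignment_length >= HOMOLOGY_MIN_LENGTH
                    and aln.percent_identity >= HOMOLOGY_MIN_IDENTITY
                    and aln.evalue <= HOMOLOGY_MAX_EVALUE
                ):
                    out.append(
                        HostSignal(
                            virus_id=vid,
                            host_genome_id=host.genome_id,
                            signal_type="homology",
                            identity=aln.percent_identity,
                            length=aln.alignment_length,
                            coverage=100.0
                            * (aln.query_end - aln.query_start + 1)
                            / len(vseq),
                            mismatches=aln.mismatches,
                            evalue=aln.evalue,
                            bitscore=aln.bitscore,
                        )
                    )
    return out


def trna_host_signal(
    virus_trnas: dict[str, list[TrnaHit]], hosts: list[HostGenome]
) -> list[HostSignal]:
    """Shared-tRNA signals: viral tRNA loci matched into host genomes."""
    out: list[HostSignal] = []
    for vid, loci in virus_trnas.items():
        for locus in loci:
            q = locus.sequence
            for host in hosts:
                for hit in search_all(q, host.sequence, max_edit_fraction=0.2):
                    qcov = 100.0 * (hit.matches + hit.mismatches) / len(q)
                    score = _nt_score(hit.matches, hit.mismatches, hit.gaps)
                    ev = NUCLEOTIDE.evalue(score, len(q), len(host.sequence))
                    if (
                        hit.alignment_length >= TRNA_MIN_LENGTH
                        and hit.identity >= TRNA_MIN_IDENTITY
                        and qcov >= TRNA_MIN_QCOV
                        and hit.mismatches <= TRNA_MAX_MISMATCHES
                        and ev <= TRNA_MAX_EVALUE
                    ):
                        out.append(
                            HostSignal(
                                virus_id=vid,
                                host_genome_id=host.genome_id,
                                signal_type="trna",
                                identity=hit.identity,
                                length=hit.alignment_length,
                                coverage=qcov,
                                mismatches=hit.mismatches,
                                evalue=ev,
                                bitscore=NUCLEOTIDE.bitscore(score),
                            )
                        )
    return out


def crispr_host_signal(
    host_arrays: dict[str, list[CrisprArray]], viruses: dict[str, str]
) -> list[HostSignal]:
    """CRISPR-spacer signals: host array spacers matched against viruses."""
    out: list[HostSignal] = []
    for host_id, arrays in host_arrays.items():
        for arr in arrays:
            for spacer in arr.spacers:
                for vid, vseq in viruses.items():
                    for hit in search_all(spacer, vseq, max_edit_fraction=0.15):
                        qcov = 100.0 * (hit.matches + hit.mismatches) / len(spacer)
                        score = _nt_score(hit.matches, hit.mismatches, hit.gaps)
                        ev = NUCLEOTIDE.evalue(score, len(spacer), len(vseq))
                        if (
                            hit.identity >= CRISPR_MIN_IDENTITY
                            and qcov >= CRISPR_MIN_QCOV
                            and hit.mismatches <= CRISPR_MAX_MISMATCHES
                            and ev <= CRISPR_MAX_EVALUE
                        ):
                            out.append(
                                HostSignal(
                                    virus_id=vid,
                                    host_genome_id=host_id,
                                    signal_type="crispr",
                                    identity=hit.identity,
                                    length=hit.alignment_length,
                                    coverage=qcov,
                                    mismatches=hit.mismatches,
                                    evalue=ev,
                                    bitscore=NUCLEOTIDE.bitscore(score),
                                )
                            )
    return out


def consensus_host(
    signals: list[HostSignal], host_taxonomy: dict[str, str], virus_id: str
) -> HostPrediction | None:
    """Per-rank consensus over all hosts implicated for one virus.

    At each rank from domain downward the prediction is the single taxon
    shared by every implicated host lineage; at the first rank where the
    lineages disagree, that rank and all deeper ranks are marked
    ``ambiguous-removed``.  Returns ``None`` when the virus has no signals.
    """
    mine = [s for s in signals if s.virus_id == virus_id]
    if not mine:
        return None
    lineages = {}
    for s in mine:
        if s.host_genome_id not in host_taxonomy:
            raise KeyError(f"unknown host genome {s.host_genome_id!r}")
        lineages[s.host_genome_id] = host_taxonomy[s.host_genome_id].split(";")
    pred = HostPrediction(virus_id=virus_id)
    ambiguous = False
    for i, rank in enumerate(RANKS):
        if ambiguous:
            pred.ranks[rank] = AMBIGUOUS
            continue
        taxa = {lin[i] for lin in lineages.values()}
        if len(taxa) == 1:
            pred.ranks[rank] = taxa.pop()
            pred.supporting[rank] = mine
        else:
            ambiguous = True
            pred.ranks[rank] = AMBIGUOUS
    return pred


def refine_ambiguous_by_quality(
    signals: list[HostSignal],
) -> list[tuple[str, float, float, float]]:
    """Advisory ranking of competing hosts for one virus.

    Hosts ordered by descending max bit-score, then descending mean
    identity, then ascending mean mismatch count, then host id.  Returned
    as (host_genome_id, max_bitscore, mean_identity, mean_mismatches); the
    caller may promote the top candidate, consensus is never overridden
    automatically.
    """
    by_host: dict[str, list[HostSignal]] = {}
    for s in signals:
        by_host.setdefault(s.host_genome_id, []).append(s)
    rows = [
        (
            host,
            float(max(s.bitscore for s in ss)),
            float(np.mean([s.identity for s in ss])),
            float(np.mean([s.mismatches for s in ss])),
        )
        for host, ss in by_host.items()
    ]
    rows.sort(key=lambda r: (-r[1], -r[2], r[3], r[0]))
    return rows


def predict_hosts(
    viruses: dict[str, str],
    hosts: list[HostGenome],
    host_taxonomy: dict[str, str],
    *,
    virus_trnas: dict[str, list[TrnaHit]] | None = None,
    host_arrays: dict[str, list[CrisprArray]] | None = None,
) -> tuple[dict[str, HostPrediction], list[HostSignal]]:
    """All three signals plus consensus for every virus.

    tRNA loci and CRISPR arrays are detected with the alignment core when
    not supplied.  Returns (predictions keyed by virus id, all signals).
    """
    from .alignment_core import find_crispr_arrays, find_trnas

    if virus_trnas is None:
        virus_trnas = {vid: find_trnas(seq) for vid, seq in viruses.items()}
    if host_arrays is None:
        host_arrays = {
            h.genome_id: find_crispr_arrays(h.sequence, h.genome_id) for h in hosts
        }
    signals = (
        homology_host_signal(viruses, hosts)
        + trna_host_signal(virus_trnas, hosts)
        + crispr_host_signal(host_arrays, viruses)
    )
    predictions: dict[str, HostPrediction] = {}
    for vid in viruses:
        pred = consensus_host(signals, host_taxonomy, vid)
        if pred is not None:
            predictions[vid] = pred
    return predictions, signals
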