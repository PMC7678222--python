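"""Viral population clustering and closest-relative taxonomy.

Bona fide viral scaffolds are clustered into species-like populations
sharing >= 80% of genes at >= 95% average nucleotide identity, by greedy
representative linkage over scaffolds sorted by decreasing length.
Taxonomy is assigned per scaffold by closest-relative voting over filtered
protein hits: the winning taxon matches the most proteins, ties resolved
by the higher mean identity, then lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .alignment_core import GeneCall, LocalAlignment, _cigar_columns, compute_ani

__all__ = [
    "ViralPopulation",
    "ClosestRelativeCall",
    "shared_gene_fraction",
    "cluster_populations",
    "filter_protein_hits",
    "assign_taxonomy_closest_relative",
]

MIN_POPULATION_ANI = 95.0
MIN_SHARED_GENE_FRACTION = 0.8

# protein-hit filter thresholds (all inclusive)
HIT_MIN_IDENTITY = 30.0
HIT_MIN_BITSCORE = 50.0
HIT_MIN_ALIGNMENT_LENGTH = 30
HIT_MAX_EVALUE = 1e-5


@dataclass
class ViralPopulation:
    population_id: str
    members: list[str]
    representative: str


@dataclass
class ClosestRelativeCall:
    scaffold_id: str
    taxon: str
    n_matched_proteins: int
    mean_identity: float
    competing: dict[str, int] = field(default_factory=dict)


def _gene_matches_scaffold(
    gene_seq: str, scaffold: str, min_identity: float, min_cov: float
) -> bool:
    """A gene is shared when some alignment window covering >= ``min_cov``
    of its length reaches >= ``min_identity`` percent identity (either
    strand).  The gene is aligned semi-globally into the scaffold with
    edlib; windows of the alignment consuming at least ``min_cov * len``
    gene positions are scanned for one meeting the identity bar."""
    glen = len(gene_seq)
    target = min_cov * glen
    budget = int(glen * (1.0 - min_cov) + glen * (1.0 - min_identity / 100.0) * 2) + 1
    from .alignment_core import _revcomp

    for q in (gene_seq, _revcomp(gene_seq)):
        res = edlib.align(q, scaffold, mode="HW", task="path", k=budget)
        if res["editDistance"] < 0:
            continue
        ops: list[str] = []
        for op, ln in _cigar_columns(res["cigar"]):
            ops.extend(op * ln)
        n = len(ops)
        # prefix sums: matches and query-consumed columns
        mat = np.zeros(n + 1, dtype=np.int64)
        qcons = np.zeros(n + 1, dtype=np.int64)
        for i, op in enumerate(ops):
            mat[i + 1] = mat[i] + (op == "=")
            qcons[i + 1] = qcons[i] + (op in "=XI")
        # minimal window starting at each column that covers the target
        j = 0
        for i in range(n):
            if j < i:
                j = i
            while j <= n and qcons[j] - qcons[i] < target:
                j += 1
            if j > n:
                break
            w_mat = mat[j] - mat[i]
            w_len = j - i
            if w_len > 0 and 100.0 * w_mat / w_len >= min_identity:
                return True
    return False


def shared_gene_fraction(
    genes_a: list[GeneCall],
    genes_b: list[GeneCall],
    seq_a: str,
    seq_b: str,
    *,
    min_identity: float = 95.0,
    min_coverage: float = 0.8,
    denominator: str = "fewer",
) -> float:
    """Fraction of shared genes between two scaffolds.

    The scaffold with fewer gene calls provides both the query genes and
    the denominator (``denominator="fewer"``, default), so that fragments
    of one genome are not penalised for missing genes; ``"query"`` uses
    ``genes_a`` / ``seq_b`` instead.
    """
    if not genes_a or not genes_b:
        raise ValueError("both scaffolds need at least one gene call")
    if denominator == "fewer":
        if len(genes_a) <= len(genes_b):
            query_genes, target = genes_a, seq_b
        else:
            query_genes, target = genes_b, seq_a
    elif denominator == "query":
        query_genes, target = genes_a, seq_b
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    shared = sum(
        1
        for g in query_genes
        if _gene_matches_scaffold(g.nucleotide, target, min_identity, min_coverage)
    )
    return shared / len(query_genes)


def cluster_populations(
    scaffolds: dict[str, str],
    genes: dict[str, list[GeneCall]],
    *,
    min_ani: float = MIN_POPULATION_ANI,
    min_shared: float = MIN_SHARED_GENE_FRACTION,
) -> list[ViralPopulation]:
    """Greedy representative-linkage clustering into viral populations.

    Scaffolds are visited by decreasing length (ties by id); each joins
    the first existing population whose representative reaches both the
    ANI and shared-gene thresholds, else seeds a new population.  The
    representative is the longest (hence first) member.  Deterministic and
    independent of input dict order.
    """
    order = sorted(scaffolds, key=lambda s: (-len(scaffolds[s]), s))
    populations: list[ViralPopulation] = []
    for sid in order:
        placed = False
        for pop in populations:
            rep = pop.representative
            ani = compute_ani(scaffolds[sid], scaffolds[rep])
            if not ani.defined or ani.ani < min_ani:
                continue
            if not genes.get(sid) or not genes.get(rep):
                continue
            sgf = shared_gene_fraction(
                genes[sid], genes[rep], scaffolds[sid], scaffolds[rep]
            )
            if sgf >= min_shared:
                pop.members.append(sid)
                placed = True
                break
        if not placed:
            populations.append(
                ViralPopulation(
                    population_id=f"VP_{len(populations) + 1}",
                    members=[sid],
                    representative=sid,
                )
            )
    return populations


def filter_protein_hits(hits: list[LocalAlignment]) -> list[LocalAlignment]:
    """Retain protein hits meeting all four inclusive thresholds:
    identity >= 30%, bit-score >= 50, alignment length >= 30 aa,
    e-value <= 1e-5."""
    return [
        h
        for h in hits
        if h.percent_identity >= HIT_MIN_IDENTITY
        and h.bitscore >= HIT_MIN_BITSCORE
        and h.alignment_length >= HIT_MIN_ALIGNMENT_LENGTH
        and h.evalue <= HIT_MAX_EVALUE
    ]


def assign_taxonomy_closest_relative(
    hits: list[LocalAlignment],
    subject_taxonomy: dict[str, str],
    scaffold_id: str = "scaffold",
) -> ClosestRelativeCall | None:
    """Closest-relative taxonomy of one scaffold from its filtered hits.

    ``hits`` are protein-space alignments whose ``query_id`` is a protein
    of the scaffold and whose ``subject_id`` maps to a taxon.  Per protein
    and taxon only the best hit (highest bit-score) is counted; the
    winning taxon matches the most proteins, ties resolved by higher mean
    identity then lexicographically smaller name.  Returns ``None`` when
    there are no hits.
    """
    if not hits:
        return None
    best: dict[tuple[str, str], LocalAlignment] = {}
    for h in hits:
        taxon = subject_taxonomy.get(h.subject_id)
        if taxon is None:
            raise KeyError(f"no taxonomy for subject {h.subject_id!r}")
        key = (h.query_id, taxon)
        if key not in best or h.bitscore > best[key].bitscore:
            best[key] = h
    per_taxon: dict[str, list[LocalAlignment]] = {}
    for (_, taxon), h in best.items():
        per_taxon.setdefault(taxon, []).append(h)
    scored = [
        (len(hs), float(np.mean([h.percent_identity for h in hs])), taxon)
        for taxon, hs in per_taxon.items()
    ]
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    n, mean_id, taxon = scored[0]
    return ClosestRelativeCall(
        scaffold_id=scaffold_id,
        taxon=taxon,
        n_matched_proteins=n,
        mean_identity=mean_id,
        competing={t: c for c, _, t in scored},
    )


def populations_table(populations: list[ViralPopulation]) -> pd.DataFrame:
    rows = [
        {
            "scaffold_id": member,
            "population_id": pop.population_id,
            "representative": pop.representative,
            "n_members": len(pop.members),
        }
        for pop in populations
        for member in pop.members
    ]
    return pd.DataFrame(rows).set_index("scaffold_id")
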