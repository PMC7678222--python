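"""Three-channel identification of putative viral scaffolds.

A scaffold from a cellular metagenome is called a putative virus when any
of three evidence channels fires: a virus-sorter category of 1 or 2, a
virus-finder score >= 0.7 with p <= 0.05, or at least 20% of its proteins
matching pVOGs with an added viral quotient (AVQ) >= 2.  The AVQ of a
scaffold is the sum of the viral quotients of the pVOGs hit by its
proteins (best hit per protein by default).  A deterministic curation rule
stands in for manual inspection: a putative virus is retained as bona fide
when it encodes a hallmark viral gene (capsid, terminase, portal, tail,
baseplate, integrase, holin) or when at least half of its proteins carry
no non-viral annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ViralEvidence",
    "PvogMatch",
    "HALLMARK_GENES",
    "compute_avq",
    "classify_putative_viral",
    "curate_bona_fide",
    "identify_bona_fide",
]

#: Hallmark viral gene terms used by the curation rule (lower-case substrings).
HALLMARK_GENES = (
    "capsid",
    "terminase",
    "portal",
    "tail",
    "baseplate",
    "integrase",
    "holin",
)

SORTER_VIRAL_CATEGORIES = (1, 2)
FINDER_MIN_SCORE = 0.7
FINDER_MAX_P = 0.05
PVOG_MIN_FRACTION = 0.20
MIN_AVQ = 2.0
PVOG_MAX_EVALUE = 1e-5


@dataclass
class PvogMatch:
    protein_id: str
    pvog_id: str
    evalue: float
    viral_quotient: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.viral_quotient <= 1.0:
            raise ValueError("viral_quotient must be in [0, 1]")
        if self.evalue > PVOG_MAX_EVALUE:
            raise ValueError(f"pVOG match e-value exceeds the {PVOG_MAX_EVALUE} cap")


@dataclass
class ViralEvidence:
    """Per-scaffold identification signals; missing channels are ``None``."""

    scaffold_id: str
    sorter_category: int | None = None
    finder_score: float | None = None
    finder_p: float | None = None
    n_proteins: int = 0
    n_pvog_proteins: int = 0
    avq: float = 0.0

    @property
    def pvog_fraction(self) -> float:
        if self.n_proteins <= 0:
            return 0.0
        return self.n_pvog_proteins / self.n_proteins


def compute_avq(
    matches: list[PvogMatch], n_proteins: int, mode: str = "best_hit"
) -> tuple[float, float]:
    """pVOG-matched protein fraction and added viral quotient of a scaffold.

    In ``best_hit`` mode (default) each protein contributes the viral
    quotient of its lowest-e-value pVOG hit (ties broken toward the higher
    quotient); ``sum_all`` sums every hit.  Returns ``(fraction, avq)``.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if mode not in ("best_hit", "sum_all"):
        raise ValueError(f"unknown AVQ mode {mode!r}")
    if not matches:
        return 0.0, 0.0
    by_protein: dict[str, list[PvogMatch]] = {}
    for m in matches:
        by_protein.setdefault(m.protein_id, []).append(m)
    # summation in sorted protein order keeps the result exactly
    # permutation-invariant in the match list
    if mode == "sum_all":
        avq = sum(
            m.viral_quotient
            for pid in sorted(by_protein)
            for m in sorted(by_protein[pid], key=lambda m: (m.evalue, -m.viral_quotient))
        )
    else:
        avq = 0.0
        for pid in sorted(by_protein):
            best = min(
                by_protein[pid], key=lambda m: (m.evalue, -m.viral_quotient)
            )
            avq += best.viral_quotient
    fraction = len(by_protein) / n_proteins
    return fraction, avq


def classify_putative_viral(ev: ViralEvidence) -> tuple[bool, list[str]]:
    """Putative-virus decision with the list of channels that fired.

    All thresholds are inclusive; a channel whose fields are missing
    simply does not fire.
    """
    channels: list[str] = []
    if ev.sorter_category is not None and ev.sorter_category in SORTER_VIRAL_CATEGORIES:
        channels.append("sorter")
    if (
        ev.finder_score is not None
        and ev.finder_p is not None
        and ev.finder_score >= FINDER_MIN_SCORE
        and ev.finder_p <= FINDER_MAX_P
    ):
        channels.append("finder")
    if ev.pvog_fraction >= PVOG_MIN_FRACTION and ev.avq >= MIN_AVQ:
        channels.append("pvog")
    return bool(channels), channels


def curate_bona_fide(
    annotations: list[str],
    *,
    hallmark_terms: tuple[str, ...] = HALLMARK_GENES,
    min_hypothetical_fraction: float = 0.5,
) -> bool:
    """Deterministic stand-in for manual bona fide curation.

    ``annotations`` is one functional label per predicted protein.
    Retained when a hallmark viral term occurs in any label, or when the
    fraction of proteins with no informative (non-viral) annotation is at
    least ``min_hypothetical_fraction``.
    """
    if not annotations:
        return False
    lowered = [a.lower() for a in annotations]
    if any(term in a for a in lowered for term in hallmark_terms):
        return True
    n_hyp = sum(
        1 for a in lowered if a in ("", "hypothetical protein", "unknown", "na")
    )
    return n_hyp / len(annotations) >= min_hypothetical_fraction


def evidence_from_tables(
    evidence: pd.DataFrame, pvog_matches: pd.DataFrame, mode: str = "best_hit"
) -> dict[str, ViralEvidence]:
    """Assemble :class:`ViralEvidence` objects from the tabular inputs."""
    by_scaffold: dict[str, list[PvogMatch]] = {}
    for row in pvog_matches.itertuples(index=False):
        by_scaffold.setdefault(row.scaffold_id, []).append(
            PvogMatch(row.protein_id, row.pvog_id, row.evalue, row.viral_quotient)
        )
    out: dict[str, ViralEvidence] = {}
    for row in evidence.itertuples(index=False):
        matches = by_scaffold.get(row.scaffold_id, [])
        n_prot = int(row.n_proteins)
        if matches:
            fraction, avq = compute_avq(matches, n_prot, mode=mode)
            n_hit = len({m.protein_id for m in matches})
        else:
            avq, n_hit = 0.0, 0
        cat = row.sorter_category
        out[row.scaffold_id] = ViralEvidence(
            scaffold_id=row.scaffold_id,
            sorter_category=None if pd.isna(cat) else int(cat),
            finder_score=None if pd.isna(row.finder_score) else float(row.finder_score),
            finder_p=None if pd.isna(row.finder_p) else float(row.finder_p),
            n_proteins=n_prot,
            n_pvog_proteins=n_hit,
            avq=avq,
        )
    return out


def identify_bona_fide(
    evidence: pd.DataFrame,
    pvog_matches: pd.DataFrame,
    annotations: pd.DataFrame,
    *,
    avq_mode: str = "best_hit",
    min_hypothetical_fraction: float = 0.5,
) -> pd.DataFrame:
    """Full identification chain over tabular inputs.

    Returns one row per scaffold with per-channel booleans, the putative
    call, and the bona fide call (putative AND curated).
    """
    ev_objects = evidence_from_tables(evidence, pvog_matches, mode=avq_mode)
    ann_by_scaffold = (
        annotations.groupby("scaffold_id")["annotation"].apply(list).to_dict()
        if len(annotations)
        else {}
    )
    rows = []
    for sid, ev in ev_objects.items():
        putative, channels = classify_putative_viral(ev)
        curated = putative and curate_bona_fide(
            ann_by_scaffold.get(sid, []),
            min_hypothetical_fraction=min_hypothetical_fraction,
        )
        rows.append(
            {
                "scaffold_id": sid,
                "sorter": "sorter" in channels,
                "finder": "finder" in channels,
                "pvog": "pvog" in channels,
                "pvog_fraction": ev.pvog_fraction,
                "avq": ev.avq,
                "putative": putative,
                "bona_fide": curated,
            }
        )
    return pd.DataFrame(rows).set_index("scaffold_id")
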