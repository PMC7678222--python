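"""File formats of the pipeline.

FASTA (70-column wrap) for genomes, scaffolds and proteins; TSV for
taxonomy (genome_id + 7-rank semicolon lineage), evidence, pVOG matches,
annotations and counts; 12-column BLAST outfmt-6 TSV for homology hits;
JSON for the ground truth; YAML for simulation configs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment_core import LocalAlignment
from .synthetic_community import (
    GroundTruth,
    PlantedSignal,
    SampleInfo,
    ScaffoldTruth,
    SimulationConfig,
)

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def write_fasta(sequences: dict[str, str], path: str | Path, wrap: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_taxonomy(taxonomy: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"genome_id": list(taxonomy), "lineage": list(taxonomy.values())}
    ).to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["genome_id"], df["lineage"]))


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_counts(values: pd.DataFrame, path: str | Path) -> None:
    values.to_csv(path, sep="\t", index_label="scaffold_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="scaffold_id")


def hits_to_table(hits: list[LocalAlignment]) -> pd.DataFrame:
    """12-column BLAST outfmt-6 table (1-based inclusive coordinates)."""
    rows = [
        {
            "qseqid": h.query_id,
            "sseqid": h.subject_id,
            "pident": round(h.percent_identity, 3),
            "length": h.alignment_length,
            "mismatch": h.mismatches,
            "gapopen": h.gap_opens,
            "qstart": h.query_start,
            "qend": h.query_end,
            "sstart": h.subject_start,
            "send": h.subject_end,
            "evalue": h.evalue,
            "bitscore": round(h.bitscore, 1),
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)


def table_to_hits(df: pd.DataFrame) -> list[LocalAlignment]:
    out = []
    for r in df.itertuples(index=False):
        alen = int(r.length)
        mis = int(r.mismatch)
        pid = float(r.pident)
        matches = round(pid * alen / 100.0)
        out.append(
            LocalAlignment(
                query_id=str(r.qseqid),
                subject_id=str(r.sseqid),
                percent_identity=pid,
                alignment_length=alen,
                mismatches=mis,
                gap_opens=int(r.gapopen),
                query_start=int(r.qstart),
                query_end=int(r.qend),
                subject_start=int(r.sstart),
                subject_end=int(r.send),
                evalue=float(r.evalue),
                bitscore=float(r.bitscore),
                matches=matches,
                gaps=alen - matches - mis,
            )
        )
    return out


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "scaffolds": {
            sid: {
                "is_viral": st.is_viral,
                "population_id": st.population_id,
                "host_genome_id": st.host_genome_id,
                "planted_signals": [dataclasses.asdict(s) for s in st.planted_signals],
                "planted_channels": st.planted_channels,
            }
            for sid, st in truth.scaffolds.items()
        },
        "samples": {
            sid: dataclasses.asdict(info) for sid, info in truth.samples.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    truth = GroundTruth()
    for sid, d in payload["scaffolds"].items():
        truth.scaffolds[sid] = ScaffoldTruth(
            scaffold_id=sid,
            is_viral=d["is_viral"],
            population_id=d["population_id"],
            host_genome_id=d["host_genome_id"],
            planted_signals=[PlantedSignal(**s) for s in d["planted_signals"]],
            planted_channels=d["planted_channels"],
        )
    for sid, d in payload["samples"].items():
        truth.samples[sid] = SampleInfo(**d)
    return truth


def write_config(cfg: SimulationConfig, path: str | Path) -> None:
    d = dataclasses.asdict(cfg)
    if d.get("samples"):
        d["samples"] = [dataclasses.asdict(s) if dataclasses.is_dataclass(s) else s for s in cfg.samples]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_config(path: str | Path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    if d.get("samples"):
        d["samples"] = [SampleInfo(**s) for s in d["samples"]]
    for key in (
        "host_length_range", "viral_length_range", "decoy_length_range",
        "gene_length_range", "gc_range", "homology_segment_length",
        "spacer_length_range",
    ):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
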