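#!/usr/bin/env python
"""Identify putative and bona fide viral scaffolds from the evidence tables.

Applies the three-channel rule (sorter category 1-2; finder score >= 0.7 &
p <= 0.05; >= 20% of proteins on pVOGs with AVQ >= 2) plus the hallmark /
hypothetical-enrichment curation rule, then scores the calls against the
generator's ground truth.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from lakevir import io
from lakevir.viral_identification import identify_bona_fide


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--community", type=Path, default=Path("results/community"))
    ap.add_argument("--out", type=Path, default=Path("results/identification_calls.tsv"))
    args = ap.parse_args()

    evidence = io.read_table(args.community / "evidence.tsv")
    pvog = io.read_table(args.community / "pvog_matches.tsv")
    annotations = io.read_table(args.community / "annotations.tsv")
    truth = io.read_ground_truth(args.community / "ground_truth.json")

    calls = identify_bona_fide(evidence, pvog, annotations)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    io.write_table(calls.reset_index(), args.out)

    called = set(calls.index[calls["bona_fide"]])
    planted = set(truth.viral_ids())
    tp = len(called & planted)
    precision = tp / len(called) if called else float("nan")
    recall = tp / len(planted)
    print(f"bona fide calls: {len(called)} / {len(calls)} scaffolds")
    print(f"precision vs ground truth: {precision:.3f}   recall: {recall:.3f}")
    per_channel = calls[["sorter", "finder", "pvog"]].sum()
    print("channel contributions:", dict(per_channel))


if __name__ == "__main__":
    main()
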