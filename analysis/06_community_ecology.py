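#!/usr/bin/env python
"""Community ecology of the synthetic lake: diversity, ordination, structure.

From the count matrix: per-sample Shannon/Simpson diversity, Bray-Curtis
dissimilarities, average-linkage dendrogram, NMDS ordination, population-
grouped abundances with a 0.5% display floor, and paired photic/aphotic vs
winter/summer scatter tables.  Figures are written alongside the tables.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram

from lakevir import io
from lakevir.community_ecology import (
    AbundanceMatrix,
    bray_curtis_matrix,
    group_abundance,
    hierarchical_cluster,
    nmds,
    paired_zone_season_scatter,
    relative_abundance,
    shannon,
    simpson,
    zscore_rows,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--community", type=Path, default=Path("results/community"))
    ap.add_argument("--populations", type=Path, default=Path("results/populations.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results/ecology"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    counts = io.read_counts(args.community / "counts.tsv")
    meta = io.read_table(args.community / "samples.tsv").set_index("sample_id")
    truth = io.read_ground_truth(args.community / "ground_truth.json")
    mat = AbundanceMatrix(values=counts, metadata=meta, kind="counts")
    rel = relative_abundance(mat)

    # restrict community structure analyses to the viral fraction
    viral_ids = [s for s in rel.values.index if truth.scaffolds[s].is_viral]
    rel_vir = AbundanceMatrix(
        values=rel.values.loc[viral_ids], metadata=meta, kind="relative"
    )

    div = pd.DataFrame(
        {
            "sample_id": rel_vir.sample_ids,
            "shannon": [shannon(rel.values[c] / rel.values[c].sum()) for c in rel.sample_ids],
            "simpson": [simpson(rel.values[c] / rel.values[c].sum()) for c in rel.sample_ids],
            "zone": [meta.loc[c, "zone"] for c in rel.sample_ids],
            "season": [meta.loc[c, "season"] for c in rel.sample_ids],
        }
    )
    io.write_table(div, out / "diversity.tsv")
    print("Shannon range: %.2f-%.2f   Simpson range: %.4f-%.4f"
          % (div.shannon.min(), div.shannon.max(), div.simpson.min(), div.simpson.max()))

    bc = bray_curtis_matrix(rel_vir)
    bc.to_csv(out / "bray_curtis.tsv", sep="\t")
    Z, leaf_order = hierarchical_cluster(bc)
    print("dendrogram leaf order:", leaf_order)

    res = nmds(bc, seed=args.seed)
    coords = pd.DataFrame(
        res.coordinates, index=res.sample_ids, columns=["NMDS1", "NMDS2"]
    )
    coords.to_csv(out / "nmds_coordinates.tsv", sep="\t", index_label="sample_id")
    print(f"NMDS stress: {res.stress:.4f}")

    # abundances grouped by viral population (0.5% display floor)
    pops = io.read_table(args.populations)
    grouping = dict(zip(pops["scaffold_id"], pops["population_id"]))
    grouped = group_abundance(rel_vir, grouping, display_min=0.005)
    grouped.to_csv(out / "population_abundance.tsv", sep="\t", index_label="group")

    # paired depth / season comparisons
    zone_pairs = [
        ("photic_5m_winter", "aphotic_1250m_winter"),
        ("photic_5m_summer", "aphotic_1250m_summer"),
        ("photic_20m_winter", "aphotic_1350m_winter"),
        ("photic_20m_summer", "aphotic_1350m_summer"),
    ]
    season_pairs = [
        ("photic_5m_winter", "photic_5m_summer"),
        ("photic_20m_winter", "photic_20m_summer"),
        ("aphotic_1250m_winter", "aphotic_1250m_summer"),
        ("aphotic_1350m_winter", "aphotic_1350m_summer"),
    ]
    tz = paired_zone_season_scatter(rel_vir, zone_pairs)
    ts = paired_zone_season_scatter(rel_vir, season_pairs)
    io.write_table(tz, out / "paired_zone.tsv")
    io.write_table(ts, out / "paired_season.tsv")
    print(
        "mean |log2 ratio| depth pairing: %.2f   season pairing: %.2f"
        % (tz.log2_ratio.abs().mean(), ts.log2_ratio.abs().mean())
    )

    # figures
    fig, ax = plt.subplots(figsize=(7, 4))
    dendrogram(Z, labels=list(bc.index), ax=ax, leaf_rotation=90)
    ax.set_ylabel("Bray-Curtis height")
    fig.tight_layout()
    fig.savefig(out / "dendrogram.png", dpi=120)

    fig, ax = plt.subplots(figsize=(5, 4))
    for zone, marker in (("photic", "o"), ("aphotic", "s")):
        mask = [meta.loc[s, "zone"] == zone for s in coords.index]
        ax.scatter(coords.NMDS1[mask], coords.NMDS2[mask], marker=marker, label=zone)
    ax.legend()
    ax.set_xlabel("NMDS1")
    ax.set_ylabel("NMDS2")
    fig.tight_layout()
    fig.savefig(out / "nmds.png", dpi=120)

    z = zscore_rows(rel_vir)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.imshow(z.values.loc[:, leaf_order].to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(leaf_order)), leaf_order, rotation=90, fontsize=6)
    ax.set_ylabel("viral scaffolds (Z-scored abundance)")
    fig.tight_layout()
    fig.savefig(out / "abundance_heatmap.png", dpi=120)
    print(f"tables and figures written to {out}")


if __name__ == "__main__":
    main()
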