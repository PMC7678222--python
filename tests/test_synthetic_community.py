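from __future__ import annotations

import itertools

import numpy as np
import pytest

from lakevir.community_ecology import bray_curtis, relative_abundance
from lakevir.io import read_counts, write_counts
from lakevir.synthetic_community import (
    SimulationConfig,
    generate_count_matrix,
    generate_host_genomes,
    generate_tool_evidence,
    generate_viral_scaffolds,
    simulate_community,
)


def _tiny_cfg(**kw) -> SimulationConfig:
    base = dict(
        seed=1,
        n_host_genomes=3,
        n_viral_populations=3,
        members_per_population=2,
        host_length_range=(50_000, 60_000),
        viral_length_range=(15_000, 20_000),
        n_decoys=4,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            _tiny_cfg(n_host_genomes=0)
        with pytest.raises(ValueError):
            _tiny_cfg(members_per_population=0)
        with pytest.raises(ValueError):
            _tiny_cfg(n_samples=1)

    def test_rejects_divergence_ordering_violation(self):
        with pytest.raises(ValueError):
            _tiny_cfg(within_population_divergence=0.06)
        with pytest.raises(ValueError):
            _tiny_cfg(between_population_divergence=0.04)


class TestHostGenomes:
    def test_construction_guarantees(self):
        hosts, taxonomy = generate_host_genomes(_tiny_cfg())
        assert len(hosts) == 3
        genera = set()
        for h in hosts:
            assert len(h.arrays) >= 1
            assert len(h.trnas) >= 5
            assert 50_000 <= len(h.sequence)
            ranks = h.lineage.split(";")
            assert len(ranks) == 7
            genera.add(ranks[5])
        assert len(genera) == 3  # distinct at genus level

    def test_seeded_determinism_is_byte_identical(self):
        cfg = _tiny_cfg()
        h1, _ = generate_host_genomes(cfg)
        h2, _ = generate_host_genomes(_tiny_cfg())
        assert [h.sequence for h in h1] == [h.sequence for h in h2]

    def test_planted_features_at_recorded_coordinates(self):
        hosts, _ = generate_host_genomes(_tiny_cfg(seed=9))
        from lakevir.trna_library import CANONICAL_TRNAS

        for h in hosts:
            for name, pos in h.trnas:
                expected = CANONICAL_TRNAS[name]
                assert h.sequence[pos : pos + len(expected)] == expected
            for arr in h.arrays:
                assert h.sequence[arr.start : arr.start + len(arr.content)] == arr.content


class TestViralScaffolds:
    def test_ground_truth_is_exhaustive(self, small_community):
        com = small_community
        assert set(com.scaffolds) == set(com.truth.scaffolds)

    def test_full_link_fraction_gives_every_virus_a_signal(self):
        cfg = _tiny_cfg(host_link_fraction=1.0)
        hosts, _ = generate_host_genomes(cfg)
        _, truth = generate_viral_scaffolds(cfg, hosts)
        for vid in truth.viral_ids():
            assert len(truth.scaffolds[vid].planted_signals) >= 1

    def test_planted_spacer_matches_virus_subsequence_and_host_array(self):
        cfg = _tiny_cfg(host_link_fraction=1.0, seed=3)
        hosts, _ = generate_host_genomes(cfg)
        scaffolds, truth = generate_viral_scaffolds(cfg, hosts)
        host_by_id = {h.genome_id: h for h in hosts}
        n_checked = 0
        for vid in truth.viral_ids():
            for sig in truth.scaffolds[vid].planted_signals:
                if sig.signal_type != "crispr":
                    continue
                assert sig.sequence in scaffolds[vid]
                host = host_by_id[sig.host_genome_id]
                assert any(sig.sequence in arr.spacers for arr in host.arrays)
                assert sig.sequence in host.sequence
                n_checked += 1
        assert n_checked > 0

    def test_intra_population_ani_above_95_by_construction(self, small_community):
        from lakevir.alignment_core import compute_ani

        com = small_community
        by_pop: dict[str, list[str]] = {}
        for vid in com.truth.viral_ids():
            by_pop.setdefault(com.truth.scaffolds[vid].population_id, []).append(vid)
        members = next(iter(by_pop.values()))
        for a, b in itertools.combinations(members[:3], 2):
            r = compute_ani(com.scaffolds[a], com.scaffolds[b])
            assert r.defined and r.ani >= 95.0

    def test_decoys_are_host_fragments(self, small_community):
        com = small_community
        host_by_id = {h.genome_id: h for h in com.hosts}
        cells = com.truth.cellular_ids()
        assert cells
        for did in cells[:3]:
            src = com.truth.scaffolds[did].host_genome_id
            assert com.scaffolds[did] in host_by_id[src].sequence


class TestToolEvidence:
    def test_full_sensitivity_every_virus_passes_a_channel(self, small_community):
        com = small_community
        for vid in com.truth.viral_ids():
            assert any(com.truth.scaffolds[vid].planted_channels.values())

    def test_zero_sensitivity_nothing_fires(self):
        cfg = _tiny_cfg(
            sorter_sensitivity=0.0, finder_sensitivity=0.0, pvog_sensitivity=0.0
        )
        hosts, _ = generate_host_genomes(cfg)
        scaffolds, truth = generate_viral_scaffolds(cfg, hosts)
        generate_tool_evidence(truth, scaffolds, cfg)
        for st in truth.scaffolds.values():
            assert not any(st.planted_channels.values())

    def test_intermediate_sensitivity_within_binomial_interval(self):
        from scipy.stats import binom

        cfg = _tiny_cfg(
            n_viral_populations=10,
            members_per_population=10,
            n_decoys=0,
            viral_length_range=(15_000, 16_000),
            sorter_sensitivity=0.6,
            finder_sensitivity=0.0,
            pvog_sensitivity=0.0,
            seed=17,
        )
        hosts, _ = generate_host_genomes(cfg)
        scaffolds, truth = generate_viral_scaffolds(cfg, hosts)
        generate_tool_evidence(truth, scaffolds, cfg)
        fired = sum(
            truth.scaffolds[v].planted_channels["sorter"] for v in truth.viral_ids()
        )
        n = len(truth.viral_ids())
        lo, hi = binom.ppf([0.005, 0.995], n, 0.6)
        assert lo <= fired <= hi

    def test_mismatched_truth_rejected(self):
        cfg = _tiny_cfg()
        hosts, _ = generate_host_genomes(cfg)
        scaffolds, truth = generate_viral_scaffolds(cfg, hosts)
        scaffolds.pop(next(iter(scaffolds)))
        with pytest.raises(ValueError):
            generate_tool_evidence(truth, scaffolds, cfg)


class TestCountMatrix:
    def test_zone_block_structure_in_bray_curtis(self, small_community):
        rel = relative_abundance(small_community.counts)
        meta = rel.metadata
        within, cross = [], []
        cols = rel.sample_ids
        for a, b in itertools.combinations(cols, 2):
            d = bray_curtis(rel.values[a], rel.values[b])
            (within if meta.loc[a, "zone"] == meta.loc[b, "zone"] else cross).append(d)
        assert np.mean(within) < np.mean(cross)

    def test_no_block_effects_no_zone_clustering(self):
        """With unit zone and season factors, zone labels do not explain
        Bray-Curtis structure (permutation test)."""
        cfg = _tiny_cfg(zone_factor=1.0, season_factor=1.0, seed=23)
        hosts, _ = generate_host_genomes(cfg)
        _, truth = generate_viral_scaffolds(cfg, hosts)
        mat = generate_count_matrix(truth, cfg)
        rel = relative_abundance(mat)
        cols = rel.sample_ids
        zones = np.array([rel.metadata.loc[c, "zone"] for c in cols])
        D = np.zeros((len(cols), len(cols)))
        for i, j in itertools.combinations(range(len(cols)), 2):
            D[i, j] = D[j, i] = bray_curtis(rel.values[cols[i]], rel.values[cols[j]])

        def stat(z):
            same = np.equal.outer(z, z)
            iu = np.triu_indices(len(z), 1)
            return D[iu][~same[iu]].mean() - D[iu][same[iu]].mean()

        obs = stat(zones)
        rng = np.random.default_rng(0)
        perm = [stat(rng.permutation(zones)) for _ in range(199)]
        p = (1 + sum(x >= obs for x in perm)) / 200
        assert p > 0.05

    def test_all_zero_row_survives_io_roundtrip(self, tmp_path):
        cfg = _tiny_cfg()
        hosts, _ = generate_host_genomes(cfg)
        _, truth = generate_viral_scaffolds(cfg, hosts)
        mat = generate_count_matrix(truth, cfg)
        mat.values.iloc[0, :] = 0
        path = tmp_path / "counts.tsv"
        write_counts(mat.values, path)
        back = read_counts(path)
        assert (back.iloc[0] == 0).all()
        assert back.shape == mat.values.shape
        assert (back.to_numpy() == mat.values.to_numpy()).all()


class TestDeterminism:
    def test_full_simulation_is_bit_reproducible(self):
        c1 = simulate_community(_tiny_cfg(seed=31))
        c2 = simulate_community(_tiny_cfg(seed=31))
        assert c1.scaffolds == c2.scaffolds
        assert [h.sequence for h in c1.hosts] == [h.sequence for h in c2.hosts]
        assert c1.evidence.equals(c2.evidence)
        assert c1.pvog_matches.equals(c2.pvog_matches)
        assert c1.counts.values.equals(c2.counts.values)
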