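import numpy as np
import pytest

from intol3d import mtr_core, synthetic_data as sd
from intol3d.mtr3d import (
    ColorScale,
    MTRScoreTrack,
    assign_colors,
    average_chains,
    score_complex,
    score_structure,
    track_to_frame,
)
from intol3d.structure3d import ResidueAlignmentMap, map_gene_to_structure

from conftest import collinear_sites


def _prep(struct, gene_id="geneA"):
    seq = struct.sequences[gene_id]
    cds = sd.cds_for_protein(seq, gene_id)
    chains = [c for c, g in struct.chain_genes.items() if g == gene_id]
    by_chain = {c: [s for s in struct.sites if s.chain_id == c] for c in chains}
    amap = map_gene_to_structure(seq, by_chain, gene_id=gene_id)
    return cds, amap


def _matched_counts(cds):
    """Observations drawn exactly at expected proportions -> MTR 1 everywhere."""
    counts = mtr_core.enumerate_codon_expectations(cds)
    for c in counts:
        c.obs_missense = c.exp_missense
        c.obs_synonymous = c.exp_synonymous
    return counts


class TestScoreStructure:
    def test_uniform_counts_score_one(self, helix_structure):
        cds, amap = _prep(helix_structure)
        counts = _matched_counts(cds)
        track = score_structure(counts, amap, helix_structure.sites, k=11)
        values = [s.value for s in track.per_chain.values()]
        assert all(v == pytest.approx(1.0) for v in values)

    def test_depleted_patch_is_track_minimum(self):
        struct = sd.make_structure(60, geometry="helix", seed=7)
        cds, amap = _prep(struct)
        counts = mtr_core.load_observed_counts(
            sd.make_variant_counts(
                cds, baseline_rate=5.0, depleted_positions=tuple(range(25, 35)),
                depletion_factor=0.0, seed=7,
            ),
            cds,
        )
        track = score_structure(counts, amap, struct.sites, k=11)
        scores = {key: s.value for key, s in track.per_chain.items() if s.value is not None}
        argmin = min(scores, key=scores.get)
        assert 25 <= argmin[1] <= 34

    def test_window_saturation_gives_whole_protein_mtr(self, helix_structure):
        cds, amap = _prep(helix_structure)
        counts = mtr_core.load_observed_counts(
            sd.make_variant_counts(cds, baseline_rate=3.0, seed=1), cds
        )
        track = score_structure(counts, amap, helix_structure.sites, k=10_000)
        values = {s.value for s in track.per_chain.values()}
        assert len(values) == 1
        whole = mtr_core.mtr_over_set(counts)
        assert values.pop() == pytest.approx(whole.value)

    def test_linear_geometry_reduces_to_1d_sliding_window(self):
        # uniformly spaced collinear sites: spatial window == sequence window
        n, k = 40, 7
        sites = collinear_sites(np.arange(n) * 3.8)
        cds = sd.make_cds(n, seed=9, gene_id="geneA")
        counts = mtr_core.load_observed_counts(
            sd.make_variant_counts(cds, baseline_rate=4.0, seed=9), cds
        )
        seq = "".join(mtr_core.GENETIC_CODE[c] for c in cds.codons)
        amap = map_gene_to_structure(seq, {"A": sites}, gene_id="geneA")
        track = score_structure(counts, amap, sites, k=k)

        half = k // 2
        by_pos = {c.codon_index: c for c in counts}
        for site in sites:
            pos = site.residue_number
            lo = max(1, min(pos - half, n - k + 1))
            window = [by_pos[p] for p in range(lo, lo + k)]
            expected = mtr_core.mtr_over_set(window)
            got = track.per_chain[site.key]
            if expected.value is None:
                assert got.value is None
            else:
                assert got.value == pytest.approx(expected.value)

    def test_unmapped_focal_and_neighbours_excluded(self):
        struct = sd.make_structure(30, geometry="helix", seed=3, dropout=(5,))
        cds, amap = _prep(struct)
        counts = _matched_counts(cds)
        track = score_structure(counts, amap, struct.sites, k=5)
        assert ("A", 5) not in track.per_chain

    def test_empty_map_rejected(self, helix_structure):
        cds, amap = _prep(helix_structure)
        counts = _matched_counts(cds)
        empty = ResidueAlignmentMap(gene_id="geneA", entries=[(1, "Z", 1)], coverage=0.01)
        with pytest.raises(ValueError):
            score_structure(counts, empty, helix_structure.sites, k=5)


class TestAverageChains:
    def test_identical_chains_average_equals_single(self):
        struct = sd.make_structure(30, geometry="two-chain", seed=5)
        cds, amap = _prep(struct)
        counts = mtr_core.load_observed_counts(
            sd.make_variant_counts(cds, baseline_rate=4.0, seed=5), cds
        )
        track = score_structure(counts, amap, struct.sites, k=9)
        averaged = average_chains(track, amap)
        for pos, value in averaged.averaged.items():
            chain_a = track.per_chain[("A", pos)].value
            chain_b = track.per_chain[("B", pos)].value
            assert value == pytest.approx((chain_a + chain_b) / 2)

    def test_hand_mean_over_defined_chains(self):
        from intol3d.mtr_core import MTRScore

        amap = ResidueAlignmentMap(
            gene_id="g",
            entries=[(1, "A", 1), (1, "B", 1), (1, "C", 1), (1, "D", 1)],
            coverage=1.0,
        )
        track = MTRScoreTrack(structure_id="S", gene_id="g", window_size=3)
        track.per_chain[("A", 1)] = MTRScore(0.8, 5, 3)
        track.per_chain[("B", 1)] = MTRScore(1.2, 5, 3)
        track.per_chain[("C", 1)] = MTRScore(None, 0, 3)  # unresolved
        # chain D never scored
        averaged = average_chains(track, amap)
        assert averaged.averaged[1] == pytest.approx(1.0)

    def test_all_chains_undefined_stays_missing(self):
        from intol3d.mtr_core import MTRScore

        amap = ResidueAlignmentMap(gene_id="g", entries=[(1, "A", 1)], coverage=1.0)
        track = MTRScoreTrack(structure_id="S", gene_id="g", window_size=3)
        track.per_chain[("A", 1)] = MTRScore(None, 0, 3)
        averaged = average_chains(track, amap)
        assert 1 not in averaged.averaged

    def test_permutation_invariant_in_chain_order(self):
        struct = sd.make_structure(25, geometry="two-chain", seed=8)
        cds, amap = _prep(struct)
        counts = mtr_core.load_observed_counts(
            sd.make_variant_counts(cds, baseline_rate=4.0, seed=8), cds
        )
        track = score_structure(counts, amap, struct.sites, k=9)
        reversed_track = MTRScoreTrack(
            structure_id=track.structure_id,
            gene_id=track.gene_id,
            window_size=track.window_size,
            per_chain=dict(reversed(list(track.per_chain.items()))),
        )
        a = average_chains(track, amap).averaged
        b = average_chains(reversed_track, amap).averaged
        assert a == b


class TestScoreComplex:
    def _complex_inputs(self, struct, **kwargs):
        inputs = []
        for gene_id in sorted(struct.sequences):
            cds, amap = _prep(struct, gene_id)
            counts = mtr_core.load_observed_counts(
                sd.make_variant_counts(cds, baseline_rate=4.0, seed=hash(gene_id) % 100,
                                       **kwargs),
                cds,
            )
            inputs.append((gene_id, counts, amap))
        return inputs

    def test_far_apart_equals_independent_runs(self):
        struct = sd.make_structure(30, geometry="complex", seed=4, contact_gap=500.0)
        inputs = self._complex_inputs(struct)
        tracks = score_complex(inputs, struct.sites, k=9)
        for gene_id, counts, amap in inputs:
            chains = [c for c, g in struct.chain_genes.items() if g == gene_id]
            own_sites = [s for s in struct.sites if s.chain_id in chains]
            solo = score_structure(counts, amap, own_sites, k=9)
            for key, score in solo.per_chain.items():
                assert tracks[gene_id].per_chain[key].value == score.value

    def test_interface_window_tallies_pool_both_genes(self):
        struct = sd.make_structure(30, geometry="complex", seed=4, contact_gap=4.0)
        inputs = self._complex_inputs(struct)
        tracks = score_complex(inputs, struct.sites, k=21)

        # brute-force oracle: nearest-21 over the pooled cloud, hand-pooled sums
        counts_by_gene = {g: {c.codon_index: c for c in counts} for g, counts, _ in inputs}
        owner = {}
        for gene_id, _, amap in inputs:
            for pos, chain, resnum in amap.entries:
                owner[(chain, resnum)] = (gene_id, pos)
        mixed_seen = False
        for focal in struct.sites:
            focal_gene, _ = owner[focal.key]

            def dist(s):
                return sum((a - b) ** 2 for a, b in zip(s.coord, focal.coord)) ** 0.5

            ranked = sorted(struct.sites, key=lambda s: (dist(s), s.chain_id, s.residue_number))
            members = ranked[:21]
            genes_in_window = {owner[m.key][0] for m in members}
            if len(genes_in_window) > 1:
                mixed_seen = True
            pooled = [counts_by_gene[owner[m.key][0]][owner[m.key][1]] for m in members]
            expected = mtr_core.mtr_over_set(pooled)
            got = tracks[focal_gene].per_chain[focal.key]
            if expected.value is None:
                assert got.value is None
            else:
                assert got.value == pytest.approx(expected.value)
        assert mixed_seen  # the contact patch must actually mix genes

    def test_partner_with_zero_observations_still_defined(self):
        struct = sd.make_structure(30, geometry="complex", seed=6, contact_gap=4.0)
        inputs = []
        for i, gene_id in enumerate(sorted(struct.sequences)):
            cds, amap = _prep(struct, gene_id)
            rate = 5.0 if i == 0 else 0.0  # partner gene observes nothing
            counts = mtr_core.load_observed_counts(
                sd.make_variant_counts(cds, baseline_rate=rate, seed=6), cds
            )
            inputs.append((gene_id, counts, amap))
        tracks = score_complex(inputs, struct.sites, k=21)
        focal_gene = sorted(struct.sequences)[0]
        defined = [s for s in tracks[focal_gene].per_chain.values() if s.value is not None]
        assert defined  # focal gene contributes observations, windows stay defined

    def test_residue_owned_by_two_genes_rejected(self):
        struct = sd.make_structure(20, geometry="complex", seed=2)
        inputs = self._complex_inputs(struct)
        # graft gene B's map onto gene A's chain
        gene_b, counts_b, _ = inputs[1]
        bad_amap = ResidueAlignmentMap(
            gene_id=gene_b, entries=[(1, "A", 1)], coverage=0.05
        )
        inputs[1] = (gene_b, counts_b, bad_amap)
        with pytest.raises(ValueError, match="two genes"):
            score_complex(inputs, struct.sites, k=5)

    def test_single_gene_rejected(self, helix_structure):
        cds, amap = _prep(helix_structure)
        counts = _matched_counts(cds)
        with pytest.raises(ValueError, match="two genes"):
            score_complex([("geneA", counts, amap)], helix_structure.sites, k=5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_depletion_recovery_ordering(self, seed):
        """Patch mean < outside mean, and patch means order with depletion d."""
        patch = tuple(range(20, 31))
        patch_means = []
        for d in (0.0, 0.25, 0.5):
            struct = sd.make_structure(60, geometry="helix", seed=seed)
            cds, amap = _prep(struct)
            counts = mtr_core.load_observed_counts(
                sd.make_variant_counts(
                    cds, baseline_rate=8.0, depleted_positions=patch,
                    depletion_factor=d, seed=seed,
                ),
                cds,
            )
            track = average_chains(
                score_structure(counts, amap, struct.sites, k=11), amap
            )
            inside = [v for p, v in track.averaged.items() if p in patch]
            outside = [v for p, v in track.averaged.items() if p not in patch]
            assert np.mean(inside) < np.mean(outside)
            patch_means.append(np.mean(inside))
        assert patch_means[0] < patch_means[1] < patch_means[2]


class TestAssignColors:
    def _track(self, values):
        return MTRScoreTrack(
            structure_id="S", gene_id="g", window_size=3,
            averaged={i + 1: v for i, v in enumerate(values)},
        )

    def test_constant_track_all_white(self):
        colors, scale = assign_colors(self._track([1.0, 1.0, 1.0]))
        assert all(c == (1.0, 1.0, 1.0) for c in colors.values())

    def test_anchor_endpoints(self):
        colors, scale = assign_colors(self._track([0.0, 1.0, 2.0]))
        assert scale.mid == 1.0
        assert colors[1] == (0.0, 0.0, 1.0)  # pure blue
        assert colors[2] == (1.0, 1.0, 1.0)  # white
        assert colors[3] == (1.0, 0.0, 0.0)  # pure red

    def test_median_mid_interpolation_in_blue_half(self):
        track = self._track([0.5, 0.9, 1.0, 1.1])
        colors, scale = assign_colors(track)
        assert scale.mid == pytest.approx(0.95)
        rgb = scale.rgb(0.94)
        assert rgb[2] == 1.0 and rgb[0] < 1.0  # blue half: full blue channel

    def test_fixed_policy_pins_mid_to_one(self):
        _, scale = assign_colors(self._track([0.2, 0.8, 1.5]), policy="fixed")
        assert scale.mid == 1.0

    def test_missing_positions_grey(self):
        track = self._track([0.5, 1.5])
        track.averaged[99] = None
        colors, _ = assign_colors(track)
        assert colors[99] == (0.5, 0.5, 0.5)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            assign_colors(self._track([]))

    def test_monotone_mapping(self):
        _, scale = assign_colors(self._track([0.0, 0.5, 1.0, 1.5, 2.0]))
        reds = [scale.rgb(v)[0] - scale.rgb(v)[2] for v in np.linspace(0, 2, 21)]
        assert all(b >= a - 1e-12 for a, b in zip(reds, reds[1:]))


def test_track_to_frame_columns(helix_structure):
    cds, amap = _prep(helix_structure)
    counts = _matched_counts(cds)
    track = average_chains(score_structure(counts, amap, helix_structure.sites, k=9), amap)
    frame = track_to_frame(track, amap)
    assert list(frame.columns) == ["gene_id", "position", "score", "n_obs"]
    assert (frame["n_obs"] > 0).all()
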