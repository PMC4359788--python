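"""Generator determinism, depth model, preset composition and spectrum
parameter recovery."""

import numpy as np
import pytest

from chocnv import depth_profiling as dp
from chocnv import ploidy
from chocnv import synthetic_data as sd


class TestAnnotation:
    def test_determinism(self):
        cfg = sd.SimulationConfig(n_genes=100, seed=7)
        assert sd.generate_annotation(cfg) == sd.generate_annotation(cfg)

    def test_mean_cds_length(self):
        cfg = sd.SimulationConfig(n_genes=5000, seed=1)
        lengths = [g.cds_length for g in sd.generate_annotation(cfg)]
        assert np.mean(lengths) == pytest.approx(1700, rel=0.05)
        assert min(lengths) >= 300
        assert all(l % 3 == 0 for l in lengths)

    def test_full_universe_size(self):
        cfg = sd.SimulationConfig(seed=0)
        assert len(sd.generate_annotation(cfg)) == 20661

    def test_chromosome_labels(self, small_annotation):
        assert {g.chromosome for g in small_annotation} <= set(sd.CHROMOSOME_LABELS)


class TestPresets:
    def test_rows_sum_to_universe(self):
        for counts in sd.CELL_LINE_PRESETS.values():
            assert sum(counts) == 20661

    def test_maps_match_counts_exactly(self):
        cfg = sd.SimulationConfig(n_genes=2000, seed=3)
        maps = sd.preset_cn_maps(cfg)
        for sample, cn_map in maps.items():
            values = np.array(list(cn_map.values()))
            expected = sd.preset_counts(sample, 2000)
            observed = tuple(int((values == c).sum()) for c in (0, 1, 2, 3))
            assert observed == expected, sample

    def test_lineage_sharing_shrinks_within_group_distances(self):
        """DXB11 and F435 share most CNV events, so they differ in far fewer
        genes than either differs from a K1 line."""
        cfg = sd.SimulationConfig(n_genes=2000, seed=3)
        maps = sd.preset_cn_maps(cfg, ["CHO_DXB11", "F435", "CHO-K1_ATCC"])
        def diff(a, b):
            return sum(maps[a][g] != maps[b][g] for g in maps[a])
        assert diff("CHO_DXB11", "F435") < diff("CHO_DXB11", "CHO-K1_ATCC")
        assert diff("CHO_DXB11", "F435") < diff("F435", "CHO-K1_ATCC")

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown presets"):
            sd.preset_cn_maps(sd.SimulationConfig(n_genes=100), ["nope"])


class TestDepthModel:
    def test_diploid_mean_depth(self, small_config, small_annotation):
        cn = {g.gene_id: 2 for g in small_annotation}
        track = sd.simulate_depth(small_annotation, cn, small_config)
        total = np.concatenate(list(track.depths.values()))
        assert total.mean() == pytest.approx(33.0, rel=0.02)

    def test_deleted_gene_zero_depth(self, small_config, small_annotation):
        gene = small_annotation[0]
        cn = {g.gene_id: 2 for g in small_annotation}
        cn[gene.gene_id] = 0
        track = sd.simulate_depth(small_annotation, cn, small_config)
        depths = track.depths[gene.scaffold]
        for start, end in gene.cds_intervals:
            assert (depths[start:end] == 0).all()

    def test_negative_copy_number_rejected(self, small_config, small_annotation):
        cn = {g.gene_id: 2 for g in small_annotation}
        cn[small_annotation[0].gene_id] = -1
        with pytest.raises(ValueError, match="negative copy number"):
            sd.simulate_depth(small_annotation, cn, small_config)

    def test_gene_medians_match_track_medians(self, small_config, small_annotation):
        """The direct per-gene sampler agrees in distribution with the
        full-track route: same model, so summaries must be within noise."""
        cn = {g.gene_id: (1 if i % 3 == 0 else 2) for i, g in enumerate(small_annotation)}
        track = sd.simulate_depth(small_annotation, cn, small_config)
        via_track, _ = dp.gene_median_depth(track, small_annotation)
        direct = sd.simulate_gene_depths(small_annotation, cn, small_config)
        a = np.array([via_track[g.gene_id] for g in small_annotation])
        b = np.array([direct[g.gene_id] for g in small_annotation])
        assert abs(a.mean() - b.mean()) < 0.5

    def test_depth_peaks_at_16_33_49(self):
        """The DXB11 preset shows the characteristic coverage modes near
        16x (haploid), 33x (diploid) and 49x (triploid)."""
        cfg = sd.SimulationConfig(n_genes=4000, seed=2)
        ann = sd.generate_annotation(cfg)
        cn = sd.preset_cn_maps(cfg, ["CHO_DXB11"])["CHO_DXB11"]
        med = np.array(list(sd.simulate_gene_depths(ann, cn, cfg).values()))
        for mode, lo, hi in [(16.5, 14, 19), (33, 31, 35), (49.5, 47, 52)]:
            assert ((med > lo) & (med < hi)).sum() > 0
        hist, edges = np.histogram(med, bins=np.arange(0, 60, 1.0))
        for peak in (16, 33, 49):
            idx = int(peak)
            assert hist[idx - 1 : idx + 2].sum() > hist[idx - 6 : idx - 3].sum()

    def test_overdispersion_widens_depth_spread(self, small_annotation):
        cn = {g.gene_id: 2 for g in small_annotation}
        tight = sd.SimulationConfig(n_genes=300, seed=7)
        wide = sd.SimulationConfig(n_genes=300, seed=7, overdispersion=0.3)
        d_tight = np.concatenate(list(sd.simulate_depth(small_annotation, cn, tight).depths.values()))
        d_wide = np.concatenate(list(sd.simulate_depth(small_annotation, cn, wide).depths.values()))
        assert d_wide.var() > 2 * d_tight.var()


class TestVariantModel:
    @staticmethod
    def _spectrum_ratio(truth):
        counts = truth["category"].value_counts()
        gc_at = counts.get("G>A", 0) + counts.get("C>T", 0)
        at_gc = counts.get("A>G", 0) + counts.get("T>C", 0)
        return gc_at / at_gc

    @staticmethod
    def _base_fractions(annotation):
        seq = "".join(g.cds_sequence for g in annotation)
        return {b: seq.count(b) / len(seq) for b in "ACGT"}

    def test_unbiased_spectrum_symmetric(self):
        cfg = sd.SimulationConfig(n_genes=3000, seed=11, ems_bias=1.0, snp_rate=2e-3)
        ann = sd.generate_annotation(cfg)
        cn = {g.gene_id: 2 for g in ann}
        _, truth, _ = sd.simulate_variants(ann, cn, cfg)
        expected = sd.expected_spectrum_ratio(self._base_fractions(ann), 1.0)
        assert self._spectrum_ratio(truth) == pytest.approx(expected, rel=0.10)

    def test_biased_spectrum_recovers_configured_excess(self):
        """At ems_bias=2 the GC->AT/AT->GC ratio matches the probability
        table enumerated independently from the generator's weights."""
        cfg = sd.SimulationConfig(n_genes=3000, seed=11, ems_bias=2.0, snp_rate=2e-3)
        ann = sd.generate_annotation(cfg)
        cn = {g.gene_id: 2 for g in ann}
        _, truth, _ = sd.simulate_variants(ann, cn, cfg)
        fractions = self._base_fractions(ann)
        # independent enumeration over ref bases and the biased alt weights
        probs = {}
        for ref in "ACGT":
            weights = {a: (2.0 if (ref, a) in {("G", "A"), ("C", "T")} else 1.0)
                       for a in "ACGT" if a != ref}
            z = sum(weights.values())
            for a, w in weights.items():
                probs[(ref, a)] = fractions[ref] * w / z
        expected = (probs[("G", "A")] + probs[("C", "T")]) / (
            probs[("A", "G")] + probs[("T", "C")]
        )
        assert self._spectrum_ratio(truth) == pytest.approx(expected, rel=0.10)
        assert expected > 1.3  # the bias is visible at all

    def test_het_alt_depth_binomial_mean(self):
        """Heterozygous alt depths at ~40x average near 20."""
        cfg = sd.SimulationConfig(
            n_genes=2000, seed=5, het_fraction=1.0, diploid_median_depth=40.0,
            snp_rate=1e-3,
        )
        ann = sd.generate_annotation(cfg)
        cn = {g.gene_id: 2 for g in ann}
        calls, truth, _ = sd.simulate_variants(ann, cn, cfg)
        het = [c for c in calls if 35 <= c.total_depth <= 45]
        assert len(het) > 300
        mean_frac = np.mean([c.alt_depth / c.total_depth for c in het])
        assert 18 / 40 <= mean_frac <= 22 / 40

    def test_haploid_variants_homozygous(self, small_config, small_annotation):
        cn = {g.gene_id: 1 for g in small_annotation}
        _, truth, _ = sd.simulate_variants(small_annotation, cn, small_config)
        assert (truth["zygosity"] == "homozygous").all()

    def test_blacklist_fraction_emitted_twice(self):
        cfg = sd.SimulationConfig(n_genes=2000, seed=3, blacklist_fraction=0.1,
                                  snp_rate=1e-3)
        ann = sd.generate_annotation(cfg)
        cn = {g.gene_id: 2 for g in ann}
        calls, truth, blacklist = sd.simulate_variants(ann, cn, cfg)
        keys = {(c.scaffold, c.pos) for c in calls}
        assert blacklist and all((c.scaffold, c.pos) in keys for c in blacklist)
        assert (truth["zygosity"] == "artifact").sum() == len(blacklist)

    def test_determinism(self, small_config, small_annotation):
        cn = {g.gene_id: 2 for g in small_annotation}
        a = sd.simulate_variants(small_annotation, cn, small_config)
        b = sd.simulate_variants(small_annotation, cn, small_config)
        assert a[0] == b[0] and a[1].equals(b[1])


def test_classifier_recovers_true_labels(small_config, small_annotation):
    """At 33x the peak separation leaves essentially no label errors."""
    rng = np.random.default_rng(0)
    cn = {g.gene_id: int(c) for g, c in zip(small_annotation,
                                            rng.choice([0, 1, 2, 3], 300))}
    med = sd.simulate_gene_depths(small_annotation, cn, small_config)
    profile = ploidy.classify_profile(dp.normalize_depths(med))
    label_of = {0: "deleted", 1: "haploid", 2: "diploid", 3: "amplified"}
    correct = sum(profile.classes[g] == label_of[c] for g, c in cn.items())
    assert correct / len(cn) >= 0.99
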