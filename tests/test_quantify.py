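import numpy as np
import pytest

from repliquant import simulate as sim
from repliquant.config import AnalysisConfig
from repliquant.io import NucleusImage
from repliquant.quantify import (
    InsufficientRegionError,
    NormalizationError,
    UndefinedRatioError,
    decondensation_metrics,
    f3h_score,
    group_by_expression,
    mod_ratio,
    normalize_mod_level,
    relative_accumulation,
)
from repliquant.segmentation import segment


class TestRelativeAccumulation:
    def test_uniform_protein_gives_unity(self, cfg):
        img, truth = sim.generate_nucleus(
            sim.NucleusSpec(accumulation_fold=1.0, rng_seed=3)
        )
        masks = segment(img, cfg)
        res = relative_accumulation(img, masks, cfg, seed=3)
        assert 0.95 <= res.relative_accumulation <= 1.05

    def test_recovers_threefold_enrichment(self, cfg):
        ratios = []
        for seed in range(20):
            img, _ = sim.generate_nucleus(
                sim.NucleusSpec(accumulation_fold=3.0, rng_seed=seed)
            )
            masks = segment(img, cfg)
            res = relative_accumulation(img, masks, cfg, seed=seed)
            ratios.append(res.relative_accumulation)
        assert np.mean(ratios) == pytest.approx(3.0, rel=0.10)

    def test_manual_identical_rois_give_exactly_one(self, late_s, cfg):
        img, _, _ = late_s
        masks = segment(img, cfg)
        centers = [(100.0, 100.0), (120.0, 130.0), (140.0, 110.0)]
        res = relative_accumulation(
            img, masks, cfg, mode="manual",
            manual_foci=centers, manual_nucleoplasm=centers,
        )
        assert res.relative_accumulation == 1.0

    def test_scale_invariance(self, late_s, cfg):
        img, _, _ = late_s
        masks = segment(img, cfg)
        res1 = relative_accumulation(img, masks, cfg, seed=0)
        scaled = NucleusImage(
            channels={
                "dna": img.channels["dna"],
                "pcna": img.channels["pcna"],
                "protein": img.channels["protein"] // 4,
            }
        )
        res2 = relative_accumulation(scaled, masks, cfg, seed=0)
        # integer division is exact for these values: ratio is unchanged
        assert res2.relative_accumulation == pytest.approx(
            res1.relative_accumulation, rel=1e-3
        )

    def test_seeded_determinism(self, late_s, cfg):
        img, _, _ = late_s
        masks = segment(img, cfg)
        a = relative_accumulation(img, masks, cfg, seed=42)
        b = relative_accumulation(img, masks, cfg, seed=42)
        assert a.relative_accumulation == b.relative_accumulation
        assert [r.center for r in a.nucleoplasm_rois] == [
            r.center for r in b.nucleoplasm_rois
        ]

    def test_insufficient_foci_raises(self, cfg):
        dna = np.full((128, 128), 100, dtype=np.uint16)
        dna[20:110, 20:110] = 5000  # nucleus without chromocenters
        img = NucleusImage(
            channels={
                "dna": dna,
                "pcna": np.full((128, 128), 1000, dtype=np.uint16),
                "protein": np.full((128, 128), 1000, dtype=np.uint16),
            }
        )
        masks = segment(img, cfg)
        with pytest.raises(InsufficientRegionError):
            relative_accumulation(img, masks, cfg, seed=0)


class TestNormalizeModLevel:
    def test_worked_example(self):
        assert normalize_mod_level(6000.0, 3.0, 2000.0) == pytest.approx(1.0)

    def test_zero_signal_gives_zero(self):
        assert normalize_mod_level(0.0, 5.0, 100.0) == 0.0

    def test_linearity(self):
        base = normalize_mod_level(1000.0, 7.0, 300.0)
        assert normalize_mod_level(3000.0, 7.0, 300.0) == pytest.approx(
            3 * base
        )
        assert normalize_mod_level(1000.0, 14.0, 300.0) == pytest.approx(
            base / 2
        )
        assert normalize_mod_level(1000.0, 7.0, 600.0) == pytest.approx(
            base / 2
        )

    def test_invalid_denominators(self):
        with pytest.raises(NormalizationError):
            normalize_mod_level(100.0, 0.0, 10.0)
        with pytest.raises(NormalizationError):
            normalize_mod_level(100.0, 10.0, 0.0)


class TestExpressionGrouping:
    @pytest.mark.parametrize(
        "fp,value,expected",
        [
            ("gfp", 40.0, "background"),
            ("gfp", 50.0, "low"),
            ("gfp", 250.0, "mid"),
            ("gfp", 600.0, "high"),
            ("mcherry", 99.9, "background"),
            ("mcherry", 100.0, "low"),
            ("mcherry", 700.0, "mid"),
            ("mcherry", 1000.0, "high"),
        ],
    )
    def test_bin_assignment(self, fp, value, expected):
        group = group_by_expression(value, fp)
        assert group.group == expected
        assert not group.out_of_range

    def test_above_top_bin_flags_out_of_range(self):
        group = group_by_expression(2000.0, "gfp")
        assert group.group == "high"
        assert group.out_of_range

    def test_partition_of_nonnegative_reals(self):
        # every value gets exactly one label; labels are monotone in value
        order = {"background": 0, "low": 1, "mid": 2, "high": 3}
        values = np.linspace(0, 6000, 1201)
        prev = -1
        for v in values:
            g = group_by_expression(float(v), "mcherry")
            assert order[g.group] >= prev
            prev = order[g.group]

    def test_unknown_fluorophore(self):
        with pytest.raises(ValueError):
            group_by_expression(10.0, "dsred")


class TestModRatio:
    def test_examples(self):
        assert mod_ratio(0.5, 0.5) == pytest.approx(1.0)
        assert mod_ratio(0.9, 0.3) == pytest.approx(3.0)

    def test_halved_5mc_doubles_ratio(self):
        assert mod_ratio(0.4, 0.1) == pytest.approx(2 * mod_ratio(0.4, 0.2))

    def test_zero_denominator(self):
        with pytest.raises(UndefinedRatioError):
            mod_ratio(0.5, 0.0)


class TestDecondensation:
    def test_area_ratio(self, cfg):
        dna = np.full((64, 64), 100, dtype=np.uint16)
        dna[10:50, 10:50] = 5000
        dna[20:30, 20:30] = 20000  # 100 px chromocenter in 1600 px nucleus
        img = NucleusImage(channels={"dna": dna})
        masks = segment(img, AnalysisConfig(min_nucleus_area=100))
        m = decondensation_metrics(img, masks)
        assert m.relative_het_area == pytest.approx(100 / 1600)

    def test_sd_decreases_as_chromocenters_fade(self, cfg):
        sds = []
        for level in (20000, 12000, 6000):
            img, _ = sim.generate_nucleus(
                sim.NucleusSpec(chromocenter_level=level, rng_seed=0)
            )
            masks = segment(img, cfg)
            sds.append(decondensation_metrics(img, masks).dapi_sd)
        assert sds[0] > sds[1] > sds[2]

    def test_empty_mask_rejected(self, cfg):
        img = NucleusImage(
            channels={"dna": np.zeros((16, 16), dtype=np.uint16)}
        )
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            masks = segment(img, cfg)
        with pytest.raises(ValueError):
            decondensation_metrics(img, masks)


class TestF3hScore:
    def test_percentages(self):
        cells = [("earlyS", True)] * 10 + [("earlyS", False)] * 40
        cells += [("lateS", False)] * 60
        out = f3h_score(cells).set_index("stage")
        assert out.loc["earlyS", "percent"] == pytest.approx(20.0)
        assert out.loc["lateS", "percent"] == 0.0
        assert not out["low_n"].any()

    def test_low_n_warning(self):
        cells = [("earlyS", True)] * 49
        with pytest.warns(UserWarning):
            out = f3h_score(cells)
        assert out["low_n"].all()

    def test_empty_and_bad_labels(self):
        with pytest.raises(ValueError):
            f3h_score([])
        with pytest.raises(ValueError):
            f3h_score([("G2", True)] * 50)
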