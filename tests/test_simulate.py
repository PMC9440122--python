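import numpy as np
import pytest

from repliquant import simulate as sim
from repliquant.frap import double_normalize


class TestNucleusGenerator:
    def test_no_enrichment_at_fold_one(self):
        img, truth = sim.generate_nucleus(
            sim.NucleusSpec(accumulation_fold=1.0, rng_seed=0)
        )
        protein = img.channel("protein").astype(float)
        ratio = protein[truth.foci].mean() / protein[
            truth.nuclear & ~truth.foci
        ].mean()
        assert 0.95 <= ratio <= 1.05

    def test_same_seed_byte_identical(self):
        spec = sim.NucleusSpec(accumulation_fold=2.0, rng_seed=11)
        img_a, _ = sim.generate_nucleus(spec)
        img_b, _ = sim.generate_nucleus(spec)
        for role in img_a.channels:
            assert img_a.channels[role].tobytes() == \
                img_b.channels[role].tobytes()

    def test_noiseless_enrichment_exact(self):
        img, truth = sim.generate_nucleus(
            sim.NucleusSpec(
                accumulation_fold=3.0, camera_gain=0, read_noise_sd=0,
                rng_seed=1,
            )
        )
        protein = img.channel("protein").astype(float)
        ratio = protein[truth.foci].mean() / protein[
            truth.nuclear & ~truth.foci
        ].mean()
        assert ratio == pytest.approx(3.0, abs=1e-12)

    def test_noise_is_zero_mean_on_interior(self):
        spec = sim.NucleusSpec(rng_seed=3)
        noisy, truth = sim.generate_nucleus(spec)
        interior = truth.nucleoplasm & ~truth.foci
        mean = noisy.channel("dna").astype(float)[interior].mean()
        sd = noisy.channel("dna").astype(float)[interior].std()
        n = interior.sum()
        assert abs(mean - spec.euchromatin_level) < 5 * sd / np.sqrt(n)

    def test_ground_truth_partition_and_containment(self):
        for seed in range(5):
            _, truth = sim.generate_nucleus(sim.NucleusSpec(rng_seed=seed))
            assert not np.any(truth.heterochromatin & ~truth.nuclear)
            assert np.array_equal(
                truth.nucleoplasm, truth.nuclear & ~truth.heterochromatin
            )
            fracs = truth.compaction_fractions
            assert fracs["euchromatin"] + fracs["chromocenter"] == \
                pytest.approx(1.0)

    def test_early_s_puncta_avoid_chromocenters(self):
        img, truth = sim.generate_nucleus(
            sim.NucleusSpec(pcna_pattern="earlyS", rng_seed=2,
                            camera_gain=0, read_noise_sd=0)
        )
        # many small puncta, mostly outside heterochromatin
        assert len(truth.foci_centers) >= 50
        centers = np.array(truth.foci_centers).round().astype(int)
        in_het = truth.heterochromatin[centers[:, 0], centers[:, 1]]
        assert in_het.sum() == 0

    def test_invalid_spec_rejected(self):
        with pytest.raises(sim.ParameterError):
            sim.NucleusSpec(accumulation_fold=-1.0)
        with pytest.raises(sim.ParameterError):
            sim.NucleusSpec(pcna_pattern="mitosis")
        with pytest.raises(sim.PlacementError):
            sim.generate_nucleus(
                sim.NucleusSpec(n_chromocenters=400, rng_seed=0)
            )


class TestFrapGenerator:
    def test_mono_exponential_midpoint_at_half_life(self):
        spec = sim.FrapSpec(k1=0.2, noise_sd=0.0)
        trace = sim.generate_frap_trace(spec)
        norm = double_normalize(trace)[trace.bleach_index:]
        t = trace.t_post
        t_half = np.log(2) / spec.k1
        midpoint = 0.5 * (spec.bleach_depth + spec.plateau)
        value = np.interp(t_half, t, norm)
        assert value == pytest.approx(midpoint, rel=1e-3)

    def test_zero_amplitude_recovery_is_flat(self):
        spec = sim.FrapSpec(plateau=0.5, bleach_depth=0.499999999,
                            noise_sd=0.0)
        trace = sim.generate_frap_trace(spec)
        post = double_normalize(trace)[trace.bleach_index:]
        assert np.allclose(post, 0.5, atol=1e-6)

    def test_invalid_frame_interval(self):
        with pytest.raises(sim.ParameterError):
            sim.FrapSpec(frame_interval=0.0)

    def test_determinism(self):
        spec = sim.FrapSpec(noise_sd=0.01, rng_seed=5)
        a = sim.generate_frap_trace(spec)
        b = sim.generate_frap_trace(spec)
        assert a.roi1.tobytes() == b.roi1.tobytes()


class TestGelGenerator:
    def test_zero_density_lane_is_blank(self):
        img, rects = sim.generate_gel([0.0, 800.0])
        r0, r1, c0, c1 = rects[0]
        region = img[r0:r1, c0:c1]
        assert np.allclose(region, region[0, 0])

    def test_overlapping_lanes_rejected(self):
        with pytest.raises(sim.GeometryError):
            sim.generate_gel([100.0], lane_width=50, lane_pitch=40)

    def test_determinism(self):
        a, _ = sim.generate_gel([100.0, 50.0], noise_sd=2.0, rng_seed=4)
        b, _ = sim.generate_gel([100.0, 50.0], noise_sd=2.0, rng_seed=4)
        assert a.tobytes() == b.tobytes()


class TestCloneGenerator:
    def test_full_methylation_bs_reads_all_c(self):
        spec = sim.CloneSpec(p_mc=1.0, p_hmc=0.0, n_clones=10,
                             chemistry="BS", conversion=1.0, rng_seed=0)
        _, truth = sim.generate_clones(spec)
        assert np.all(truth.emitted == "C")

    def test_full_methylation_tab_reads_all_t(self):
        spec = sim.CloneSpec(p_mc=1.0, p_hmc=0.0, n_clones=10,
                             chemistry="TAB", rng_seed=0)
        _, truth = sim.generate_clones(spec)
        assert np.all(truth.emitted == "T")

    def test_pure_hmc_tab_reads_all_c(self):
        spec = sim.CloneSpec(p_mc=0.0, p_hmc=1.0, n_clones=10,
                             chemistry="TAB", rng_seed=0)
        _, truth = sim.generate_clones(spec)
        assert np.all(truth.emitted == "C")

    def test_emitted_base_written_into_sequence(self):
        spec = sim.CloneSpec(p_mc=0.3, p_hmc=0.3, n_clones=5, rng_seed=2)
        records, truth = sim.generate_clones(spec)
        for i, rec in enumerate(records):
            for j, pos in enumerate(truth.cpg_positions):
                assert str(rec.seq)[pos] == truth.emitted[i, j]

    def test_invalid_specs(self):
        with pytest.raises(sim.ParameterError):
            sim.CloneSpec(n_clones=0)
        with pytest.raises(sim.ParameterError):
            sim.CloneSpec(p_mc=0.8, p_hmc=0.5)
        with pytest.raises(sim.ParameterError):
            sim.CloneSpec(reference="ATTAGGATTA")  # no CpG

    def test_determinism(self):
        spec = sim.CloneSpec(n_clones=8, rng_seed=9)
        a, _ = sim.generate_clones(spec)
        b, _ = sim.generate_clones(spec)
        assert [str(r.seq) for r in a] == [str(r.seq) for r in b]
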