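"""Generator determinism, geometry and ground-truth closure."""

import numpy as np
import pytest

from spindlemetrics import (
    SpindleGroundTruth,
    generate_amplicons,
    generate_anaphase_series,
    generate_count_table,
    generate_ct_table,
    generate_spindle_stack,
)
from spindlemetrics.errors import (
    GenerationError,
    GeometryError,
    ValidationError,
)
from spindlemetrics.genotyping import ASSAYS
from spindlemetrics.synthetic import Optics


class TestSpindleStack:
    def test_seeded_determinism(self):
        truth = SpindleGroundTruth.bipolar(divergence=0.4, seed=42)
        a, _ = generate_spindle_stack(truth, Optics())
        b, _ = generate_spindle_stack(truth, Optics())
        for ch in a.channels:
            np.testing.assert_array_equal(a.channels[ch], b.channels[ch])

    def test_zero_optics_gives_zero_stack(self):
        truth = SpindleGroundTruth.bipolar(seed=1)
        optics = Optics(photon_scale=0.0, read_noise_sd=0.0, background=0.0)
        stack, _ = generate_spindle_stack(truth, optics)
        for arr in stack.channels.values():
            assert not arr.any()

    def test_divergence_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            SpindleGroundTruth.bipolar(divergence=1.2)
        with pytest.raises(ValidationError):
            SpindleGroundTruth.bipolar(divergence=-0.1)

    def test_too_small_shape_raises_geometry_error(self):
        truth = SpindleGroundTruth.bipolar(seed=1)
        with pytest.raises(GeometryError):
            generate_spindle_stack(truth, Optics(), shape=(20, 96, 100))

    def test_cylinder_cross_section_width_constant_along_axis(
            self, noiseless_cylinder):
        # brute-force per-plane profile scan: for a non-converging bundle the
        # fiber positions are identical in every cross-section, so the FWHM
        # must not vary along the axis (away from the blurred ends)
        stack, truth, _ = noiseless_cylinder
        img = stack.channel("tubulin")
        widths = []
        for xi in range(45, 115):  # x in [9, 23] um; poles at 3.9 / 27.9
            prof = img[9, :, xi] + img[10, :, xi]  # rows bracketing z-centre
            plateau = np.median(prof[prof >= 0.75 * prof.max()])
            half = plateau / 2.0
            above = np.flatnonzero(prof > half)
            i0, i1 = above[0], above[-1]
            left = i0 - 1 + (prof[i0 - 1] - half) / (prof[i0 - 1] - prof[i0])
            right = i1 + (half - prof[i1]) / (prof[i1 + 1] - prof[i1])
            widths.append((right - left) * stack.voxel_size[1])
        assert max(widths) - min(widths) <= stack.voxel_size[1]

    @pytest.mark.parametrize("divergence", [0.0, 0.5, 1.0])
    def test_axial_slab_intensity_conserved(self, divergence):
        # straight fibers deposit the same integrated intensity per axial
        # slab; blur only redistributes it, so between plate and pole the
        # slab sums are constant (hence non-increasing) within tolerance
        truth = SpindleGroundTruth.bipolar(divergence=divergence, seed=4)
        stack, _ = generate_spindle_stack(truth, Optics.noiseless())
        slabs = stack.channel("tubulin").sum(axis=(0, 1))
        interior = slabs[88:132]  # x in [17.6, 26.2] um, plate 15.9, pole 27.9
        assert (interior.max() - interior.min()) / interior.mean() < 0.05

    def test_ground_truth_masks_match_signal(self, noiseless_cone):
        stack, truth, masks = noiseless_cone
        # every fiber-labeled voxel carries tubulin signal after blur
        assert stack.channel("tubulin")[masks.tubulin].min() > 0
        # the DNA mask is an ellipsoid of the stated plate diameter
        coords = np.argwhere(masks.dna) * np.asarray(stack.voxel_size)
        extent = coords.max(axis=0) - coords.min(axis=0)
        assert extent[1] == pytest.approx(truth.plate_width_true, abs=0.5)


class TestAnaphaseSeries:
    def test_zero_speed_keeps_centroids_static(self):
        truth = SpindleGroundTruth.bipolar(seed=2)
        _, ana = generate_anaphase_series(truth, speed=0.0, n_timepoints=4)
        gt = ana.chromosome_mass_centroids
        assert np.allclose(gt, gt[0])

    def test_separation_grows_at_twice_the_poleward_speed(self):
        truth = SpindleGroundTruth.bipolar(seed=2)
        _, ana = generate_anaphase_series(truth, speed=0.5, n_timepoints=5,
                                          time_step=5.0)
        gt = ana.chromosome_mass_centroids
        sep = np.linalg.norm(gt[:, 0] - gt[:, 1], axis=1)
        np.testing.assert_allclose(np.diff(sep), 5.0, atol=1e-9)

    def test_rendered_frames_track_ground_truth(self):
        from scipy import ndimage
        truth = SpindleGroundTruth.bipolar(seed=5)
        stack, ana = generate_anaphase_series(truth, speed=0.4,
                                              n_timepoints=5)
        vs = np.asarray(stack.voxel_size)
        for t in range(5):
            img = stack.channel("dna")[t]
            # independent oracle: label the two bright masses directly
            mask = img > 0.5 * img.max()
            labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
            assert n == 2
            found = np.array([
                (np.argwhere(labels == lab) * vs).mean(axis=0)
                for lab in (1, 2)
            ])
            for truth_c in ana.chromosome_mass_centroids[t]:
                err = np.linalg.norm(found - truth_c, axis=1).min()
                assert err < 0.5

    def test_negative_speed_rejected(self):
        truth = SpindleGroundTruth.bipolar(seed=2)
        with pytest.raises(ValidationError):
            generate_anaphase_series(truth, speed=-0.1)


class TestTables:
    def test_noiseless_equal_expression_gives_flat_ct(self):
        df = generate_ct_table({"wt": 1.0, "het": 1.0}, n_replicates=3)
        target = df[df.gene == "target"]["ct"]
        assert target.nunique() == 1

    def test_halved_expression_costs_one_cycle(self):
        df = generate_ct_table({"wt": 1.0, "mut": 0.5}, n_replicates=2)
        t_wt = df[(df.genotype == "wt") & (df.gene == "target")]["ct"].iloc[0]
        t_mut = df[(df.genotype == "mut") & (df.gene == "target")]["ct"].iloc[0]
        assert t_mut - t_wt == pytest.approx(1.0)

    def test_nonpositive_expression_rejected(self):
        with pytest.raises(ValidationError):
            generate_ct_table({"wt": 1.0, "mut": 0.0})

    @pytest.mark.parametrize("p,expect", [(1.0, "all"), (0.0, "none")])
    def test_count_table_extremes(self, p, expect):
        df = generate_count_table({"g": p}, n_scored=200, n_plants=5, seed=1)
        if expect == "all":
            assert (df.n_positive == df.n_scored).all()
        else:
            assert (df.n_positive == 0).all()

    def test_count_table_estimates_probability(self):
        # parameter mirrors the wild-type viable-pollen rate
        p = 0.977
        df = generate_count_table({"wt": p}, n_scored=500, n_plants=10, seed=3)
        n = df.n_scored.sum()
        k = df.n_positive.sum()
        # pooled estimate within the 99% binomial CI around p
        half = 2.576 * np.sqrt(p * (1 - p) / n)
        assert abs(k / n - p) < half

    def test_count_table_deterministic(self):
        a = generate_count_table({"g": 0.5}, seed=9)
        b = generate_count_table({"g": 0.5}, seed=9)
        assert a.equals(b)


class TestAmplicons:
    @pytest.mark.parametrize("assay,allele,length,cuts", [
        ("dv1-1", "cut-allele", 235, (152,)),
        ("dv1-1", "uncut-allele", 235, ()),
        ("dv1-IG", "cut-allele", 533, (272,)),
        ("dv1-IG", "uncut-allele", 533, ()),
    ])
    def test_site_count_matches_request(self, assay, allele, length, cuts):
        amp = generate_amplicons(assay, allele, length, cuts, seed=7)
        assert len(amp.sequence) == length
        # exhaustive substring scan oracle, independent of find_sites
        site = ASSAYS[assay].enzyme.site
        occurrences = [i for i in range(len(amp.sequence) - len(site) + 1)
                       if amp.sequence[i:i + len(site)] == site]
        assert len(occurrences) == len(cuts)

    @pytest.mark.parametrize("seed", range(5))
    def test_multi_cut_positions_exact(self, seed):
        cuts = (50, 120, 300)
        amp = generate_amplicons("dv1-IG", "cut-allele", 400, cuts, seed=seed)
        from spindlemetrics.genotyping import NSII, find_sites
        assert tuple(find_sites(amp.sequence, NSII)) == cuts

    def test_overlapping_sites_raise(self):
        with pytest.raises(GenerationError):
            generate_amplicons("dv1-IG", "cut-allele", 400, (100, 102), seed=0)

    def test_cut_position_outside_amplicon_rejected(self):
        with pytest.raises(ValidationError):
            generate_amplicons("dv1-1", "cut-allele", 235, (0,), seed=0)
        with pytest.raises(ValidationError):
            generate_amplicons("dv1-1", "cut-allele", 235, (235,), seed=0)
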