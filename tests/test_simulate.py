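"""The synthetic-data generator: determinism, stated marginals, ground truth."""

import numpy as np
import pandas as pd
import pytest

from orfstruct import dms
from orfstruct import simulate as sim
from orfstruct.gini import gini_value
from orfstruct.model import orf_profile, spacing


class TestMakeGenome:
    def test_deterministic_for_fixed_seed(self):
        a = sim.make_genome(6, seed=3)
        b = sim.make_genome(6, seed=3)
        assert a.sequences == b.sequences and a.orfs == b.orfs

    def test_overlap_fraction_zero_means_positive_spacings(self):
        ann = sim.make_genome(10, overlap_fraction=0.0, seed=1)
        assert all(spacing(u, d) > 0 for u, d in ann.adjacent_pairs())

    def test_requested_overlap_fraction_is_realized(self):
        ann = sim.make_genome(80, overlap_fraction=0.25, seed=2)
        sps = [spacing(u, d) for u, d in ann.adjacent_pairs()]
        frac = np.mean([s <= 0 for s in sps])
        assert abs(frac - 0.25) < 0.08

    def test_single_orf_operons_have_no_pairs(self):
        ann = sim.make_genome(5, orfs_per_operon=(1, 1), seed=0)
        assert ann.adjacent_pairs() == []

    def test_orf_lengths_are_codon_multiples_in_range(self):
        ann = sim.make_genome(10, orf_len=(300, 450), seed=4)
        for o in ann.orfs:
            assert o.length % 3 == 0 and 300 <= o.length <= 450

    def test_start_and_stop_codons_in_transcript_orientation(self):
        ann = sim.make_genome(6, overlap_fraction=0.0, seed=5, minus_fraction=0.5)
        for o in ann.orfs:
            s = ann.orf_sequence(o)
            assert s[:3] == "ATG" and s[-3:] == "TAA"


class TestMakeStructures:
    def test_realized_paired_fraction_tracks_target(self):
        ann0 = sim.make_genome(15, seed=6)
        _, truth = sim.make_structures(ann0, (0.0, 0.8), seed=6)
        err = (
            truth.per_orf.realized_paired_fraction
            - truth.per_orf.target_paired_fraction
        ).abs()
        assert err.max() <= 0.05

    def test_zero_fraction_gives_all_dot_structure(self):
        ann0 = sim.make_genome(3, seed=7)
        ann, truth = sim.make_structures(ann0, 0.0, seed=7)
        for o in ann.orfs:
            assert not truth.orf_paired(ann, o).any()
            assert set(truth.dotbrackets[o.id]) == {"."}

    def test_hairpins_stay_inside_orfs(self):
        ann0 = sim.make_genome(10, seed=8, overlap_fraction=0.0)
        ann, truth = sim.make_structures(ann0, 0.6, seed=8)
        inside = np.zeros_like(next(iter(truth.paired.values())))
        covered = {k: np.zeros_like(v) for k, v in truth.paired.items()}
        for o in ann.orfs:
            covered[(o.replicon, o.strand)][o.start : o.end] = True
        for key, lab in truth.paired.items():
            assert not (lab & ~covered[key]).any()

    def test_boundary_violation_flag_crosses_a_start_codon(self):
        ann0 = sim.make_genome(5, seed=9, overlap_fraction=0.0)
        ann, truth = sim.make_structures(
            ann0, 0.3, boundary_violation=True, seed=9
        )
        crossings = 0
        for up, down in ann.adjacent_pairs():
            up_lab = truth.orf_paired(ann, up)
            down_lab = truth.orf_paired(ann, down)
            # the violation writes a stem arm near the upstream stop and its
            # complement inside the downstream ORF
            if up_lab[-20:].any() and down_lab[25:45].any():
                crossings += 1
        assert crossings >= 1

    def test_infeasible_packing_raises(self):
        ann0 = sim.make_genome(2, orf_len=(90, 90), seed=10)
        with pytest.raises(ValueError, match="infeasible"):
            sim.make_structures(ann0, 0.9, seed=10)

    def test_truth_gini_monotone_in_paired_fraction(self):
        ann0 = sim.make_genome(12, orfs_per_operon=(2, 2), seed=11)
        grid = np.linspace(0.05, 0.75, len(ann0.orfs))
        targets = {o.id: float(g) for o, g in zip(ann0.orfs, grid)}
        ann, truth = sim.make_structures(ann0, targets, seed=11)
        ginis = []
        for o in ann.orfs:
            prof = sim.truth_reactivity(ann, truth, o)
            ginis.append(gini_value(prof.ac_values()))
        order = np.argsort([targets[o.id] for o in ann.orfs])
        g = np.asarray(ginis)[order]
        assert (np.diff(g) > -1e-9).all()


class TestDmsCounts:
    def test_bit_reproducible(self):
        ann0 = sim.make_genome(4, seed=12)
        ann, truth = sim.make_structures(ann0, 0.4, seed=12)
        t1 = sim.simulate_dms_counts(ann, truth, seed=99)
        t2 = sim.simulate_dms_counts(ann, truth, seed=99)
        for key in t1.counts:
            np.testing.assert_array_equal(t1.counts[key], t2.counts[key])

    def test_zero_background_means_zero_gu_counts(self):
        ann0 = sim.make_genome(4, seed=13)
        ann, truth = sim.make_structures(ann0, 0.4, seed=13)
        track = sim.simulate_dms_counts(ann, truth, gu_background=0.0, seed=13)
        for o in ann.orfs:
            seq = np.array(list(ann.orf_sequence(o)))
            prof = orf_profile(track, o)
            assert prof[(seq == "G") | (seq == "T")].sum() == 0

    def test_paired_counts_vanish_in_noiseless_limit(self):
        ann0 = sim.make_genome(4, seed=14)
        ann, truth = sim.make_structures(ann0, 0.5, seed=14)
        track = sim.simulate_dms_counts(
            ann, truth, depth=200, dispersion=0.0, paired_leak=0.0, seed=14
        )
        for o in ann.orfs[:5]:
            lab = truth.orf_paired(ann, o)
            seq = np.array(list(ann.orf_sequence(o)))
            paired_ac = lab & ((seq == "A") | (seq == "C"))
            assert orf_profile(track, o)[paired_ac].sum() == 0

    def test_marginal_mean_matches_formula(self):
        """Monte-Carlo check: mean count at unpaired A/C ~= depth * k."""
        ann0 = sim.make_genome(2, orfs_per_operon=(2, 2), seed=15)
        ann, truth = sim.make_structures(ann0, 0.5, seed=15)
        orf = ann.orfs[0]
        expected, k = sim.expected_dms_means(ann, truth, orf, depth=30.0)
        seq = np.array(list(ann.orf_sequence(orf)))
        lab = truth.orf_paired(ann, orf)
        unpaired_ac = ((seq == "A") | (seq == "C")) & ~lab
        draws = []
        for s in range(70):  # 70 tracks x >140 positions > 1e4 draws
            track = sim.simulate_dms_counts(ann, truth, depth=30.0, seed=1000 + s)
            draws.append(orf_profile(track, orf)[unpaired_ac])
        draws = np.concatenate(draws)
        mean = draws.mean()
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert draws.size >= 10_000
        assert abs(mean - 30.0 * k) <= 3 * se

    def test_orf_mean_coverage_hits_depth_target(self):
        ann0 = sim.make_genome(10, seed=16)
        ann, truth = sim.make_structures(ann0, (0.0, 0.8), seed=16)
        track = sim.simulate_dms_counts(ann, truth, depth=30.0, seed=16)
        covs = [dms.mean_coverage(track, o) for o in ann.orfs]
        assert abs(np.mean(covs) - 30.0) < 2.0


class TestExpression:
    def test_constant_te_when_slope_and_noise_zero(self):
        ann0 = sim.make_genome(5, seed=17)
        ann, truth = sim.make_structures(ann0, (0.0, 0.8), seed=17)
        sim.simulate_expression(ann, truth, te_model=(0.5, 0.0, 0.0), seed=17)
        te = truth.per_orf["true_te"]
        np.testing.assert_allclose(te, np.exp(0.5))

    def test_hundredfold_te_ratio_reflected_in_ribo_density(self):
        """Two-ORF operon with TE ratio 100 and one mRNA level."""
        ann0 = sim.make_genome(1, orfs_per_operon=(2, 2), seed=18)
        ann, truth = sim.make_structures(ann0, 0.0, seed=18)
        truth.per_orf["realized_paired_fraction"] = [0.0, 1.0]
        # ln TE = -b * pf with b = ln(100): TE ratio is exactly 100
        ribo, _ = sim.simulate_expression(
            ann, truth, te_model=(0.0, np.log(100), 0.0),
            ribo_depth=200.0, dispersion=0.0, seed=18,
        )
        up, down = ann.adjacent_pairs()[0]
        r_up = orf_profile(ribo, up).mean()
        r_down = orf_profile(ribo, down).mean()
        ratio = max(r_up, r_down) / min(r_up, r_down)
        assert ratio == pytest.approx(100.0, rel=0.05)

    def test_ramp_multiplier_doubles_early_density(self):
        ann0 = sim.make_genome(5, orf_len=(450, 600), seed=19)
        ann, truth = sim.make_structures(ann0, 0.2, seed=19)
        ribo, _ = sim.simulate_expression(
            ann, truth, ramp=(2.0, 50), dispersion=0.0, seed=19,
            te_model=(0.0, 0.0, 0.0),
        )
        for o in ann.orfs[:4]:
            prof = orf_profile(ribo, o)
            early = prof[: 150].mean()
            plateau = prof[150 : o.n_codons * 3].mean()
            assert early / plateau == pytest.approx(2.0, rel=0.1)

    def test_break_junctions_split_mrna_level(self):
        ann0 = sim.make_genome(40, seed=20)
        ann, truth = sim.make_structures(ann0, 0.2, seed=20)
        _, mrna = sim.simulate_expression(
            ann, truth, break_fraction=0.5, dispersion=0.05, seed=20
        )
        levels = truth.per_orf.set_index("orf_id")["mrna_level"]
        for r in truth.pairs.itertuples():
            ratio = levels[r.downstream_id] / levels[r.upstream_id]
            if r.same_message:
                assert ratio == pytest.approx(1.0)
            else:
                assert ratio > 2.0 or ratio < 0.5


class TestFixtures:
    def test_fixture_round_trip(self, tmp_path):
        bundle = sim.make_dataset(seed=21, n_operons=4, n_dms_replicates=1)
        sim.write_fixture(bundle, tmp_path)
        back = sim.read_fixture(tmp_path)
        assert back.annotation.sequences == bundle.annotation.sequences
        assert back.annotation.orfs == bundle.annotation.orfs
        assert set(back.tracks) == set(bundle.tracks)
        for name in bundle.tracks:
            for key in bundle.tracks[name].counts:
                np.testing.assert_array_equal(
                    back.tracks[name].counts[key], bundle.tracks[name].counts[key]
                )
        for key in bundle.truth.paired:
            np.testing.assert_array_equal(
                back.truth.paired[key], bundle.truth.paired[key]
            )
        pd.testing.assert_frame_equal(
            back.truth.pairs, bundle.truth.pairs, check_dtype=False
        )

    def test_make_dataset_deterministic(self):
        b1 = sim.make_dataset(seed=22, n_operons=3, n_dms_replicates=1)
        b2 = sim.make_dataset(seed=22, n_operons=3, n_dms_replicates=1)
        assert b1.annotation.sequences == b2.annotation.sequences
        for name in b1.tracks:
            for key in b1.tracks[name].counts:
                np.testing.assert_array_equal(
                    b1.tracks[name].counts[key], b2.tracks[name].counts[key]
                )
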