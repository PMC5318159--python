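"""RPKM, footprint-density corrections, TE, ratios, codon occupancy."""

import numpy as np
import pandas as pd
import pytest

from orfstruct import expression as ex
from orfstruct import simulate as sim
from orfstruct.model import CountTrack, GenomeAnnotation, Orf, orf_profile


def _uniform_setup(L=1200, value=1.0, library=1_000_000):
    ann = GenomeAnnotation(
        sequences={"chr": "ACGT" * (L // 2)},
        orfs=[Orf("g1", "chr", 100, 100 + L, "+")],
    )
    track = CountTrack.from_annotation("mrna", ann)
    track.array("chr", "+")[100 : 100 + L] = value
    # pad library size with off-ORF counts
    rest = library - value * L
    track.array("chr", "-")[0] = rest
    return ann, track


class TestRpkm:
    def test_uniform_one_read_per_nt_formula(self):
        # 1 read/nt over 1 kb in a 1e6-read library: RPKM = 1000
        ann, track = _uniform_setup(L=1000)
        assert ex.mrna_rpkm(track, ann.orf("g1")) == pytest.approx(1000.0)

    def test_doubling_library_halves_rpkm(self):
        ann, track = _uniform_setup(L=1000)
        orf = ann.orf("g1")
        one = ex.mrna_rpkm(track, orf, library_size=1e6)
        two = ex.mrna_rpkm(track, orf, library_size=2e6)
        assert two == pytest.approx(one / 2)

    def test_uniform_profile_unchanged_by_winsorization(self):
        v = np.full(100, 7.0)
        np.testing.assert_array_equal(ex.winsorize_two_sided(v, 0.90), v)

    def test_zero_length_orf_rejected(self):
        ann, track = _uniform_setup()
        bad = Orf("z", "chr", 10, 10, "+")
        with pytest.raises(ValueError):
            ex.mrna_rpkm(track, bad)


class TestFootprintDensity:
    def _ribo(self, profile):
        L = profile.size
        pad = (-L) % 4
        seq = "ACGT" * ((L + pad + 200) // 4 + 1)
        ann = GenomeAnnotation(
            sequences={"chr": seq}, orfs=[Orf("g1", "chr", 0, L, "+")]
        )
        track = CountTrack.from_annotation("ribo", ann)
        track.array("chr", "+")[:L] = profile
        return ann, track

    def test_flat_signal_is_a_fixed_point_of_all_corrections(self):
        ann, track = self._ribo(np.full(600, 4.0))
        d = ex.footprint_density(track, ann.orf("g1"), ramp_profile=np.ones(100))
        assert d == pytest.approx(4.0)

    def test_known_ramp_multiplier_is_divided_out(self):
        bundle_ann = sim.make_genome(12, orf_len=(450, 600), seed=51)
        ann, truth = sim.make_structures(bundle_ann, 0.2, seed=51)
        ribo, _ = sim.simulate_expression(
            ann, truth, ramp=(2.0, 50), dispersion=0.02, seed=51,
            te_model=(0.0, 0.0, 0.0),
        )
        cfg = ex.CorrectionConfig()
        ramp = ex.estimate_ramp_profile(ribo, ann, cfg)
        rel_err = []
        for orf in ann.orfs:
            prof = orf_profile(ribo, orf)
            plateau = prof[150 : orf.n_codons * 3 - 15].mean()
            d = ex.footprint_density(ribo, orf, cfg, ramp)
            rel_err.append(abs(d - plateau) / plateau)
        assert np.mean(rel_err) < 0.02

    def test_pause_spike_capped_by_winsorization(self):
        prof = np.full(600, 2.0)
        prof[300:303] = 200.0  # a 100x pause
        ann, track = self._ribo(prof)
        d = ex.footprint_density(track, ann.orf("g1"))
        assert abs(d - 2.0) / 2.0 < 0.05

    def test_edge_codons_masked(self):
        prof = np.full(300, 1.0)
        prof[:15] = 50.0  # initiation pile-up within the first 5 codons
        prof[-15:] = 50.0
        ann, track = self._ribo(prof)
        assert ex.footprint_density(track, ann.orf("g1")) == pytest.approx(1.0)

    def test_too_short_gene_flagged_nan(self):
        ann, track = self._ribo(np.full(30, 1.0))
        assert np.isnan(ex.footprint_density(track, ann.orf("g1")))


class TestTranslationEfficiency:
    def test_te_is_density_over_rpkm(self):
        bundle = sim.make_dataset(seed=52, n_operons=5, n_dms_replicates=0)
        table = ex.expression_table(
            bundle.tracks["ribo"], bundle.tracks["mrna"], bundle.annotation
        )
        ok = table["te"].notna()
        assert ok.any()
        np.testing.assert_allclose(
            table.loc[ok, "te"], table.loc[ok, "density"] / table.loc[ok, "rpkm"]
        )

    def test_min_reads_cutoff_excludes_127(self):
        bundle = sim.make_dataset(seed=53, n_operons=4, n_dms_replicates=0)
        ann = bundle.annotation
        ribo = bundle.tracks["ribo"]
        starved = ann.orfs[0]
        arr = ribo.array(starved.replicon, starved.strand)
        arr[starved.start : starved.end] = 0.0
        arr[starved.start : starved.start + 127] = 1.0  # 127 reads exactly
        table = ex.expression_table(ribo, bundle.tracks["mrna"], ann)
        row = table.set_index("orf_id").loc[starved.id]
        assert row["low_reads"] and np.isnan(row["te"])

    def test_excluded_gene_list_flags_but_keeps_row(self):
        bundle = sim.make_dataset(seed=54, n_operons=3, n_dms_replicates=0)
        victim = bundle.annotation.orfs[0].id
        cfg = ex.CorrectionConfig(excluded_genes=(victim,))
        table = ex.expression_table(
            bundle.tracks["ribo"], bundle.tracks["mrna"], bundle.annotation, cfg
        )
        row = table.set_index("orf_id").loc[victim]
        assert row["excluded_gene"] and np.isnan(row["te"])

    def test_te_invariant_to_depth_rescaling(self):
        bundle = sim.make_dataset(seed=55, n_operons=4, n_dms_replicates=0)
        ann = bundle.annotation
        ribo, mrna = bundle.tracks["ribo"], bundle.tracks["mrna"]
        t1 = ex.expression_table(ribo, mrna, ann)
        scaled = CountTrack.from_annotation("mrna", ann)
        for key in mrna.counts:
            scaled.counts[key][:] = mrna.counts[key] * 10.0
        t2 = ex.expression_table(ribo, scaled, ann)
        ok = t1["te"].notna()
        np.testing.assert_allclose(t1.loc[ok, "te"], t2.loc[ok, "te"], rtol=1e-9)

    def test_recovers_true_te_ordering(self):
        from scipy import stats as sps

        bundle = sim.make_dataset(
            seed=56, n_operons=25, te_model=(0.0, 4.0, 0.3),
            mrna_depth=50.0, ribo_depth=50.0, n_dms_replicates=0,
        )
        table = ex.expression_table(
            bundle.tracks["ribo"], bundle.tracks["mrna"], bundle.annotation
        )
        m = table.merge(bundle.truth.per_orf, on="orf_id")
        ok = m["te"].notna()
        rho = sps.spearmanr(m.loc[ok, "te"], m.loc[ok, "true_te"]).statistic
        assert rho >= 0.95


class TestTeRatios:
    def test_equal_tes_give_unit_ratio(self):
        pairs = pd.DataFrame(
            [{"upstream_id": "a", "downstream_id": "b", "spacing": 10}]
        )
        table = pd.DataFrame(
            [{"orf_id": "a", "te": 0.5}, {"orf_id": "b", "te": 0.5}]
        )
        df, _, _ = ex.adjacent_te_ratios(pairs, table)
        assert df["te_ratio"].iloc[0] == pytest.approx(1.0)

    def test_dusb_fis_like_contrast(self):
        # printed TEs 0.02 and 2.06 give a ~103-fold downstream/upstream ratio
        pairs = pd.DataFrame(
            [{"upstream_id": "dusB", "downstream_id": "fis", "spacing": 25}]
        )
        table = pd.DataFrame(
            [{"orf_id": "dusB", "te": 0.02}, {"orf_id": "fis", "te": 2.06}]
        )
        df, _, _ = ex.adjacent_te_ratios(pairs, table)
        assert df["te_ratio"].iloc[0] == pytest.approx(103.0)

    def test_pairs_missing_te_are_skipped(self):
        pairs = pd.DataFrame(
            [
                {"upstream_id": "a", "downstream_id": "b", "spacing": 5},
                {"upstream_id": "b", "downstream_id": "c", "spacing": 5},
            ]
        )
        table = pd.DataFrame(
            [
                {"orf_id": "a", "te": 1.0},
                {"orf_id": "b", "te": np.nan},
                {"orf_id": "c", "te": 2.0},
            ]
        )
        df, _, _ = ex.adjacent_te_ratios(pairs, table)
        assert df.empty

    def test_identical_class_distributions_have_uniform_ks_p(self):
        rng = np.random.default_rng(57)
        ps = []
        for rep in range(40):
            n = 60
            ratios = rng.lognormal(0.0, 1.0, size=2 * n)
            pairs = pd.DataFrame(
                {
                    "upstream_id": [f"u{i}" for i in range(2 * n)],
                    "downstream_id": [f"d{i}" for i in range(2 * n)],
                    "spacing": [(-1 if i < n else 10) for i in range(2 * n)],
                }
            )
            table = pd.DataFrame(
                {
                    "orf_id": [f"u{i}" for i in range(2 * n)]
                    + [f"d{i}" for i in range(2 * n)],
                    "te": np.concatenate([np.ones(2 * n), ratios]),
                }
            )
            _, _, p = ex.adjacent_te_ratios(pairs, table)
            ps.append(p)
        # under the null, p-values should not pile up at small values
        assert np.mean(np.asarray(ps) < 0.05) < 0.2


class TestCodonOccupancy:
    def _pause_setup(self, pause_codon="CTA", factor=3.0):
        ann = sim.make_genome(10, seed=58)  # random codons, CTA present
        truth = sim.SimulationTruth(
            per_orf=pd.DataFrame(
                {
                    "orf_id": [o.id for o in ann.orfs],
                    "operon": [o.operon for o in ann.orfs],
                    "target_paired_fraction": 0.0,
                    "realized_paired_fraction": 0.0,
                }
            ),
            paired={
                (rep, s): np.zeros(len(seq), dtype=bool)
                for rep, seq in ann.sequences.items()
                for s in ("+", "-")
            },
            pairs=pd.DataFrame(
                columns=["upstream_id", "downstream_id", "operon", "spacing",
                         "same_message"]
            ),
        )
        ribo, _ = sim.simulate_expression(
            ann, truth, codon_pause={pause_codon: factor}, dispersion=0.0,
            te_model=(0.0, 0.0, 0.0), seed=58,
        )
        return ann, ribo

    def test_uniform_signal_gives_unit_occupancy(self):
        ann, ribo = self._pause_setup(factor=1.0)
        assert ex.codon_occupancy(ribo, ann, "CTG") == pytest.approx(1.0, rel=0.05)

    def test_engineered_pause_recovered(self):
        ann, ribo = self._pause_setup("CTA", 3.0)
        cta = ex.codon_occupancy(ribo, ann, "CTA")
        ctg = ex.codon_occupancy(ribo, ann, "CTG")
        assert cta == pytest.approx(3.0, rel=0.1)
        assert ctg == pytest.approx(1.0, rel=0.1)

    def test_control_normalization_of_identical_samples(self):
        ann, ribo = self._pause_setup(factor=1.0)
        base = ex.codon_occupancy(ribo, ann, "CTG")
        assert ex.codon_occupancy(ribo, ann, "CTG", control=base) == pytest.approx(1.0)
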