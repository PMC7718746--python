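import numpy as np
import pytest

import damidkit as dk
from damidkit.differential import isoform_ratios


@pytest.fixture(scope="module")
def diff_setup(small_dataset, small_assignment, polII_tracks):
    kd = [polII_tracks[("knockdown", r)] for r in range(2)]
    ctl = [polII_tracks[("control", r)] for r in range(2)]
    return kd, ctl


class TestDifferenceTracks:
    def test_identity_gives_zero(self, diff_setup):
        kd, _ = diff_setup
        diffs = dk.difference_tracks(kd, kd)
        for d in diffs:
            assert np.allclose(d.values, 0.0)

    def test_arithmetic(self):
        fmap = dk.build_fragment_map({"c": "AAGATC" + "A" * 4})
        kd = dk.RatioTrack(fmap, [1.5, 1.5], genotype="knockdown", replicate=0)
        ctl = dk.RatioTrack(fmap, [0.5, 0.5], genotype="control", replicate=0)
        (d,) = dk.difference_tracks([kd], [ctl])
        assert np.allclose(d.values, 1.0)

    def test_elementwise_oracle(self, diff_setup):
        kd, ctl = diff_setup
        diffs = dk.difference_tracks(kd, ctl)
        for d, k, c in zip(diffs, kd, ctl):
            assert np.array_equal(d.values, k.values - c.values)

    def test_unequal_replicates_rejected(self, diff_setup):
        kd, ctl = diff_setup
        with pytest.raises(ValueError, match="pairing"):
            dk.difference_tracks(kd, ctl[:1])

    def test_scaled_inputs_rejected(self, diff_setup):
        kd, ctl = diff_setup
        with pytest.raises(ValueError, match="unscaled"):
            dk.difference_tracks([dk.scale_by_sd(kd[0])], [ctl[0]])


class TestLocusAverageRatio:
    def test_constant_gene(self, small_assignment):
        fmap = small_assignment.fmap
        track = dk.RatioTrack(fmap, np.full(fmap.n_fragments, 0.5))
        gid = small_assignment.gene_ids()[0]
        assert dk.locus_average_ratio(track, gid, small_assignment) == pytest.approx(0.5)

    def test_zero_track(self, small_assignment):
        fmap = small_assignment.fmap
        track = dk.RatioTrack(fmap, np.zeros(fmap.n_fragments))
        gid = small_assignment.gene_ids()[3]
        assert dk.locus_average_ratio(track, gid, small_assignment) == 0.0

    def test_loop_oracle(self, small_assignment, diff_setup):
        kd, ctl = diff_setup
        avg = dk.average_tracks(dk.difference_tracks(kd, ctl))
        lens = avg.fmap.lengths
        for gid in small_assignment.gene_ids()[:10]:
            idx = small_assignment.gene_fragments(gid)
            num = sum(lens[i] * avg.values[i] for i in idx)
            den = sum(lens[i] for i in idx)
            assert dk.locus_average_ratio(avg, gid, small_assignment) == pytest.approx(
                num / den, abs=1e-12
            )

    def test_unknown_gene_errors(self, small_assignment, diff_setup):
        kd, ctl = diff_setup
        avg = dk.average_tracks(dk.difference_tracks(kd, ctl))
        with pytest.raises(KeyError):
            dk.locus_average_ratio(avg, "no_such_gene", small_assignment)


def _numerator(small_assignment, polII_tracks, genotype="knockdown"):
    avg = dk.average_tracks(
        [polII_tracks[(genotype, r)] for r in range(2)]
    )
    table = dk.occupancy_significance(avg, small_assignment, n_perm=500, seed=5)
    genes = dk.gene_table_from_transcripts(table)
    genes.attrs["genotype"] = genotype
    return genes


class TestDifferentialGenes:
    def test_genotype_label_checked(self, small_assignment, diff_setup, polII_tracks):
        kd, ctl = diff_setup
        numerator = _numerator(small_assignment, polII_tracks)
        numerator.attrs["genotype"] = "control"
        with pytest.raises(ValueError, match="genotype"):
            dk.differential_genes(
                dk.difference_tracks(kd, ctl),
                small_assignment,
                n_perm=200,
                numerator_gene_table=numerator,
                numerator_genotype="knockdown",
            )

    def test_antisymmetry_before_filtering(self, small_assignment, diff_setup):
        kd, ctl = diff_setup
        fwd = dk.average_tracks(dk.difference_tracks(kd, ctl))
        rev = dk.average_tracks(dk.difference_tracks(ctl, kd))
        assert np.allclose(fwd.values, -rev.values, atol=1e-12)
        for gid in small_assignment.gene_ids()[:5]:
            a = dk.locus_average_ratio(fwd, gid, small_assignment)
            b = dk.locus_average_ratio(rev, gid, small_assignment)
            assert a == pytest.approx(-b, abs=1e-12)

    def test_shared_signal_invariance(
        self, small_assignment, diff_setup, polII_tracks
    ):
        kd, ctl = diff_setup
        numerator = _numerator(small_assignment, polII_tracks)
        base = dk.differential_genes(
            dk.difference_tracks(kd, ctl),
            small_assignment,
            n_perm=300,
            seed=4,
            numerator_gene_table=numerator,
        )
        # add the same fragment-wise signal to both genotypes
        rng = np.random.default_rng(0)
        shared = rng.normal(size=kd[0].fmap.n_fragments)
        kd2 = [t.with_values(t.values + shared) for t in kd]
        ctl2 = [t.with_values(t.values + shared) for t in ctl]
        shifted = dk.differential_genes(
            dk.difference_tracks(kd2, ctl2),
            small_assignment,
            n_perm=300,
            seed=4,
            numerator_gene_table=numerator,
        )
        assert base.query("in_up_list").gene_id.tolist() == (
            shifted.query("in_up_list").gene_id.tolist()
        )

    def test_numerator_filter_semantics(
        self, small_dataset, small_assignment, diff_setup, polII_tracks
    ):
        kd, ctl = diff_setup
        _, _, _, truth, _ = small_dataset
        numerator = _numerator(small_assignment, polII_tracks)
        table = dk.differential_genes(
            dk.difference_tracks(kd, ctl),
            small_assignment,
            n_perm=2000,
            seed=4,
            numerator_gene_table=numerator,
        )
        sig_up = table[(table.direction == "up") & (table.fdr < 0.01)]
        assert not sig_up.empty
        # strip numerator significance from one significantly-up gene
        victim = sig_up.gene_id.iloc[0]
        hacked = numerator.copy()
        hacked.attrs["genotype"] = numerator.attrs["genotype"]
        hacked.loc[hacked.gene_id == victim, "significant"] = False
        table2 = dk.differential_genes(
            dk.difference_tracks(kd, ctl),
            small_assignment,
            n_perm=2000,
            seed=4,
            numerator_gene_table=hacked,
        )
        row = table2.set_index("gene_id").loc[victim]
        assert not row.in_up_list
        assert not row.bound_in_numerator
        assert "numerator" in row.exclusion_reason

    def test_fc_threshold_applies_to_down_only(
        self, small_assignment, diff_setup, polII_tracks
    ):
        kd, ctl = diff_setup
        numerator = _numerator(small_assignment, polII_tracks)
        table = dk.differential_genes(
            dk.difference_tracks(kd, ctl),
            small_assignment,
            n_perm=300,
            seed=4,
            fc_threshold=1.3,
            numerator_gene_table=numerator,
        )
        down_called = table[table.in_down_list]
        assert (down_called.locus_delta.abs() > np.log2(1.3)).all()
        # up-gene membership never consults passes_fc
        up = table[table.in_up_list]
        assert (up.fdr < 0.01).all() and up.bound_in_numerator.all()

    def test_isoform_ratios_match_transcript_means(
        self, small_assignment, diff_setup
    ):
        kd, ctl = diff_setup
        avg = dk.average_tracks(dk.difference_tracks(kd, ctl))
        iso = isoform_ratios(avg, small_assignment).set_index("transcript_id")
        table, _ = dk.transcript_occupancy(avg, small_assignment, min_fragments=1)
        for _, row in table.iterrows():
            assert iso.loc[row.transcript_id, "delta"] == pytest.approx(
                row.mean_occupancy, abs=1e-12
            )

    def test_sensitivity_monotone_in_effect_size(self):
        from dataclasses import replace

        recovered = []
        for effect in (0.5, 1.0, 2.0):
            cfg = replace(
                dk.SimulationConfig(seed=21, n_chromosomes=2,
                                    chromosome_length=80_000, n_genes=50,
                                    n_derepressed=8, library_size=400_000),
                effect_size=effect,
            )
            _, fmap, ann, truth, counts = dk.simulate_experiment(cfg)
            assign = dk.map_fragments_to_transcripts(fmap, ann)
            tracks = {
                (gt, r): dk.compute_ratio_track(
                    counts[(gt, "Dam-PolII", r)], counts[(gt, "Dam", r)], fmap,
                    genotype=gt, replicate=r,
                )
                for gt in ("control", "knockdown")
                for r in range(2)
            }
            numerator = dk.gene_table_from_transcripts(
                dk.occupancy_significance(
                    dk.average_tracks(
                        [tracks[("knockdown", r)] for r in range(2)]
                    ),
                    assign, n_perm=500, seed=5,
                )
            )
            table = dk.differential_genes(
                dk.difference_tracks(
                    [tracks[("knockdown", r)] for r in range(2)],
                    [tracks[("control", r)] for r in range(2)],
                ),
                assign, n_perm=2000, seed=6, numerator_gene_table=numerator,
            )
            true_up = set(truth.loc[truth.delta_polII_knockdown > 0, "gene_id"])
            called = set(table.query("in_up_list").gene_id)
            recovered.append(len(true_up & called))
        assert recovered == sorted(recovered)
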