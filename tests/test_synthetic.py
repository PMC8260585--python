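import numpy as np
import pytest
from scipy import stats

from diazoquant import (
    SampleSpec,
    SyntheticTruth,
    TaxonSpec,
    TruthValidationError,
    default_truth,
    derive_seed,
    generate_truth,
    simulate_flow_cytometry,
    simulate_imaging,
    simulate_metagenome,
    synthetic_catalog,
)
from diazoquant.synthetic import _marker_weights, concentration_factor_of, with_seed


def _one_taxon_truth(density=1e3, ploidy=1.0, background=1e6, **kw):
    return SyntheticTruth(
        taxa=(TaxonSpec("solo", "cyanobacteria", density, ploidy),),
        background_bacteria_density=background,
        outgroup_read_fraction=kw.get("outgroup", 0.0),
        unassigned_read_fraction=kw.get("unassigned", 0.0),
    )


class TestTruth:
    def test_config_passthrough_and_fraction(self):
        config = {
            "taxa": [{"label": "solo", "group": "cyanobacteria", "density": 1e3, "ploidy": 1}],
            "background_bacteria_density": 1e6,
        }
        truth = generate_truth(config, seed=5)
        assert truth.taxon("solo").density == 1e3
        assert truth.diazotroph_cell_fraction == pytest.approx(1e3 / 1e6)

    def test_identical_config_and_seed_gives_identical_truth(self, tmp_path):
        config = tmp_path / "c.yaml"
        config.write_text(
            "taxa:\n- {label: solo, group: cyano, density: 1000, ploidy: 2}\n"
            "background_bacteria_density: 1.0e6\n"
        )
        assert generate_truth(str(config), seed=1) == generate_truth(str(config), seed=1)

    @pytest.mark.parametrize(
        "bad",
        [
            {"density": -1.0, "ploidy": 1.0},
            {"density": 10.0, "ploidy": -1.0},
        ],
    )
    def test_negative_density_or_ploidy_rejected(self, bad):
        with pytest.raises(TruthValidationError):
            TaxonSpec("x", "g", bad["density"], bad["ploidy"])

    def test_duplicate_labels_rejected(self):
        taxa = (TaxonSpec("a", "g", 1, 1), TaxonSpec("a", "g", 2, 1))
        with pytest.raises(TruthValidationError, match="unique"):
            SyntheticTruth(taxa=taxa, background_bacteria_density=1e6)

    def test_fractions_must_leave_room_for_markers(self):
        with pytest.raises(TruthValidationError):
            SyntheticTruth(
                taxa=(TaxonSpec("a", "g", 1, 1),),
                background_bacteria_density=1e6,
                outgroup_read_fraction=0.5,
                unassigned_read_fraction=0.5,
            )


class TestMetagenome:
    def test_counts_conserve_total_reads(self, truth, catalog):
        for seed in (1, 2, 3):
            spec = SampleSpec("s", V_seawater=10, Vi=1e-3, total_reads=5000, seed=seed)
            reads, counts = simulate_metagenome(truth, spec, catalog)
            assert counts["count"].sum() == 5000
            assert len(reads) == 5000

    def test_fixed_seed_reproduces_reads_and_counts(self, truth, catalog):
        spec = SampleSpec("s", V_seawater=10, Vi=1e-3, total_reads=2000, seed=9)
        r1, c1 = simulate_metagenome(truth, spec, catalog)
        r2, c2 = simulate_metagenome(truth, spec, catalog)
        assert r1.equals(r2) and c1.equals(c2)

    def test_nifh_count_within_binomial_ci_of_expectation(self):
        """nifH weight 1 vs recA weight 999 at 1e5 reads: count in the 99% CI of
        Binomial(1e5, 1e-3)."""
        truth = _one_taxon_truth(density=1.0, ploidy=1.0, background=999.0)
        spec = SampleSpec("s", V_seawater=10, Vi=1e-3, total_reads=100_000, seed=7)
        cat = synthetic_catalog(truth, seed=0)
        _, counts = simulate_metagenome(truth, spec, cat, emit_reads=False)
        nifh = int(counts.loc[counts["gene"] == "nifH", "count"].sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], 100_000, 1e-3)
        assert lo <= nifh <= hi

    def test_zero_substitution_rate_reads_are_exact_substrings(self, catalog):
        truth = default_truth()
        spec = SampleSpec("s", V_seawater=10, Vi=1e-3, total_reads=500, seed=3,
                          substitution_rate=0.0)
        reads, _ = simulate_metagenome(truth, spec, catalog)
        markers = reads[reads["source_gene"] != "unassigned"]
        assert not markers.empty
        for row in markers.itertuples(index=False):
            assert row.sequence in catalog[row.source_ref].sequence

    def test_length_weighted_mode_scales_weights_by_gene_length(self):
        """Equal copy weights, nifH 750 bp vs recA 1000 bp: expected read
        ratio is exactly 750/1000."""
        truth = _one_taxon_truth(density=1e6, ploidy=1.0, background=1e6)
        cat = synthetic_catalog(truth, seed=0, recA_length=1000)
        _, w_copy = _marker_weights(truth, cat, "copy")
        _, w_len = _marker_weights(truth, cat, "length_weighted")
        assert w_copy[0] / w_copy[1] == pytest.approx(1.0)
        assert w_len[0] / w_len[1] == pytest.approx(0.75)

    def test_missing_catalog_sequence_raises(self, catalog):
        truth = SyntheticTruth(
            taxa=(TaxonSpec("not_in_catalog", "g", 1e3, 1.0),),
            background_bacteria_density=1e6,
        )
        with pytest.raises(KeyError, match="not_in_catalog"):
            simulate_metagenome(truth, SampleSpec("s", 10, 1e-3, 100), catalog)


class TestImaging:
    def test_zero_density_gives_zero_detections(self):
        truth = _one_taxon_truth(density=0.0)
        spec = SampleSpec("s", V_seawater=100, Vi=1e-3, total_reads=1, seed=1)
        assert simulate_imaging(truth, spec).empty

    def test_poisson_mean_matches_density_vi_cf(self):
        """density 100/L, Vi 1e-3 L, Cf 30 -> mean detections 3.0 (2 SE over 1e4 reps)."""
        truth = _one_taxon_truth(density=100.0)
        spec = SampleSpec("s", V_seawater=100, Vi=1e-3, total_reads=1, seed=0)
        assert concentration_factor_of(spec) == pytest.approx(30.0)
        n_rep = 10_000
        counts = np.array(
            [len(simulate_imaging(truth, spec, seed=k)) for k in range(n_rep)]
        )
        se = np.sqrt(3.0 / n_rep)
        assert abs(counts.mean() - 3.0) < 2 * se

    def test_fixed_seed_reproduces_table(self, truth):
        spec = SampleSpec("s", V_seawater=50, Vi=1e-4, total_reads=1, seed=5)
        t1 = simulate_imaging(truth, spec, seed=77)
        t2 = simulate_imaging(truth, spec, seed=77)
        assert t1.equals(t2)

    def test_axes_respect_minor_le_major(self, truth):
        spec = SampleSpec("s", V_seawater=100, Vi=1e-3, total_reads=1, seed=8)
        det = simulate_imaging(truth, spec)
        assert not det.empty
        assert (det["minor_um"] <= det["major_um"]).all()
        assert (det["minor_um"] > 0).all()


class TestFlowCytometry:
    def test_zero_cv_returns_truth_exactly(self, truth):
        spec = SampleSpec("s", V_seawater=10, Vi=1e-3, total_reads=1, seed=1)
        assert simulate_flow_cytometry(truth, spec, cv=0.0) == truth.background_bacteria_density

    def test_lognormal_mean_matches_truth(self, truth):
        spec = SampleSpec("s", V_seawater=10, Vi=1e-3, total_reads=1, seed=1)
        draws = np.array(
            [simulate_flow_cytometry(truth, spec, cv=0.1, seed=k) for k in range(10_000)]
        )
        bg = truth.background_bacteria_density
        se = bg * 0.1 / np.sqrt(draws.size)
        assert abs(draws.mean() - bg) < 2 * se

    def test_negative_cv_rejected(self, truth):
        spec = SampleSpec("s", V_seawater=10, Vi=1e-3, total_reads=1, seed=1)
        with pytest.raises(ValueError):
            simulate_flow_cytometry(truth, spec, cv=-0.1)


def test_derive_seed_is_deterministic_and_bounded():
    seeds = [derive_seed(123, k) for k in range(100)]
    assert seeds == [derive_seed(123, k) for k in range(100)]
    assert len(set(seeds)) == 100
    assert all(0 <= s < 2**31 for s in seeds)


def test_with_seed_changes_only_the_seed(sample_spec):
    s2 = with_seed(sample_spec, 7)
    assert s2.seed == 7 and s2.sample_id == sample_spec.sample_id
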