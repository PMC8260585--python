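import pytest

from diazoquant import (
    MarkerCounts,
    RecruitmentParams,
    SampleSpec,
    count_marker_reads,
    recruit,
    simulate_metagenome,
    synthetic_catalog,
)
from diazoquant.recruitment import (
    STATUS_ASSIGNED,
    STATUS_LOW_COMPLEXITY,
    STATUS_OUTGROUP,
    STATUS_TOO_SHORT,
)

from _oracle import oracle_recruit


@pytest.fixture(scope="module")
def five_taxa_catalog(five_taxa_truth):
    return synthetic_catalog(five_taxa_truth, seed=21)


def _simulated_reads(truth, catalog, n_reads, sub_rate, seed, read_length=100):
    spec = SampleSpec(
        "sim", V_seawater=10, Vi=1e-3, total_reads=n_reads,
        read_length=read_length, substitution_rate=sub_rate, seed=seed,
    )
    reads, _ = simulate_metagenome(truth, spec, catalog)
    return reads


class TestGates:
    def test_short_read_is_unassigned(self, five_taxa_catalog):
        ref = five_taxa_catalog.sequences[0]
        table = recruit([("short", ref.sequence[:60])], five_taxa_catalog)
        assert list(table["status"]) == [STATUS_TOO_SHORT]

    def test_low_complexity_read_is_unassigned(self, five_taxa_catalog):
        table = recruit([("polyA", "A" * 100)], five_taxa_catalog)
        assert list(table["status"]) == [STATUS_LOW_COMPLEXITY]

    def test_outgroup_read_is_recorded_but_excluded_from_marker_counts(
        self, five_taxa_catalog
    ):
        og = five_taxa_catalog.subset("outgroup_nifH_like")[0]
        table = recruit([("decoy", og.sequence[100:200])], five_taxa_catalog)
        assert list(table["status"]) == [STATUS_OUTGROUP]
        counts = count_marker_reads(table, five_taxa_catalog, "s")
        assert counts.reads_nifH == 0 and counts.reads_outgroup == 1

    def test_empty_read_set_gives_empty_table(self, five_taxa_catalog):
        table = recruit([], five_taxa_catalog)
        assert table.empty


class TestRecovery:
    def test_taxon_recall_at_five_percent_divergence(
        self, five_taxa_truth, five_taxa_catalog
    ):
        """200 reads at 5% substitution from 5 mutually divergent taxa:
        recall >= 95%, cross-taxon misassignment <= 2%."""
        reads = _simulated_reads(five_taxa_truth, five_taxa_catalog, 200, 0.05, seed=13)
        table = recruit(reads, five_taxa_catalog).set_index("read_id")
        truth_map = dict(zip(reads["read_id"], reads["source_ref"]))
        correct = wrong_taxon = 0
        for rid, src_ref in truth_map.items():
            status = table.loc[rid, "status"]
            if status == STATUS_ASSIGNED and table.loc[rid, "reference_id"] == src_ref:
                correct += 1
            elif status == STATUS_ASSIGNED:
                wrong_taxon += 1
        assert correct / len(truth_map) >= 0.95
        assert wrong_taxon / len(truth_map) <= 0.02

    def test_matches_exhaustive_oracle_on_small_problem(
        self, five_taxa_truth, five_taxa_catalog
    ):
        reads = _simulated_reads(
            five_taxa_truth, five_taxa_catalog, 20, 0.08, seed=4, read_length=80
        )
        pairs = list(zip(reads["read_id"], reads["sequence"]))
        pairs.append(("tiny", "ACGT" * 10))
        pairs.append(("junk", "A" * 80))
        params = RecruitmentParams()
        table = recruit(pairs, five_taxa_catalog, params).set_index("read_id")
        expected = oracle_recruit(pairs, five_taxa_catalog, params)
        for rid, (ref_id, status) in expected.items():
            assert table.loc[rid, "status"] == status
            assert table.loc[rid, "reference_id"] == ref_id


class TestMonotonicityAndConservation:
    def test_raising_min_identity_never_increases_counts(
        self, five_taxa_truth, five_taxa_catalog
    ):
        reads = _simulated_reads(five_taxa_truth, five_taxa_catalog, 120, 0.1, seed=6)
        previous = None
        for min_id in (70.0, 80.0, 90.0, 97.0):
            params = RecruitmentParams(min_identity=min_id)
            counts = count_marker_reads(
                recruit(reads, five_taxa_catalog, params), five_taxa_catalog, "s"
            )
            if previous is not None:
                assert counts.reads_recA <= previous.reads_recA
                assert counts.reads_outgroup <= previous.reads_outgroup
                for taxon, c in counts.reads_nifH_by_taxon.items():
                    assert c <= previous.reads_nifH_by_taxon.get(taxon, 0)
            previous = counts

    def test_statuses_partition_the_read_set(self, truth, catalog):
        spec = SampleSpec("s", V_seawater=10, Vi=1e-3, total_reads=150,
                          substitution_rate=0.03, seed=17)
        reads, _ = simulate_metagenome(truth, spec, catalog)
        counts = count_marker_reads(recruit(reads, catalog), catalog, "s")
        assert counts.total == len(reads)


class TestCounting:
    def test_tally_by_taxon(self, five_taxa_catalog):
        ref_a = five_taxa_catalog.for_taxon("taxon_0")[0]
        rec = five_taxa_catalog.subset("recA")[0]
        reads = [(f"a{k}", ref_a.sequence[k : k + 90]) for k in range(7)]
        reads += [(f"r{k}", rec.sequence[k : k + 90]) for k in range(3)]
        table = recruit(reads, five_taxa_catalog)
        counts = count_marker_reads(table, five_taxa_catalog, "s")
        assert counts.reads_nifH_by_taxon == {"taxon_0": 7}
        assert counts.reads_recA == 3

    def test_empty_table_gives_all_zero_counts(self, five_taxa_catalog):
        counts = count_marker_reads(recruit([], five_taxa_catalog), five_taxa_catalog, "s")
        assert counts.total == 0

    def test_unknown_level_rejected(self, five_taxa_catalog):
        table = recruit([], five_taxa_catalog)
        with pytest.raises(ValueError, match="level"):
            count_marker_reads(table, five_taxa_catalog, "s", level="species")

    def test_group_level_aggregates_taxa(self, truth, catalog):
        spec = SampleSpec("s", V_seawater=10, Vi=1e-3, total_reads=300, seed=23)
        reads, _ = simulate_metagenome(truth, spec, catalog)
        by_taxon = count_marker_reads(recruit(reads, catalog), catalog, "s", level="taxon")
        by_group = count_marker_reads(recruit(reads, catalog), catalog, "s", level="group")
        assert by_group.reads_nifH == by_taxon.reads_nifH
        assert set(by_group.reads_nifH_by_taxon) <= {
            "cyanobacteria", "proteobacteria", "planctomycetes"
        }

    def test_from_latent_matches_simulator_totals(self, truth, catalog):
        spec = SampleSpec("s", V_seawater=10, Vi=1e-3, total_reads=4000, seed=31)
        _, latent = simulate_metagenome(truth, spec, catalog, emit_reads=False)
        counts = MarkerCounts.from_latent(latent)
        assert counts.total == 4000
        assert counts.reads_recA == int(latent.loc[latent["gene"] == "recA", "count"].sum())
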