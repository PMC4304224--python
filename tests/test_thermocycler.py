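"""Thermocycler simulation: extension, amplicon calling, trajectories."""

import pytest

from pdpcr import (
    CycleProtocol,
    PairingMode,
    QPCRResult,
    Strand,
    antiparallel_complement,
    extend_primer,
    find_binding_sites,
    parallel_complement,
    relative_quantity,
    reverse,
    run_pcr,
    threshold_cycle,
)
from pdpcr.design import design_conventional_pair, design_pdpcr_pair
from pdpcr.fixtures import FixtureSpec, generate_template

PROTO = CycleProtocol(cycles=30, anneal_celsius=55.0)


def one_site(primer, strand, mode):
    (site,) = find_binding_sites(primer, strand, mode=mode)
    return site


class TestExtendPrimer:
    def test_parallel_extension_copies_to_template_3prime_end(
        self, demo, template_strand
    ):
        site = one_site(demo["PD-PCR-1"], template_strand, PairingMode.PARALLEL)
        product = extend_primer(site, template_strand, demo["PD-PCR-1"])
        assert product.seq == parallel_complement(template_strand.seq)
        assert len(product) == 120
        assert product.origin.value == "primer_extension"

    def test_antiparallel_extension_copies_to_template_5prime_end(
        self, demo, template_strand
    ):
        site = one_site(demo["PCR-1"], template_strand, PairingMode.ANTIPARALLEL)
        product = extend_primer(site, template_strand, demo["PCR-1"])
        assert product.seq == antiparallel_complement(template_strand.seq)

    def test_full_coverage_site_yields_primer_itself(self):
        strand = Strand("GATTACAGATTACAGATTACAGATT")
        primer = antiparallel_complement(strand.seq)
        site = one_site(primer, strand, PairingMode.ANTIPARALLEL)
        product = extend_primer(site, strand, primer)
        assert product.seq == primer

    def test_mismatched_primer_rejected(self, demo, template_strand):
        site = one_site(demo["PCR-1"], template_strand, PairingMode.ANTIPARALLEL)
        with pytest.raises(ValueError):
            extend_primer(site, template_strand, demo["PD-PCR-1"])


class TestSchemes:
    def test_conventional_run_amplifies_template_without_polarity_change(
        self, demo, template_strand
    ):
        report = run_pcr(
            [template_strand], [demo["PCR-1"], demo["PCR-2"]], PROTO
        )
        assert len(report.amplicons) == 1
        amp = report.amplicons[0]
        assert amp.length == 120
        assert {str(amp.top_strand), str(amp.bottom_strand)} == {
            str(template_strand.seq),
            str(antiparallel_complement(template_strand.seq)),
        }
        assert amp.same_polarity_as_template and not amp.opposite_polarity

    def test_pdpcr_run_amplifies_opposite_polarity_product(
        self, demo, template_strand
    ):
        report = run_pcr(
            [template_strand],
            [demo["PD-PCR-1"], demo["PD-PCR-2"]],
            PROTO,
            allow_parallel=True,
        )
        assert len(report.amplicons) == 1
        amp = report.amplicons[0]
        assert amp.length == 120
        assert {str(amp.top_strand), str(amp.bottom_strand)} == {
            str(parallel_complement(template_strand.seq)),
            str(reverse(template_strand.seq)),
        }
        assert amp.opposite_polarity and not amp.same_polarity_as_template

    def test_pdpcr_requires_parallel_annealing(self, demo, template_strand):
        report = run_pcr(
            [template_strand],
            [demo["PD-PCR-1"], demo["PD-PCR-2"]],
            PROTO,
            allow_parallel=False,
        )
        assert report.amplicons == []

    @pytest.mark.parametrize("primer_name", ["PD-PCR-1", "PD-PCR-2"])
    def test_single_primer_gives_runoff_only(self, demo, template_strand, primer_name):
        report = run_pcr(
            [template_strand], [demo[primer_name]], PROTO, allow_parallel=True
        )
        assert report.amplicons == []

    def test_no_template_control(self, demo):
        for pair in (("PCR-1", "PCR-2"), ("PD-PCR-1", "PD-PCR-2")):
            report = run_pcr(
                [], [demo[p] for p in pair], PROTO, allow_parallel=True
            )
            assert report.amplicons == []

    def test_no_primers_rejected(self, template_strand):
        with pytest.raises(ValueError):
            run_pcr([template_strand], [], PROTO)

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            CycleProtocol(cycles=0)
        with pytest.raises(ValueError):
            CycleProtocol(anneal_celsius=120)


class TestTrajectories:
    def test_copy_counts_never_decrease(self, demo, template_strand):
        report = run_pcr(
            [template_strand],
            [demo["PD-PCR-1"], demo["PD-PCR-2"]],
            CycleProtocol(cycles=12, anneal_celsius=55.0),
            allow_parallel=True,
        )
        for counts in report.trajectory.values():
            assert all(b >= a for a, b in zip(counts, counts[1:]))
        totals = [
            sum(report.trajectory[lbl][c] for lbl in report.trajectory)
            for c in range(13)
        ]
        assert all(b >= a for a, b in zip(totals, totals[1:]))

    def test_amplicon_count_doubles_once_both_primers_active(
        self, demo, template_strand
    ):
        report = run_pcr(
            [template_strand], [demo["PCR-1"], demo["PCR-2"]], PROTO
        )
        counts = report.amplicon_strand_counts()
        # conventional: template itself is an amplicon strand, doubling from cycle 1
        assert counts[0] == 100
        for a, b in zip(counts, counts[1:]):
            assert b == 2 * a

    def test_one_cycle_lag_between_schemes(self, demo, template_strand):
        conv = run_pcr([template_strand], [demo["PCR-1"], demo["PCR-2"]], PROTO)
        pd = run_pcr(
            [template_strand],
            [demo["PD-PCR-1"], demo["PD-PCR-2"]],
            PROTO,
            allow_parallel=True,
        )
        for fold in (2, 16, 1024, 2**20):
            assert threshold_cycle(pd, fold) == threshold_cycle(conv, fold) + 1

    def test_threshold_fold_one_crossed_at_cycle_zero(self, demo, template_strand):
        conv = run_pcr([template_strand], [demo["PCR-1"], demo["PCR-2"]], PROTO)
        assert threshold_cycle(conv, 1) == 0

    def test_single_primer_never_crosses_exponential_threshold(
        self, demo, template_strand
    ):
        report = run_pcr(
            [template_strand], [demo["PD-PCR-1"]], PROTO, allow_parallel=True
        )
        assert threshold_cycle(report, 1024) is None
        assert report.threshold_cycle is None

    def test_determinism(self, demo, template_strand):
        primers = [demo["PD-PCR-1"], demo["PD-PCR-2"]]
        r1 = run_pcr([template_strand], primers, PROTO, allow_parallel=True)
        r2 = run_pcr([template_strand], primers, PROTO, allow_parallel=True)
        assert r1 == r2

    def test_bernoulli_efficiency_reproducible_and_bounded(
        self, demo, template_strand
    ):
        primers = [demo["PCR-1"], demo["PCR-2"]]
        kwargs = dict(protocol=CycleProtocol(cycles=10, anneal_celsius=55.0))
        ideal = run_pcr([template_strand], primers, **kwargs)
        s1 = run_pcr([template_strand], primers, efficiency=0.7, seed=7, **kwargs)
        s2 = run_pcr([template_strand], primers, efficiency=0.7, seed=7, **kwargs)
        assert s1 == s2
        assert s1.amplicon_strand_counts()[-1] <= ideal.amplicon_strand_counts()[-1]
        # counts still never decrease
        for counts in s1.trajectory.values():
            assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestSchemeRelation:
    def test_pdpcr_product_equals_conventional_product_of_reversed_template(self):
        """The algebraic heart of the opposite-polarity claim, on random
        templates with auto-designed primers."""
        templates = generate_template(
            FixtureSpec(template_length=90, gc_fraction=0.5, seed=11, count=8)
        )
        for T in templates:
            pd_pair = design_pdpcr_pair(T, 20, 20)
            conv_pair = design_conventional_pair(reverse(T), fwd_len=20, rev_len=20)
            proto = CycleProtocol(cycles=8, anneal_celsius=0.5)
            pd = run_pcr(
                [Strand(T)], [pd_pair.primer1, pd_pair.primer2], proto,
                allow_parallel=True,
            )
            conv = run_pcr(
                [Strand(reverse(T))], [conv_pair.primer1, conv_pair.primer2], proto
            )
            assert len(pd.amplicons) == len(conv.amplicons) == 1
            pd_strands = {
                str(pd.amplicons[0].top_strand), str(pd.amplicons[0].bottom_strand)
            }
            conv_strands = {
                str(conv.amplicons[0].top_strand), str(conv.amplicons[0].bottom_strand)
            }
            assert pd_strands == conv_strands


class TestQPCR:
    def test_relative_quantity_for_reported_threshold_cycles(self):
        # a 14.03-cycle lag corresponds to ~6e-5 of the reference quantity
        assert relative_quantity(23.29, 9.26) == pytest.approx(5.978e-5, rel=1e-3)

    def test_equal_cts_give_unity(self):
        assert relative_quantity(20.0, 20.0) == 1.0

    def test_target_ahead_of_reference_exceeds_unity(self):
        assert relative_quantity(8.0, 10.0) == 4.0

    def test_result_validation(self):
        with pytest.raises(ValueError):
            QPCRResult(ct_target=1.0, ct_reference=2.0, relative_quantity=0.0)
        r = QPCRResult(1.0, 2.0, relative_quantity(1.0, 2.0))
        assert r.relative_quantity == 2.0
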