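"""Generator correctness: determinism, closed-form mixtures, reconstruction."""

import numpy as np
import pytest

from castscan import (
    TargetSite,
    emit_amplicon_reads,
    emit_long_reads,
    emit_uditas_reads,
    make_donor,
    make_reference,
    simulate_events,
)
from castscan.errors import InvalidArgumentError
from castscan.simulate import integrated_allele, oriented_sequence


def test_make_reference_is_deterministic_and_acgt():
    a = make_reference(10, 0.5, seed=1)
    b = make_reference(10, 0.5, seed=1)
    assert a.sequence == b.sequence
    assert len(a) == 10
    assert set(a.sequence) <= set("ACGT")


def test_make_reference_rejects_empty():
    with pytest.raises(InvalidArgumentError):
        make_reference(0, 0.5, seed=1)


def test_make_reference_gc_content():
    ref = make_reference(100_000, 0.41, seed=7)
    gc = sum(b in "GC" for b in ref.sequence) / len(ref)
    assert abs(gc - 0.41) <= 0.02


def test_simulate_events_degenerate_orientation(amplicon):
    ref, site, _ = amplicon
    events = simulate_events(ref, site, n=1000, p_trl=1.0, seed=1)
    assert all(ev.orientation == "T-RL" for ev in events)


def test_simulate_events_zero_spread_pins_offset(amplicon):
    ref, site, _ = amplicon
    events = simulate_events(ref, site, n=1000, offset_mode=49,
                             offset_spread=0, seed=1)
    assert all(ev.offset_bp == 49 for ev in events if ev.is_on_target)


def test_simulate_events_site_outside_reference():
    ref = make_reference(100, 0.5, seed=1)
    site = TargetSite(ref_name=ref.name, start=80, end=112)
    with pytest.raises(InvalidArgumentError):
        simulate_events(ref, site, n=10, seed=1)


@pytest.mark.parametrize("rate,expect", [
    (0.02, 1 - 0.98**5),
    (0.004, 1 - 0.996**5),
])
def test_tsd_substitution_incidence_matches_binomial(amplicon, rate, expect):
    """Fraction of events with >=1 TSD substitution follows the per-base
    closed form 1-(1-rate)^tsd_len within 4 sigma at n=10^4."""
    ref, site, _ = amplicon
    n = 10_000
    events = simulate_events(ref, site, n=n, tsd_sub_rate=rate, tsd_len=5,
                             seed=3)
    hit = sum(bool(ev.tsd_subs) for ev in events)
    sigma = np.sqrt(n * expect * (1 - expect))
    assert abs(hit - n * expect) <= 4 * sigma


def test_orientation_and_offtarget_mixtures_match_binomial(lysate):
    ref, site, _ = lysate
    n = 10_000
    p_trl, p_off = 0.95, 0.1
    events = simulate_events(ref, site, n=n, p_trl=p_trl,
                             offtarget_rate=p_off, seed=4)
    n_trl = sum(ev.orientation == "T-RL" for ev in events)
    n_off = sum(not ev.is_on_target for ev in events)
    assert abs(n_trl - n * p_trl) <= 4 * np.sqrt(n * p_trl * (1 - p_trl))
    assert abs(n_off - n * p_off) <= 4 * np.sqrt(n * p_off * (1 - p_off))


def test_offtarget_positions_keep_clear_of_target(lysate):
    ref, site, _ = lysate
    events = simulate_events(ref, site, n=2000, offtarget_rate=0.5, seed=5)
    for ev in events:
        if not ev.is_on_target:
            # exclusion zone is around the on-target insertion point
            assert abs(ev.offset_bp - 49) > 1000


def test_event_tsd_records_substituted_sequence(amplicon):
    ref, site, _ = amplicon
    events = simulate_events(ref, site, n=500, tsd_sub_rate=0.1, seed=6)
    oref = oriented_sequence(ref, site)
    for ev in events:
        ots = ev.tsd_start  # plus-strand site; oriented == plus here
        ref_tsd = oref[ots:ots + ev.tsd_len]
        assert len(ev.tsd_seq) == ev.tsd_len
        for p, base in ev.tsd_subs:
            assert ev.tsd_seq[p] == base != ref_tsd[p]
        untouched = [i for i in range(ev.tsd_len)
                     if i not in {p for p, _ in ev.tsd_subs}]
        assert all(ev.tsd_seq[i] == ref_tsd[i] for i in untouched)


class TestAmpliconReads:
    def test_pure_unintegrated_run_is_error_free_amplicon(self, amplicon):
        ref, site, donor = amplicon
        events = simulate_events(ref, site, n=10, seed=1)
        reads, manifest = emit_amplicon_reads(
            ref, site, donor, events, depth=5, unintegrated_fraction=1.0,
            indel_profile={"rate": 0.0}, error_rate=0.0, seed=1)
        oref = oriented_sequence(ref, site)
        assert len(reads) == 50
        for rid, seq, _ in reads:
            truth = manifest.reads[rid]
            assert truth["kind"] == "unintegrated"
            assert seq in oref

    def test_trl_read_suffix_is_right_end_prefix(self, amplicon):
        ref, site, donor = amplicon
        ev = simulate_events(ref, site, n=1, p_trl=1.0, offset_spread=0,
                             tsd_sub_rate=0.0, seed=2)[0]
        reads, _ = emit_amplicon_reads(ref, site, donor, [ev], depth=1,
                                       unintegrated_fraction=0.0,
                                       error_rate=0.0, seed=2)
        _, seq, _ = reads[0]
        # the transposon tail of an upstream T-RL read starts with the RE
        cassette = donor.right_end + donor.cargo
        tx_start = next(i for i in range(len(seq))
                        if cassette.startswith(seq[i:]))
        assert len(seq) - tx_start >= 30

    def test_read_count_accounting(self, amplicon):
        """depth=50 over 100 events at unintegrated_fraction=0.5 gives 5000
        integrated reads and about as many unintegrated."""
        ref, site, donor = amplicon
        events = simulate_events(ref, site, n=100, seed=3)
        reads, manifest = emit_amplicon_reads(
            ref, site, donor, events, depth=50, unintegrated_fraction=0.5,
            seed=3)
        kinds = [manifest.reads[rid]["kind"] for rid, _, _ in reads]
        assert kinds.count("integrated") == 5000
        assert kinds.count("unintegrated") == 5000

    def test_short_read_len_rejected(self, amplicon):
        ref, site, donor = amplicon
        events = simulate_events(ref, site, n=1, seed=1)
        with pytest.raises(InvalidArgumentError):
            emit_amplicon_reads(ref, site, donor, events, read_len=40, seed=1)

    def test_seed_determinism_and_manifest_conservation(self, amplicon):
        ref, site, donor = amplicon
        events = simulate_events(ref, site, n=20, seed=9)
        out1 = emit_amplicon_reads(ref, site, donor, events, depth=5,
                                   unintegrated_fraction=0.4, error_rate=0.01,
                                   indel_profile={"rate": 0.3}, seed=9)
        out2 = emit_amplicon_reads(ref, site, donor, events, depth=5,
                                   unintegrated_fraction=0.4, error_rate=0.01,
                                   indel_profile={"rate": 0.3}, seed=9)
        assert out1[0] == out2[0]
        assert out1[1].to_json() == out2[1].to_json()
        ids = [r[0] for r in out1[0]]
        out1[1].validate_against_reads(ids)  # raises on violation

    def test_reconstruction_oracle(self, amplicon):
        """At error_rate=0, splicing reference/donor per the manifest truth
        reproduces every read string exactly."""
        ref, site, donor = amplicon
        events = simulate_events(ref, site, n=15, seed=11)
        reads, manifest = emit_amplicon_reads(
            ref, site, donor, events, depth=3, unintegrated_fraction=0.4,
            indel_profile={"rate": 0.5}, error_rate=0.0,
            sides=("upstream", "downstream"), seed=11)
        oref = oriented_sequence(ref, site)
        read_len = manifest.parameters["read_len"]
        for rid, seq, _ in reads:
            truth = manifest.reads[rid]
            if truth["kind"] == "integrated":
                ev = manifest.event_by_id(truth["event"])
                allele, _, _ = integrated_allele(oref, ev, site, donor)
                start = truth["allele_start"]
                assert seq == allele[start:start + read_len]
            else:
                start = truth["start"]
                indel = truth["indel"]
                if indel is None:
                    expect = oref[start:start + read_len]
                elif indel["kind"] == "deletion":
                    col, ln = indel["column"], indel["length"]
                    expect = (oref[start:col]
                              + oref[col + ln:start + read_len + ln])
                else:
                    col, ln = indel["column"], indel["length"]
                    expect = (oref[start:col] + indel["inserted"]
                              + oref[col:start + read_len - ln])
                assert seq == expect


class TestUditasReads:
    def test_single_event_single_umi(self, lysate):
        ref, site, donor = lysate
        ev = simulate_events(ref, site, n=1, seed=1)
        reads, manifest = emit_uditas_reads(ref, site, donor, ev,
                                            umis_per_event=1, reads_per_umi=3,
                                            seed=1)
        assert len(reads) == 3
        umis = {manifest.reads[rid]["umi"] for rid, _, _ in reads}
        assert len(umis) == 1

    def test_two_events_two_flank_positions(self, lysate):
        ref, site, donor = lysate
        events = simulate_events(ref, site, n=2, offtarget_rate=0.999, seed=2)
        reads, manifest = emit_uditas_reads(ref, site, donor, events,
                                            umis_per_event=1, reads_per_umi=1,
                                            seed=2)
        flank_starts = {
            manifest.event_by_id(manifest.reads[rid]["event"]).tsd_start
            for rid, _, _ in reads}
        assert len(flank_starts) == 2

    def test_umi_collision_count_within_birthday_bound(self, lysate):
        """500 12-mers collide with expectation 500^2/(2*4^12) ~ 0.007; the
        realized distinct-UMI shortfall must stay tiny."""
        ref, site, donor = lysate
        events = simulate_events(ref, site, n=500, seed=3)
        _, manifest = emit_uditas_reads(ref, site, donor, events,
                                        umi_len=12, umis_per_event=1,
                                        reads_per_umi=1, seed=3)
        umis = [t["umi"] for t in manifest.reads.values()]
        collisions = len(umis) - len(set(umis))
        assert collisions <= 2

    def test_umi_len_floor(self, lysate):
        ref, site, donor = lysate
        ev = simulate_events(ref, site, n=1, seed=1)
        with pytest.raises(InvalidArgumentError):
            emit_uditas_reads(ref, site, donor, ev, umi_len=5, seed=1)

    def test_offtarget_events_get_one_umi(self, lysate):
        ref, site, donor = lysate
        events = simulate_events(ref, site, n=50, offtarget_rate=0.5, seed=4)
        _, manifest = emit_uditas_reads(ref, site, donor, events,
                                        umis_per_event=5, reads_per_umi=2,
                                        seed=4)
        per_event = {}
        for t in manifest.reads.values():
            per_event.setdefault(t["event"], set()).add(t["umi"])
        for ev in events:
            if not ev.is_on_target:
                assert len(per_event[ev.event_id]) == 1


class TestLongReads:
    def test_pure_simple_has_no_backbone(self, amplicon):
        ref, site, donor = amplicon
        events = simulate_events(ref, site, n=20, seed=5)
        reads, _ = emit_long_reads(ref, site, donor, events,
                                   simple_fraction=1.0, seed=5)
        assert all(donor.backbone not in seq for _, seq in reads)

    def test_pure_cointegrate_contains_backbone(self, amplicon):
        ref, site, donor = amplicon
        events = simulate_events(ref, site, n=20, p_trl=1.0, seed=5)
        reads, _ = emit_long_reads(ref, site, donor, events,
                                   simple_fraction=0.0, seed=5)
        assert all(donor.backbone in seq for _, seq in reads)

    def test_simple_count_within_binomial(self, amplicon):
        ref, site, donor = amplicon
        n, p = 500, 0.9
        events = simulate_events(ref, site, n=n, seed=7)
        _, manifest = emit_long_reads(ref, site, donor, events,
                                      simple_fraction=p, seed=7)
        n_simple = sum(t["product_class"] == "simple"
                       for t in manifest.reads.values())
        assert abs(n_simple - n * p) <= 3 * np.sqrt(n * p * (1 - p))

    def test_cointegrate_needs_backbone(self, amplicon):
        ref, site, _ = amplicon
        linear = make_donor(backbone_len=0, seed=1)
        events = simulate_events(ref, site, n=5, seed=1)
        with pytest.raises(InvalidArgumentError):
            emit_long_reads(ref, site, linear, events, simple_fraction=0.5,
                            seed=1)
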