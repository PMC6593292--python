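"""Reaction classification and the SNP/deletion calling decision table."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mihatyper import (
    CallingConfig,
    Flag,
    Genotype,
    InputError,
    NoiseConfig,
    ReactionResult,
    ReactionStatus,
    call_deletion_locus,
    call_sample,
    call_snp_locus,
    check_internal_control,
    classify_reaction,
    concordance,
    render_plate,
)
from mihatyper.calls import GenotypeCall

POS = lambda cq: ReactionResult(ReactionStatus.POSITIVE, cq, 1500.0)
NEG = lambda cq=None: ReactionResult(ReactionStatus.NEGATIVE, cq, 1500.0)
INV = ReactionResult(ReactionStatus.INVALID, 22.0, 120.0)


class TestClassifyReaction:
    @pytest.mark.parametrize(
        "cq, rfu, status",
        [
            (22.0, 1500.0, ReactionStatus.POSITIVE),
            (29.99, 301.0, ReactionStatus.POSITIVE),
            (30.0, 1500.0, ReactionStatus.NEGATIVE),   # threshold is strict
            (31.0, 1500.0, ReactionStatus.NEGATIVE),
            (None, 1500.0, ReactionStatus.NEGATIVE),
            (22.0, 250.0, ReactionStatus.INVALID),     # RFU floor wins
            (None, 100.0, ReactionStatus.INVALID),
        ],
    )
    def test_decision_table(self, cfg, cq, rfu, status):
        assert classify_reaction(cq, rfu, cfg).status is status

    def test_cq_beyond_run_is_an_input_error(self, cfg):
        with pytest.raises(InputError):
            classify_reaction(41.0, 1500.0, cfg)


class TestInternalControl:
    @pytest.mark.parametrize(
        "cq_ref, cq_alt, ok",
        [
            (21.0, 21.9, True),
            (21.0, 22.4, True),
            (21.0, 22.5, False),   # exactly 1.5 apart counts as failure
            (21.0, 23.0, False),
        ],
    )
    def test_agreement_gate(self, cfg, cq_ref, cq_alt, ok):
        assert check_internal_control(POS(cq_ref), POS(cq_alt), cfg) is ok

    def test_missing_control_cq_fails(self, cfg):
        assert check_internal_control(POS(21.0), NEG(None), cfg) is False

    def test_low_rfu_control_fails(self, cfg):
        assert check_internal_control(POS(21.0), INV, cfg) is False

    def test_late_control_with_recorded_cq_can_still_pass(self, cfg):
        # the gate requires agreement, not positivity, of the controls
        assert check_internal_control(NEG(31.0), NEG(31.5), cfg) is True


class TestSnpCaller:
    @pytest.mark.parametrize(
        "ref_cq, alt_cq, expected",
        [
            (22.0, 23.1, Genotype.HET),       # delta 1.1 < 2
            (22.0, 24.0, Genotype.HOM_REF),   # delta exactly 2 -> homozygous
            (24.0, 22.0, Genotype.HOM_ALT),
            (22.0, 23.9, Genotype.HET),
        ],
    )
    def test_both_positive_delta_rule(self, ha1, cfg, ref_cq, alt_cq, expected):
        call = call_snp_locus(ha1, POS(ref_cq), POS(alt_cq), True, cfg)
        assert call.genotype is expected

    def test_single_positive_is_homozygous(self, ha1, cfg):
        assert call_snp_locus(ha1, NEG(), POS(25.0), True, cfg).genotype is Genotype.HOM_ALT
        assert call_snp_locus(ha1, POS(25.0), NEG(), True, cfg).genotype is Genotype.HOM_REF

    def test_both_negative_is_no_call_not_genotype(self, ha1, cfg):
        call = call_snp_locus(ha1, NEG(), NEG(), True, cfg)
        assert call.genotype is Genotype.NO_CALL
        assert call.reason

    def test_control_failure_overrides_everything(self, ha1, cfg):
        call = call_snp_locus(ha1, POS(22.0), POS(25.0), False, cfg)
        assert call.genotype is Genotype.NO_CALL
        assert Flag.CONTROL_FAIL in call.flags

    def test_invalid_reaction_yields_low_rfu_no_call(self, ha1, cfg):
        call = call_snp_locus(ha1, INV, POS(25.0), True, cfg)
        assert call.genotype is Genotype.NO_CALL
        assert Flag.LOW_RFU in call.flags

    @given(
        s_ref=st.sampled_from(list(ReactionStatus)),
        s_alt=st.sampled_from(list(ReactionStatus)),
        ok=st.booleans(),
        cq_ref=st.floats(15.0, 29.9),
        cq_alt=st.floats(15.0, 29.9),
    )
    @settings(max_examples=200, deadline=None)
    def test_exhaustive_and_symmetric(self, ha1, s_ref, s_alt, ok, cq_ref, cq_alt):
        """Every input combination returns a defined call, and swapping
        the REF/ALT reactions mirrors hom_ref <-> hom_alt."""
        def rx(status, cq):
            return ReactionResult(
                status, cq if status is not ReactionStatus.NEGATIVE else None,
                120.0 if status is ReactionStatus.INVALID else 1500.0,
            )

        a, b = rx(s_ref, cq_ref), rx(s_alt, cq_alt)
        fwd = call_snp_locus(ha1, a, b, ok)
        rev = call_snp_locus(ha1, b, a, ok)
        assert isinstance(fwd, GenotypeCall)
        mirror = {
            Genotype.HOM_REF: Genotype.HOM_ALT,
            Genotype.HOM_ALT: Genotype.HOM_REF,
        }
        assert rev.genotype is mirror.get(fwd.genotype, fwd.genotype)

    @given(
        cq_ref=st.one_of(st.none(), st.floats(15.0, 40.0)),
        cq_alt=st.one_of(st.none(), st.floats(15.0, 40.0)),
        rfu_ref=st.floats(0.0, 3000.0),
        rfu_alt=st.floats(0.0, 3000.0),
        tighter_rfu=st.floats(300.0, 800.0),
        tighter_cq=st.floats(20.0, 30.0),
    )
    @settings(max_examples=150, deadline=None)
    def test_tightening_thresholds_never_rescues_a_no_call(
        self, ha1, cq_ref, cq_alt, rfu_ref, rfu_alt, tighter_rfu, tighter_cq
    ):
        """Raising min_rfu or lowering positivity_cq can only void calls."""
        base = CallingConfig()
        tight = CallingConfig(min_rfu=tighter_rfu, positivity_cq=tighter_cq)

        def call_with(c):
            return call_snp_locus(
                ha1,
                classify_reaction(cq_ref, rfu_ref, c),
                classify_reaction(cq_alt, rfu_alt, c),
                True,
                c,
            )

        if call_with(base).genotype is Genotype.NO_CALL:
            assert call_with(tight).genotype is Genotype.NO_CALL


class TestDeletionCaller:
    def test_double_negative_is_homozygous_deletion(self, panel, cfg):
        call = call_deletion_locus(panel.deletion_locus, NEG(), NEG(), True, cfg)
        assert call.genotype is Genotype.ABSENT

    def test_double_positive_is_present(self, panel, cfg):
        call = call_deletion_locus(panel.deletion_locus, POS(24.1), POS(24.3), True, cfg)
        assert call.genotype is Genotype.PRESENT
        assert not call.flags

    def test_discordant_replicates_present_but_flagged(self, panel, cfg):
        call = call_deletion_locus(panel.deletion_locus, POS(24.1), NEG(), True, cfg)
        assert call.genotype is Genotype.PRESENT
        assert Flag.REPLICATE_DISCORDANT in call.flags

    def test_control_and_rfu_gates_apply(self, panel, cfg):
        assert (
            call_deletion_locus(panel.deletion_locus, POS(24.1), POS(24.3), False, cfg)
            .genotype is Genotype.NO_CALL
        )
        call = call_deletion_locus(panel.deletion_locus, INV, NEG(), True, cfg)
        assert Flag.LOW_RFU in call.flags

    def test_wrong_caller_for_locus_kind_rejected(self, panel, ha1, cfg):
        with pytest.raises(ValueError):
            call_deletion_locus(ha1, NEG(), NEG(), True, cfg)
        with pytest.raises(ValueError):
            call_snp_locus(panel.deletion_locus, NEG(), NEG(), True, cfg)


class TestCallSample:
    def test_control_failure_scoped_to_its_panel(self, panel, freqs, noise_free):
        from mihatyper import simulate_genotype_vector

        genos = {"S": simulate_genotype_vector(freqs, panel, 5)}
        records, _ = render_plate(genos, panel, noise_free, seed=5)
        # push panel 4's ALT-well control 2 cycles late
        tampered = [
            r if not (r.panel_index == 4 and r.channel == 5 and r.mix_group.value == "ALT")
            else type(r)(r.well_id, r.sample_id, r.panel_index, r.mix_group,
                         r.channel, r.target, r.cq + 2.0, r.end_rfu)
            for r in records
        ]
        calls = call_sample(tampered, panel)
        by_name = {c.locus.name: c for c in calls}
        for locus in panel.loci:
            if locus.panel_index == 4:
                assert by_name[locus.name].genotype is Genotype.NO_CALL
                assert Flag.CONTROL_FAIL in by_name[locus.name].flags
            else:
                assert by_name[locus.name].genotype is not Genotype.NO_CALL

    def test_all_low_rfu_voids_all_loci(self, panel, freqs, noise_free):
        from dataclasses import replace
        from mihatyper import simulate_genotype_vector

        genos = {"S": simulate_genotype_vector(freqs, panel, 6)}
        records, _ = render_plate(genos, panel, noise_free, seed=6)
        dim = [replace(r, end_rfu=150.0) for r in records]
        calls = call_sample(dim, panel)
        assert all(c.genotype is Genotype.NO_CALL for c in calls)

    def test_missing_well_pair_voids_only_that_panel(self, panel, freqs, noise_free):
        from mihatyper import simulate_genotype_vector

        genos = {"S": simulate_genotype_vector(freqs, panel, 7)}
        records, _ = render_plate(genos, panel, noise_free, seed=7)
        partial = [r for r in records if r.panel_index != 2]
        calls = call_sample(partial, panel)
        by_name = {c.locus.name: c for c in calls}
        for locus in panel.loci:
            voided = by_name[locus.name].genotype is Genotype.NO_CALL
            assert voided is (locus.panel_index == 2)


class TestConcordance:
    def test_identical_call_sets_fully_concordant(self, panel, freqs):
        from mihatyper import simulate_genotype_vector

        calls = []
        for seed in range(10):  # 10 samples x 20 loci = 200 points
            calls.extend(simulate_genotype_vector(freqs, panel, seed))
        summary = concordance(calls, list(calls))
        assert summary.n_compared == 200
        assert summary.n_discordant == 0

    def test_flipped_call_is_named(self, panel, freqs, ha1):
        from mihatyper import simulate_genotype_vector

        a = simulate_genotype_vector(freqs, panel, 1)
        b = list(a)
        idx = next(i for i, c in enumerate(b) if c.locus.name == ha1.name)
        flipped = Genotype.HOM_REF if b[idx].genotype is not Genotype.HOM_REF else Genotype.HOM_ALT
        b[idx] = GenotypeCall(ha1, flipped)
        summary = concordance(a, b)
        assert summary.n_discordant == 1
        assert ha1.name in summary.discordances[0][0]

    def test_no_call_points_excluded_from_comparison(self, panel, freqs):
        from mihatyper import simulate_genotype_vector

        a, b = [], []
        for seed in range(16):  # 16 subjects x 20 loci = 320 points
            vec = simulate_genotype_vector(freqs, panel, seed)
            a.extend(vec)
            b.extend(vec)
        for i in range(42):  # low-coverage exclusions on one side
            b[i * 7] = GenotypeCall(
                b[i * 7].locus, Genotype.NO_CALL, reason="coverage below 15 reads"
            )
        summary = concordance(a, b)
        assert summary.n_total == 320
        assert summary.n_excluded == 42
        assert summary.n_compared == 278

    def test_mismatched_locus_sets_rejected(self, panel, freqs):
        from mihatyper import simulate_genotype_vector

        a = simulate_genotype_vector(freqs, panel, 1)
        with pytest.raises(InputError):
            concordance(a, list(reversed(a)))
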