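import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import _oracles
from panelcnv.cnv_hmm import (
    CopyStatePath,
    TransitionModel,
    call_cnvs,
    filter_reportable,
    initial_distribution,
    posterior_decode,
    segment_calls,
    transition_matrix,
    viterbi,
)
from panelcnv.config import PipelineConfig
from panelcnv.depth_model import nb_log_pmf
from panelcnv.panel import Panel, TargetRegion, ReportingRule
from panelcnv.simulate import SimConfig, Spike, simulate_cohort

STATES = (0, 1, 2, 3)


def _emissions_from_depths(depths, mu=650.0, r=1e4, epsilon0=0.01):
    em = np.empty((len(depths), 4))
    for s_idx, c in enumerate(STATES):
        scale = epsilon0 if c == 0 else c / 2.0
        em[:, s_idx] = nb_log_pmf(np.asarray(depths), scale * mu, r)
    return em


class TestTransitionModel:
    def test_gap_zero_is_identity(self):
        np.testing.assert_array_equal(
            transition_matrix(0, TransitionModel()), np.eye(4)
        )

    def test_printed_rates(self):
        tm = TransitionModel()
        assert tm.p_cnv_to_wt_per_bp == 1 / 6200
        assert tm.p_cnv_prior == 0.001
        assert tm.p_wt_to_cnv_per_bp == pytest.approx(0.001 / 6200)

    def test_single_bp_entry_mass_equals_prior_times_exit(self):
        T = transition_matrix(1, TransitionModel())
        wt = STATES.index(2)
        cnv = [i for i in range(4) if i != wt]
        assert T[wt, cnv].sum() == pytest.approx(0.001 / 6200, rel=1e-12)

    @pytest.mark.parametrize("gap", [1, 100, 6200, 100_000])
    def test_closed_form_matches_repeated_multiplication(self, gap):
        tm = TransitionModel()
        closed = transition_matrix(gap, tm)
        brute = _oracles.repeated_multiplication(tm, gap)
        assert np.abs(closed - brute).max() < 1e-12

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(gap=st.integers(min_value=0, max_value=2_000_000))
    def test_rows_stochastic_for_all_gaps(self, gap):
        T = transition_matrix(gap, TransitionModel())
        assert np.all(T >= 0)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_gap_clamped_to_max(self):
        tm = TransitionModel(max_gap_bp=1000)
        np.testing.assert_array_equal(
            transition_matrix(10_000, tm), transition_matrix(1000, tm)
        )

    def test_initial_distribution_is_stationary_prior(self):
        pi = initial_distribution(TransitionModel())
        wt = STATES.index(2)
        cnv_mass = pi.sum() - pi[wt]
        assert cnv_mass == pytest.approx(0.001 / 1.001, rel=1e-12)
        assert pi[wt] > 0.999
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        # stationarity: pi T = pi
        np.testing.assert_allclose(
            pi @ transition_matrix(17, TransitionModel()), pi, atol=1e-15
        )


class TestDecoding:
    def test_flat_depth_decodes_all_diploid(self):
        em = _emissions_from_depths([648, 655, 650, 651, 649])
        path = viterbi(em, [2000] * 4, TransitionModel())
        assert list(path.states) == [2] * 5

    def test_half_depth_run_decodes_het_deletion(self):
        em = _emissions_from_depths([650, 325, 325, 325, 650])
        path = viterbi(em, [2000] * 4, TransitionModel())
        assert list(path.states) == [2, 1, 1, 1, 2]

    def test_empty_block(self):
        path = viterbi(np.zeros((0, 4)), [], TransitionModel())
        assert path.states.size == 0 and path.log_joint == 0.0

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(
        n=st.integers(min_value=1, max_value=6),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_viterbi_log_joint_equals_enumerated_maximum(self, n, seed):
        rng = np.random.default_rng(seed)
        em = rng.normal(-10, 3, size=(n, 4))
        gaps = rng.integers(1, 50_000, size=n - 1)
        tm = TransitionModel()
        path = viterbi(em, gaps, tm)
        best, _ = _oracles.enumerate_paths(em, gaps, tm)
        assert path.log_joint == pytest.approx(best, abs=1e-9)

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(
        n=st.integers(min_value=1, max_value=6),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_posteriors_match_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        em = rng.normal(-10, 3, size=(n, 4))
        gaps = rng.integers(1, 50_000, size=n - 1)
        tm = TransitionModel()
        post = posterior_decode(em, gaps, tm)
        _, brute = _oracles.enumerate_paths(em, gaps, tm)
        np.testing.assert_allclose(post, brute, atol=1e-9)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_strong_signal_posterior_confident(self):
        em = _emissions_from_depths([650, 325, 325, 325, 650])
        post = posterior_decode(em, [2000] * 4, TransitionModel())
        wt = STATES.index(2)
        assert 1.0 - post[2, wt] > 0.99


def _toy_targets(n, gene="BRCA1", chrom="chr17"):
    return [
        TargetRegion(chrom, 1000 * i, 1000 * i + 200, gene, f"exon {i + 1}")
        for i in range(n)
    ]


class TestSegmentation:
    def test_all_diploid_yields_no_calls(self):
        path = CopyStatePath(np.array([2, 2, 2]), 0.0)
        post = np.tile([0.0, 0.0, 1.0, 0.0], (3, 1))
        assert segment_calls(path, post, _toy_targets(3)) == []

    def test_runs_become_typed_calls(self):
        path = CopyStatePath(np.array([2, 1, 1, 2, 3, 2]), 0.0)
        post = np.tile([0.0, 0.0, 0.002, 0.0], (6, 1))
        post[:, 2] = 1 - post.sum(axis=1) + post[:, 2]
        post = post / post.sum(axis=1, keepdims=True)
        # give the called targets decisive non-diploid posteriors
        for t in (1, 2, 4):
            post[t] = [0.0, 0.997, 0.003, 0.0] if t != 4 else [0.0, 0.0, 0.003, 0.997]
        calls = segment_calls(path, post, _toy_targets(6))
        assert len(calls) == 2
        deletion, duplication = calls
        assert deletion.event_type == "deletion" and deletion.n_targets == 2
        assert deletion.first_region.exon_label == "exon 2"
        assert deletion.last_region.exon_label == "exon 3"
        assert duplication.event_type == "duplication"
        assert duplication.n_targets == 1

    def test_confidence_is_mean_of_non_diploid_posteriors(self):
        path = CopyStatePath(np.array([1, 1, 1]), 0.0)
        post = np.zeros((3, 4))
        p_del = [0.98, 0.96, 0.91]
        for t, p in enumerate(p_del):
            post[t] = [0.0, p, 1 - p, 0.0]
        (call,) = segment_calls(path, post, _toy_targets(3))
        assert call.confidence == pytest.approx(np.mean(p_del))
        assert call.min_posterior == pytest.approx(min(p_del))

    def test_status_thresholds(self):
        cfg = PipelineConfig(t_conf=0.99, t_retest=0.5)
        for p, status in ((0.999, "confident"), (0.7, "retest"), (0.3, "no_call")):
            path = CopyStatePath(np.array([1]), 0.0)
            post = np.array([[0.0, p, 1 - p, 0.0]])
            (call,) = segment_calls(path, post, _toy_targets(1), cfg)
            assert call.status == status


class TestReportingRules:
    def _call(self, gene, event, exon="exon 9"):
        t = TargetRegion("chr2", 0, 100, gene, exon)
        copy = 1 if event == "deletion" else 3
        from panelcnv.cnv_hmm import CnvCall

        return CnvCall(
            sample_id="s", gene=gene, first_region=t, last_region=t,
            event_type=event, copy_number=copy, n_targets=1,
            confidence=1.0, min_posterior=1.0, status="confident",
            exon_labels=[exon],
        )

    def _panel(self):
        return Panel(
            "p",
            [
                TargetRegion("chr2", 0, 100, "EPCAM", "exon 9"),
                TargetRegion("chr17", 0, 100, "BRCA1", "exon 12"),
            ],
            gene_roi_bp={"BRCA1": 100},
            reporting_rules={
                "EPCAM": ReportingRule(
                    events=frozenset({"deletion"}), must_overlap_exon="exon 9"
                )
            },
        )

    def test_epcam_duplication_dropped(self):
        calls = filter_reportable([self._call("EPCAM", "duplication")], self._panel())
        assert calls == []

    def test_epcam_exon9_deletion_kept(self):
        calls = filter_reportable([self._call("EPCAM", "deletion")], self._panel())
        assert len(calls) == 1

    def test_default_gene_reports_everything(self):
        calls = filter_reportable(
            [self._call("BRCA1", "duplication", "exon 12")], self._panel()
        )
        assert len(calls) == 1


class TestEndToEnd:
    def test_single_sample_batch_rejected(self, panel):
        dm, _ = simulate_cohort(panel, SimConfig(n_samples=2, seed=0))
        from panelcnv.depth_model import DepthMatrix

        one = DepthMatrix(dm.depths[:, :1], dm.target_ids, dm.sample_ids[:1])
        with pytest.raises(ValueError, match="at least 2 samples"):
            call_cnvs(one, panel)

    def test_null_batches_are_clean(self, panel):
        for seed in range(4):
            dm, _ = simulate_cohort(panel, SimConfig(n_samples=16, seed=seed))
            assert call_cnvs(dm, panel) == []

    def test_single_exon_duplication_recovered_with_exact_boundary(self, panel):
        spike = Spike(sample=4, gene="MSH2", first_target=7, n_targets=1, copy_number=3)
        dm, truth = simulate_cohort(
            panel, SimConfig(n_samples=16, spikes=[spike], seed=11)
        )
        calls = call_cnvs(dm, panel)
        assert len(calls) == 1
        call = calls[0]
        assert call.status == "confident"
        assert call.sample_id == "S04"
        assert (call.gene, call.event_type, call.copy_number) == ("MSH2", "duplication", 3)
        lo, hi = truth.spike_spans[0]
        ids = panel.target_ids()
        assert call.first_region.target_id == ids[lo]
        assert call.last_region.target_id == ids[hi]

    def test_brca1_exon12_duplication_carrier(self, panel):
        """A known replicate-control scenario: one sample duplicated for
        BRCA1 exon 12 yields exactly one confident BRCA1 duplication."""
        block = [r.exon_label for r in panel.regions_for_gene("BRCA1")]
        spike = Spike(
            sample=0, gene="BRCA1",
            first_target=block.index("exon 12"), n_targets=1, copy_number=3,
        )
        dm, _ = simulate_cohort(panel, SimConfig(n_samples=16, spikes=[spike], seed=2))
        calls = call_cnvs(dm, panel)
        assert len(calls) == 1
        assert calls[0].gene == "BRCA1"
        assert calls[0].event_type == "duplication"
        assert calls[0].first_region.exon_label == "exon 12"
        assert calls[0].status == "confident"

    def test_confidence_monotone_in_event_length(self):
        """For fixed per-target signal, longer events are never less
        confident (deterministic half-depth grid)."""
        tm = TransitionModel()
        confs = []
        for k in (1, 2, 3, 5, 8):
            depths = [650] * 3 + [325] * k + [650] * 3
            em = _emissions_from_depths(depths, r=100.0)  # noisy: not saturated
            gaps = [2000] * (len(depths) - 1)
            post = posterior_decode(em, gaps, tm)
            path = viterbi(em, gaps, tm)
            calls = segment_calls(
                path, post, _toy_targets(len(depths)), PipelineConfig()
            )
            assert len(calls) == 1
            confs.append(calls[0].confidence)
        assert all(b >= a - 1e-12 for a, b in zip(confs, confs[1:]))
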