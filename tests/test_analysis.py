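"""Unit and property tests for the enrichment / correlation / thresholds suite."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deskdock.analysis import (
    LabeledScores,
    PairedMeasurements,
    correlation,
    kendall_tau_b,
    load_labeled_scores,
    proc_auc,
    roc_auc,
    spearman_rho,
    thresholds_report,
)


def labeled(scores, labels, direction="lower_better"):
    ids = [f"x{i}" for i in range(len(scores))]
    return LabeledScores(ids, np.asarray(scores, float), list(labels), direction)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_proc_auc(scores, labels, direction="lower_better", clip=True):
    """Hand enumeration of the log-ROC statistic: walk the sorted list,
    decoys ahead on ties, mean of log10(1/beta) over actives."""
    sign = -1.0 if direction == "lower_better" else 1.0
    entries = sorted(
        zip(scores, labels), key=lambda t: (-sign * t[0], t[1] == "active")
    )
    n_dec = sum(1 for lab in labels if lab == "decoy")
    decoys_seen = 0
    logs = []
    for _, lab in entries:
        if lab == "decoy":
            decoys_seen += 1
        else:
            beta = decoys_seen / n_dec
            if clip:
                beta = max(beta, 1.0 / n_dec)
            logs.append(math.log10(1.0 / beta))
    return sum(logs) / len(logs)


def brute_roc_auc(scores, labels, direction="lower_better"):
    """Pair-counting oracle: fraction of (active, decoy) pairs the active
    wins, ties counting half."""
    sign = -1.0 if direction == "lower_better" else 1.0
    actives = [sign * s for s, lab in zip(scores, labels) if lab == "active"]
    decoys = [sign * s for s, lab in zip(scores, labels) if lab == "decoy"]
    wins = sum(
        1.0 if a > d else (0.5 if a == d else 0.0) for a in actives for d in decoys
    )
    return wins / (len(actives) * len(decoys))


def brute_tau_b(x, y):
    """Pure-Python O(n^2) pair classification for Kendall tau-b."""
    n = len(x)
    c = d = tx = ty = tboth = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = int(x[i] > x[j]) - int(x[i] < x[j])
            dy = int(y[i] > y[j]) - int(y[i] < y[j])
            if dx == 0 and dy == 0:
                tboth += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                c += 1
            else:
                d += 1
    denom = math.sqrt((c + d + ty) * (c + d + tx))
    return None if denom == 0 else (c - d) / denom


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


class TestEnrichment:
    def test_single_active_ranked_worst_gives_zero(self):
        data = labeled([-5.0, -4.0, -3.0, -1.0], ["decoy", "decoy", "decoy", "active"])
        res = proc_auc(data)
        assert res.proc_auc == 0.0  # beta = 1, log10(1) = 0
        assert res.n_clipped == 0

    def test_alternating_adad_hand_enumeration(self):
        # actives at -4, -2; decoys at -3, -1: betas (0 -> clipped 0.5, 0.5)
        data = labeled([-4.0, -3.0, -2.0, -1.0], ["active", "decoy", "active", "decoy"])
        res = proc_auc(data)
        assert res.proc_auc == pytest.approx(math.log10(2.0))
        assert res.n_clipped == 1
        assert res.roc_auc == pytest.approx(0.75)
        assert list(res.betas) == [0.5, 0.5]

    def test_perfect_separation_roc(self):
        data = labeled([-9, -8, -3, -2, -1], ["active", "active", "decoy", "decoy", "decoy"])
        assert roc_auc(data) == pytest.approx(1.0)
        # betas all clipped to 1/3 -> pROC = log10(3), the clipping ceiling
        assert proc_auc(data).proc_auc == pytest.approx(math.log10(3.0))

    def test_tied_active_decoy_ranks_decoy_first(self):
        data = labeled([-5.0, -5.0, -1.0], ["active", "decoy", "decoy"])
        res = proc_auc(data)
        assert list(res.betas) == [0.5]  # pessimistic: the tied decoy counts as better

    @pytest.mark.parametrize("n_labels", range(1, 15))
    def test_matches_hand_enumeration_on_all_four_ligand_labelings(self, n_labels):
        """Every active/decoy labeling of 4 distinct scores agrees with the
        walk-the-list oracle (both-class labelings only)."""
        labels = [
            "active" if (n_labels >> k) & 1 else "decoy" for k in range(4)
        ]
        if len(set(labels)) < 2:
            pytest.skip("single-class labeling")
        scores = [-4.0, -3.0, -2.0, -1.0]
        data = labeled(scores, labels)
        res = proc_auc(data)
        assert res.proc_auc == pytest.approx(brute_proc_auc(scores, labels))
        assert res.roc_auc == pytest.approx(brute_roc_auc(scores, labels))

    def test_single_class_raises_naming_missing_class(self):
        with pytest.raises(ValueError, match="decoy"):
            proc_auc(labeled([1.0, 2.0], ["active", "active"]))
        with pytest.raises(ValueError, match="active"):
            proc_auc(labeled([1.0, 2.0], ["decoy", "decoy"]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform_and_direction_flip(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = ["active"] * 6 + ["decoy"] * 24
        base = proc_auc(labeled(scores, labels))
        # strictly monotone transform preserves all ranks
        warped = proc_auc(labeled(np.exp(scores) + 3 * scores, labels))
        assert warped.proc_auc == pytest.approx(base.proc_auc)
        assert warped.roc_auc == pytest.approx(base.roc_auc)
        # negating scores and flipping the direction flag changes nothing
        flipped = proc_auc(labeled(-scores, labels, direction="higher_better"))
        assert flipped.proc_auc == pytest.approx(base.proc_auc)
        assert flipped.roc_auc == pytest.approx(base.roc_auc)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounds(self, seed):
        rng = np.random.default_rng(seed)
        n_dec = 20
        scores = rng.normal(size=25)
        labels = ["active"] * 5 + ["decoy"] * n_dec
        res = proc_auc(labeled(scores, labels))
        assert 0.0 <= res.proc_auc <= math.log10(n_dec)
        assert 0.0 <= res.roc_auc <= 1.0


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


def paired(x, y, **kw):
    kw.setdefault("docking_direction", "higher_better")
    kw.setdefault("experimental_direction", "higher_better")
    return PairedMeasurements(np.asarray(x, float), np.asarray(y, float), **kw)


class TestCorrelation:
    def test_perfectly_monotonic_identities(self):
        x = np.arange(1.0, 11.0)
        y = x**3
        assert spearman_rho(paired(x, y)).rho == 1.0
        assert kendall_tau_b(paired(x, y)).tau_b == 1.0
        assert spearman_rho(paired(x, y[::-1])).rho == -1.0
        assert kendall_tau_b(paired(x, y[::-1])).tau_b == -1.0

    def test_rank_difference_example(self):
        # d = (0, 1, -1, 0), sum d^2 = 2 -> rho = 1 - 12/60 = 0.8
        res = spearman_rho(paired([1, 2, 3, 4], [1, 3, 2, 4]))
        assert res.rho == pytest.approx(0.8)
        assert sorted(res.rank_differences) == [-1, 0, 0, 1]

    def test_tau_pair_counts_example(self):
        res = kendall_tau_b(paired([1, 2, 3, 4], [1, 3, 2, 4]))
        assert (res.concordant, res.discordant) == (5, 1)
        assert res.ties_dock_only == res.ties_exp_only == res.ties_both == 0
        assert res.tau_b == pytest.approx(4.0 / 6.0)

    def test_constant_vectors_flag_undefined(self):
        res = spearman_rho(paired([1, 2, 3], [5, 5, 5]))
        assert res.rho_undefined
        res = kendall_tau_b(paired([1, 2, 3], [5, 5, 5]))
        assert res.tau_b_undefined

    def test_pair_accounting_covers_all_pairs(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 4, size=20).astype(float)
        y = rng.integers(0, 4, size=20).astype(float)
        res = kendall_tau_b(paired(x, y))
        total = (
            res.concordant + res.discordant + res.ties_dock_only
            + res.ties_exp_only + res.ties_both
        )
        assert total == 20 * 19 // 2

    def test_direction_flip_invariance(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=15), rng.normal(size=15)
        base = correlation(paired(x, y))
        flip = correlation(
            paired(-x, y, docking_direction="lower_better",
                   experimental_direction="higher_better")
        )
        assert flip.rho == pytest.approx(base.rho)
        assert flip.tau_b == pytest.approx(base.tau_b)

    @given(st.integers(0, 2**31 - 1), st.integers(3, 50))
    @settings(max_examples=60, deadline=None)
    def test_tau_matches_brute_force_with_ties(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, max(2, n // 2), size=n).astype(float)
        y = rng.integers(0, max(2, n // 2), size=n).astype(float)
        res = kendall_tau_b(paired(x, y))
        expected = brute_tau_b(list(x), list(y))
        if expected is None:
            assert res.tau_b_undefined
        else:
            assert res.tau_b == pytest.approx(expected)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 50))
    @settings(max_examples=60, deadline=None)
    def test_rho_matches_closed_form_on_tie_free_data(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.permutation(n).astype(float)
        y = rng.permutation(n).astype(float)
        res = spearman_rho(paired(x, y))
        from scipy.stats import rankdata

        d = rankdata(x) - rankdata(y)
        closed = 1.0 - 6.0 * float(d @ d) / (n * (n**2 - 1))
        assert res.rho == pytest.approx(closed)

    def test_cross_check_against_scipy(self):
        from scipy.stats import kendalltau, spearmanr

        rng = np.random.default_rng(21)
        x = rng.integers(0, 6, size=40).astype(float)
        y = x + rng.integers(0, 6, size=40)
        res = correlation(paired(x, y))
        assert res.rho == pytest.approx(spearmanr(x, y).statistic)
        assert res.tau_b == pytest.approx(kendalltau(x, y).statistic)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------


class TestThresholds:
    def test_all_points_better_than_both_thresholds(self):
        data = paired([9, 8, 7], [9, 8, 7])
        rep = thresholds_report(data, 5.0, 5.0)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (3, 0, 0, 0)
        assert rep.fractions["tp"] == 1.0

    def test_symmetric_straddle_gives_one_per_quadrant(self):
        data = paired([1, 1, 9, 9], [1, 9, 1, 9])
        rep = thresholds_report(data, 5.0, 5.0)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (1, 1, 1, 1)

    def test_boundary_point_counts_as_active(self):
        # censored value reported exactly at the threshold -> active side
        data = paired([5.0, 4.0], [5.0, 4.0])
        rep = thresholds_report(data, 5.0, 5.0)
        assert rep.tp == 1 and rep.tn == 1

    def test_direction_aware(self):
        data = paired(
            [-9.0, -1.0], [0.1, 50.0],
            docking_direction="lower_better", experimental_direction="lower_better",
        )
        rep = thresholds_report(data, -5.0, 1.0)
        assert rep.tp == 1 and rep.tn == 1

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(3)
        data = paired(rng.normal(size=37), rng.normal(size=37))
        rep = thresholds_report(data, 0.2, -0.3)
        assert rep.tp + rep.fp + rep.tn + rep.fn == 37


# ---------------------------------------------------------------------------
# file-level driver
# ---------------------------------------------------------------------------


class TestRunAnalysis:
    def _write_screen(self, path, seed):
        from deskdock.simdata import SyntheticScreenSpec, generate_screen, write_screen_csv

        write_screen_csv(generate_screen(SyntheticScreenSpec(seed=seed, n_actives=8,
                                                             n_decoys=40, delta=2.0)), path)

    def test_enrichment_mode_two_inputs(self, tmp_path):
        from deskdock.config import parse_analysis_config

        for i in (0, 1):
            self._write_screen(tmp_path / f"s{i}.csv", seed=i)
        conf = parse_analysis_config(
            '{"mode": "enrichment", "inputs": ['
            '{"path": "s0.csv"}, {"path": "s1.csv"}],'
            f'"report_path": "report.csv"}}',
            base_dir=tmp_path,
        )
        report = __import__("deskdock").run_analysis(conf)
        assert len(report) == 2
        assert set(report["status"]) == {"ok"}
        assert {"proc_auc", "roc_auc"} <= set(report.columns)
        assert (tmp_path / "report.csv").exists()

    def test_failing_input_reported_not_fatal(self, tmp_path):
        from deskdock.config import parse_analysis_config

        self._write_screen(tmp_path / "good.csv", seed=0)
        (tmp_path / "empty.csv").write_text("ligand_id,score,label\n")
        conf = parse_analysis_config(
            '{"mode": "enrichment", "inputs": ['
            '{"path": "empty.csv"}, {"path": "good.csv"}]}',
            base_dir=tmp_path,
        )
        report = __import__("deskdock").run_analysis(conf)
        assert report.iloc[0]["status"].startswith("failed")
        assert report.iloc[1]["status"] == "ok"

    def test_report_rerun_is_byte_identical(self, tmp_path):
        from deskdock.config import parse_analysis_config

        self._write_screen(tmp_path / "s.csv", seed=4)
        conf = parse_analysis_config(
            '{"mode": "enrichment", "inputs": [{"path": "s.csv"}],'
            '"report_path": "rep.csv"}',
            base_dir=tmp_path,
        )
        __import__("deskdock").run_analysis(conf)
        first = (tmp_path / "rep.csv").read_bytes()
        __import__("deskdock").run_analysis(conf)
        assert (tmp_path / "rep.csv").read_bytes() == first

    def test_loader_requires_columns(self, tmp_path):
        (tmp_path / "bad.csv").write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="ligand_id"):
            load_labeled_scores(tmp_path / "bad.csv")
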