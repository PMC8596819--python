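"""Screening-score analysis: enrichment, rank correlation, and threshold modes.

Three analysis modes over one or more docking score tables:

* **enrichment** — how well a docking configuration ranks known actives above
  property-matched decoys, summarised by the logarithmic ROC area (pROC AUC)
  and the classical ROC AUC. The log-FPR axis weights early recovery of
  actives, which is what matters in prospective hit finding.
* **correlation** — rank agreement between docking scores and experimental
  binding data (Spearman's rho and Kendall's tau-b; tau-b accounts for the
  ties that limit-of-quantification censoring produces).
* **thresholds** — quadrant counts under hard active/inactive boundaries on
  both the docking and the experimental axis, for data too noisy to correlate.

All statistics are rank-based and direction-aware: a score table carries a
``lower_better`` / ``higher_better`` convention (docking engines differ) and
every comparison honours it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

LOWER = "lower_better"
HIGHER = "higher_better"
DIRECTIONS = (LOWER, HIGHER)

ACTIVE = "active"
DECOY = "decoy"


def _goodness(scores: np.ndarray, direction: str) -> np.ndarray:
    """Map scores onto a higher-is-better axis."""
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown score direction {direction!r}; expected one of {DIRECTIONS}")
    scores = np.asarray(scores, dtype=float)
    return -scores if direction == LOWER else scores


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class LabeledScores:
    """Scores for a screen of actives and decoys.

    ``labels`` holds ``"active"`` / ``"decoy"`` per entry; ``direction`` says
    whether lower or higher scores are better for this backend.
    """

    ligand_ids: list[str]
    scores: np.ndarray
    labels: list[str]
    direction: str = LOWER

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not (len(self.ligand_ids) == len(self.scores) == len(self.labels)):
            raise ValueError("ligand_ids, scores and labels must have equal length")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        bad = set(self.labels) - {ACTIVE, DECOY}
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}; expected 'active'/'decoy'")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("all scores must be finite")

    @property
    def n(self) -> int:
        return len(self.scores)

    @property
    def n_actives(self) -> int:
        return sum(1 for lab in self.labels if lab == ACTIVE)

    @property
    def n_decoys(self) -> int:
        return self.n - self.n_actives


@dataclass
class PairedMeasurements:
    """Docking scores paired with experimental values for the same ligands.

    ``loq_censored`` optionally flags experimental values reported at an assay
    limit of quantification; censoring produces ties, which is why tau-b is
    reported alongside Spearman.
    """

    docking: np.ndarray
    experimental: np.ndarray
    docking_direction: str = LOWER
    experimental_direction: str = LOWER
    loq_censored: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.docking = np.asarray(self.docking, dtype=float)
        self.experimental = np.asarray(self.experimental, dtype=float)
        if self.docking.shape != self.experimental.shape or self.docking.ndim != 1:
            raise ValueError("docking and experimental must be 1-D arrays of equal length")
        if len(self.docking) < 2:
            raise ValueError("need at least 2 paired measurements")
        for d in (self.docking_direction, self.experimental_direction):
            if d not in DIRECTIONS:
                raise ValueError(f"unknown direction {d!r}")
        if self.loq_censored is not None:
            self.loq_censored = np.asarray(self.loq_censored, dtype=bool)
            if self.loq_censored.shape != self.docking.shape:
                raise ValueError("loq_censored must match data length")

    @property
    def n(self) -> int:
        return len(self.docking)


@dataclass
class EnrichmentResult:
    proc_auc: float
    roc_auc: float
    betas: np.ndarray  # per-active FPR, after clipping, best-ranked active first
    n: int
    n_actives: int
    n_decoys: int
    n_clipped: int


@dataclass
class CorrelationResult:
    n: int
    rho: float = math.nan
    rho_undefined: bool = False
    tau_b: float = math.nan
    tau_b_undefined: bool = False
    rank_differences: np.ndarray | None = None
    concordant: int = 0
    discordant: int = 0
    ties_dock_only: int = 0
    ties_exp_only: int = 0
    ties_both: int = 0


@dataclass
class ThresholdReport:
    score_threshold: float
    experimental_threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    n: int
    fractions: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def _check_both_classes(data: LabeledScores) -> None:
    if data.n_actives == 0:
        raise ValueError("enrichment analysis requires at least one 'active' entry")
    if data.n_decoys == 0:
        raise ValueError("enrichment analysis requires at least one 'decoy' entry")


def proc_auc(data: LabeledScores) -> EnrichmentResult:
    """Logarithmic-ROC area under the curve.

    Entries are ordered best score first. For the i-th active recovered,
    ``beta_i`` is the fraction of decoys ranked strictly better; the statistic
    is the mean over actives of ``log10(1 / beta_i)``. Ties between an active
    and a decoy rank the decoy first (pessimistic, deterministic). An active
    recovered before any decoy would give ``beta = 0`` and a divergent log, so
    betas are clipped below at ``1 / n_decoys``; the clip count is reported.

    Random selection gives an expected value of ``log10(e) ≈ 0.434``; values
    above that demonstrate enrichment. Unlike the classical ROC AUC the
    statistic has no upper bound of 1 (its ceiling under this clipping is
    ``log10(n_decoys)``).
    """
    _check_both_classes(data)
    g = _goodness(data.scores, data.direction)
    is_active = np.array([lab == ACTIVE for lab in data.labels])
    # sort best-first; on score ties decoys (False) come before actives (True)
    order = np.lexsort((is_active, -g))
    active_sorted = is_active[order]
    decoys_before = np.cumsum(~active_sorted) - (~active_sorted)
    betas_raw = decoys_before[active_sorted] / data.n_decoys
    floor = 1.0 / data.n_decoys
    n_clipped = int(np.sum(betas_raw < floor))
    betas = np.maximum(betas_raw, floor)
    value = float(np.mean(np.log10(1.0 / betas)))
    return EnrichmentResult(
        proc_auc=value,
        roc_auc=roc_auc(data),
        betas=betas,
        n=data.n,
        n_actives=data.n_actives,
        n_decoys=data.n_decoys,
        n_clipped=n_clipped,
    )


def roc_auc(data: LabeledScores) -> float:
    """Classical ROC AUC via the Mann–Whitney rank formula; ties count half."""
    _check_both_classes(data)
    g = _goodness(data.scores, data.direction)
    ranks = rankdata(g)  # fractional ranks, ascending
    is_active = np.array([lab == ACTIVE for lab in data.labels])
    n_a, n_d = data.n_actives, data.n_decoys
    rank_sum = float(ranks[is_active].sum())
    return (rank_sum - n_a * (n_a + 1) / 2.0) / (n_a * n_d)


# ---------------------------------------------------------------------------
# rank correlation
# ---------------------------------------------------------------------------


def spearman_rho(data: PairedMeasurements) -> CorrelationResult:
    """Spearman rank correlation on the direction-aligned pair.

    Ranks are fractional (average) ranks so tied inputs are handled; on
    tie-free data the result equals the classical closed form
    ``1 - 6 * sum(d_i^2) / (n (n^2 - 1))`` where ``d_i`` is the rank
    difference of the i-th pair. A constant vector on either side leaves the
    coefficient undefined (flagged, not raised).
    """
    x = _goodness(data.docking, data.docking_direction)
    y = _goodness(data.experimental, data.experimental_direction)
    n = data.n
    rx, ry = rankdata(x), rankdata(y)
    d = rx - ry
    result = CorrelationResult(n=n, rank_differences=d)
    sx, sy = rx.std(), ry.std()
    if sx == 0.0 or sy == 0.0:
        result.rho_undefined = True
        return result
    has_ties = len(np.unique(rx)) < n or len(np.unique(ry)) < n
    if has_ties:
        # Pearson on fractional ranks; reduces to the closed form without ties
        rho = float(np.corrcoef(rx, ry)[0, 1])
    else:
        rho = 1.0 - 6.0 * float(d @ d) / (n * (n * n - 1))
    result.rho = float(np.clip(rho, -1.0, 1.0))
    return result


def kendall_tau_b(data: PairedMeasurements) -> CorrelationResult:
    """Kendall tau-b: all n(n-1)/2 pairs classified, with tie correction.

    ``tau_b = (C - D) / sqrt((C + D + T_exp_only) * (C + D + T_dock_only))``
    where C and D count concordant and discordant pairs and the T terms count
    pairs tied on exactly one variable; pairs tied on both are excluded from
    every term. An all-tied vector zeroes a denominator factor and the
    coefficient is flagged undefined.
    """
    x = _goodness(data.docking, data.docking_direction)
    y = _goodness(data.experimental, data.experimental_direction)
    n = data.n
    iu, ju = np.triu_indices(n, k=1)
    sx = np.sign(x[iu] - x[ju])
    sy = np.sign(y[iu] - y[ju])
    prod = sx * sy
    c = int(np.sum(prod > 0))
    d = int(np.sum(prod < 0))
    tie_x = sx == 0
    tie_y = sy == 0
    t_both = int(np.sum(tie_x & tie_y))
    t_dock = int(np.sum(tie_x & ~tie_y))
    t_exp = int(np.sum(~tie_x & tie_y))
    result = CorrelationResult(
        n=n,
        concordant=c,
        discordant=d,
        ties_dock_only=t_dock,
        ties_exp_only=t_exp,
        ties_both=t_both,
    )
    denom_sq = (c + d + t_exp) * (c + d + t_dock)
    if denom_sq == 0:
        result.tau_b_undefined = True
        return result
    result.tau_b = float(np.clip((c - d) / math.sqrt(denom_sq), -1.0, 1.0))
    return result


def correlation(data: PairedMeasurements) -> CorrelationResult:
    """Both rank coefficients merged into one record."""
    rho = spearman_rho(data)
    tau = kendall_tau_b(data)
    tau.rho = rho.rho
    tau.rho_undefined = rho.rho_undefined
    tau.rank_differences = rho.rank_differences
    return tau


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------


def thresholds_report(
    data: PairedMeasurements, score_threshold: float, experimental_threshold: float
) -> ThresholdReport:
    """Quadrant counts under hard docking/experimental boundaries.

    A point better than or exactly at a threshold counts as active on that
    axis (one consistent boundary rule, relevant for censored values reported
    exactly at an assay limit). TP means predicted active (docking) and
    measured active (experimental).
    """
    if not (math.isfinite(score_threshold) and math.isfinite(experimental_threshold)):
        raise ValueError("thresholds must be finite")
    gd = _goodness(data.docking, data.docking_direction)
    ge = _goodness(data.experimental, data.experimental_direction)
    td = _goodness(np.array([score_threshold]), data.docking_direction)[0]
    te = _goodness(np.array([experimental_threshold]), data.experimental_direction)[0]
    pred = gd >= td
    true = ge >= te
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    tn = int(np.sum(~pred & ~true))
    n = data.n
    return ThresholdReport(
        score_threshold=score_threshold,
        experimental_threshold=experimental_threshold,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        n=n,
        fractions={k: v / n for k, v in zip(("tp", "fp", "tn", "fn"), (tp, fp, tn, fn))},
    )


# ---------------------------------------------------------------------------
# file-level driver
# ---------------------------------------------------------------------------


def load_labeled_scores(path: str | Path, direction: str = LOWER) -> LabeledScores:
    """Read a labelled score CSV (columns: ligand_id, score, label)."""
    df = pd.read_csv(path)
    for col in ("ligand_id", "score", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return LabeledScores(
        ligand_ids=[str(x) for x in df["ligand_id"]],
        scores=df["score"].to_numpy(dtype=float),
        labels=[str(x) for x in df["label"]],
        direction=direction,
    )


def load_paired_measurements(
    path: str | Path,
    docking_direction: str = LOWER,
    experimental_direction: str = LOWER,
) -> PairedMeasurements:
    """Read a paired CSV (columns: ligand_id, score, exp_value[, loq])."""
    df = pd.read_csv(path)
    for col in ("score", "exp_value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    loq = df["loq"].to_numpy(dtype=bool) if "loq" in df.columns else None
    return PairedMeasurements(
        docking=df["score"].to_numpy(dtype=float),
        experimental=df["exp_value"].to_numpy(dtype=float),
        docking_direction=docking_direction,
        experimental_direction=experimental_direction,
        loq_censored=loq,
    )


def run_analysis(conf, tables: Sequence | None = None) -> pd.DataFrame:
    """Run one analysis mode over every input and write the comparison table.

    ``conf`` is an ``AnalysisConfiguration``; ``tables`` optionally supplies
    pre-loaded inputs (``LabeledScores`` or ``PairedMeasurements`` per entry)
    instead of reading each input's CSV path. One failing input (empty or
    malformed file) is reported in its row and does not abort the others.
    """
    from .config import AnalysisConfiguration  # local import to avoid a cycle

    if not isinstance(conf, AnalysisConfiguration):
        raise TypeError("conf must be an AnalysisConfiguration")
    if tables is not None and len(tables) != len(conf.inputs):
        raise ValueError("tables must align with conf.inputs")

    rows: list[dict] = []
    for idx, inp in enumerate(conf.inputs):
        name = inp.name or str(inp.path)
        row: dict = {"input": name, "status": "ok"}
        try:
            if conf.mode == "enrichment":
                data = (
                    tables[idx]
                    if tables is not None
                    else load_labeled_scores(inp.path, inp.direction)
                )
                res = proc_auc(data)
                row.update(
                    proc_auc=res.proc_auc,
                    roc_auc=res.roc_auc,
                    n=res.n,
                    n_actives=res.n_actives,
                    n_decoys=res.n_decoys,
                    n_clipped=res.n_clipped,
                )
            elif conf.mode == "correlation":
                data = (
                    tables[idx]
                    if tables is not None
                    else load_paired_measurements(
                        inp.path, inp.direction, conf.experimental_direction
                    )
                )
                res = correlation(data)
                row.update(
                    rho=None if res.rho_undefined else res.rho,
                    tau_b=None if res.tau_b_undefined else res.tau_b,
                    n=res.n,
                    concordant=res.concordant,
                    discordant=res.discordant,
                    ties_dock_only=res.ties_dock_only,
                    ties_exp_only=res.ties_exp_only,
                    ties_both=res.ties_both,
                )
            elif conf.mode == "thresholds":
                data = (
                    tables[idx]
                    if tables is not None
                    else load_paired_measurements(
                        inp.path, inp.direction, conf.experimental_direction
                    )
                )
                rep = thresholds_report(data, conf.score_threshold, conf.experimental_threshold)
                row.update(
                    tp=rep.tp, fp=rep.fp, tn=rep.tn, fn=rep.fn, n=rep.n, **{
                        f"frac_{k}": v for k, v in rep.fractions.items()
                    }
                )
            else:  # pragma: no cover - config validation rejects earlier
                raise ValueError(f"unknown analysis mode {conf.mode!r}")
        except Exception as exc:  # one bad input must not sink the batch
            row["status"] = f"failed: {exc}"
        rows.append(row)

    report = pd.DataFrame(rows)
    if conf.report_path is not None:
        Path(conf.report_path).parent.mkdir(parents=True, exist_ok=True)
        report.to_csv(conf.report_path, index=False)
    return report
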