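"""End-to-end pipeline: features -> stepwise selection -> LOOCV, plus the
parameter sweep and the electrode-importance analysis.

The default procedure selects features once on the full dataset and then
cross-validates the classifier on the selected columns.  Because the
selection sees every trial, that estimate carries selection bias when the
candidate pool is large relative to the number of trials; setting
``selection_within_folds=True`` re-runs the stepwise selection inside every
leave-one-out fold instead, giving a selection-bias-free (and typically
lower) accuracy estimate.  Both modes are deterministic for a fixed dataset
and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import confint_proportions_2indep, proportions_ztest

from .classify import (
    ConfusionMatrix,
    Metrics,
    compute_metrics,
    fit_discriminant,
    loocv,
)
from .features import FEATURE_TYPES, build_catalog, extract_features
from .modwt import get_filter, max_safe_level
from .selection import GroupedFeatureMatrix, SelectionResult, stepwise_select

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Knobs of one pipeline run (mirrors the method's parameter grid)."""

    wavelet: str = "d4"
    J: int | None = None  # None -> max_safe_level(N, L)
    ftypes: tuple[str, ...] = FEATURE_TYPES
    n_variables: int = 5
    kind: str = "linear"  # "linear" | "quadratic"
    shrinkage: float = 1e-4
    selection_within_folds: bool = False
    positive_label: str | None = None

    def __post_init__(self) -> None:
        if self.n_variables < 1:
            raise ValueError("n_variables must be >= 1")
        if not self.ftypes:
            raise ValueError("at least one feature type is required")


@dataclass
class PipelineResult:
    selection: SelectionResult
    confusion: ConfusionMatrix
    metrics: Metrics
    config: PipelineConfig
    positive_label: str


def build_feature_matrix(
    trials: Sequence[np.ndarray],
    labels: Sequence[str],
    channel_names: Sequence[str],
    wavelet: str = "d4",
    J: int | None = None,
    ftypes: tuple[str, ...] = FEATURE_TYPES,
) -> GroupedFeatureMatrix:
    """Extract the candidate features of every trial into one grouped matrix."""
    f = get_filter(wavelet)
    N = np.asarray(trials[0]).shape[1]
    if J is None:
        J = max_safe_level(N, f.L)
    catalog = build_catalog(list(channel_names), J, ftypes)
    X = np.empty((len(trials), len(catalog)))
    for i, trial in enumerate(trials):
        fv = extract_features(
            trial, channel_names, wavelet=f, J=J, ftypes=ftypes, trial_id=str(i)
        )
        X[i] = fv.values
    return GroupedFeatureMatrix(X=X, labels=np.asarray(labels), catalog=catalog)


def _loocv_with_selection(
    gfm: GroupedFeatureMatrix, cfg: PipelineConfig, positive: str
) -> ConfusionMatrix:
    """LOOCV where the stepwise selection is re-run inside every fold."""
    n = gfm.X.shape[0]
    tp = fn = fp = tn = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        fold = GroupedFeatureMatrix(
            X=gfm.X[mask], labels=gfm.labels[mask], catalog=gfm.catalog
        )
        sel = stepwise_select(fold, cfg.n_variables)
        cols = sel.selected_indices
        model = fit_discriminant(
            gfm.X[mask][:, cols],
            gfm.labels[mask],
            kind=cfg.kind,
            shrinkage=cfg.shrinkage,
        )
        pred = model.predict(gfm.X[i : i + 1, cols])[0]
        mask[i] = True
        actual_pos = gfm.labels[i] == positive
        pred_pos = pred == positive
        if actual_pos and pred_pos:
            tp += 1
        elif actual_pos:
            fn += 1
        elif pred_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def run_pipeline(
    trials: Sequence[np.ndarray],
    labels: Sequence[str],
    channel_names: Sequence[str],
    cfg: PipelineConfig,
    gfm: GroupedFeatureMatrix | None = None,
) -> PipelineResult:
    """Run extraction, selection and LOOCV evaluation for one configuration.

    ``gfm`` may be supplied to reuse an already-extracted feature matrix
    (it must match ``cfg.wavelet`` / ``cfg.J`` / ``cfg.ftypes``).
    """
    if gfm is None:
        gfm = build_feature_matrix(
            trials, labels, channel_names, cfg.wavelet, cfg.J, cfg.ftypes
        )
    positive = (
        cfg.positive_label
        if cfg.positive_label is not None
        else str(np.unique(gfm.labels)[0])
    )

    selection = stepwise_select(gfm, cfg.n_variables)
    logger.info(
        "selected %d features; V trajectory: %s",
        len(selection.selected),
        ", ".join(f"{v:.4g}" for v in selection.v_trajectory),
    )
    if cfg.selection_within_folds:
        cm = _loocv_with_selection(gfm, cfg, positive)
    else:
        cm = loocv(
            gfm.X[:, selection.selected_indices],
            gfm.labels,
            kind=cfg.kind,
            shrinkage=cfg.shrinkage,
            positive=positive,
        )
    return PipelineResult(
        selection=selection,
        confusion=cm,
        metrics=compute_metrics(cm),
        config=cfg,
        positive_label=positive,
    )


def parameter_sweep(
    trials: Sequence[np.ndarray],
    labels: Sequence[str],
    channel_names: Sequence[str],
    wavelets: Sequence[str],
    ftype_sets: Sequence[tuple[str, ...]],
    n_variables_grid: Sequence[int],
    kinds: Sequence[str],
    J: int | None = None,
    shrinkage: float = 1e-4,
    selection_within_folds: bool = False,
) -> pd.DataFrame:
    """Evaluate every parameter combination; one long-format row per run.

    Features are extracted once per wavelet (with both feature families) and
    reused across feature-type subsets and grid points.  A failing
    combination is recorded as a row with ``status = "failed"`` and the
    error message; the sweep continues.
    """
    if not (len(wavelets) and len(ftype_sets) and len(n_variables_grid) and len(kinds)):
        raise ValueError("all sweep grids must be nonempty")
    rows = []
    for wavelet in wavelets:
        try:
            full = build_feature_matrix(
                trials, labels, channel_names, wavelet, J, FEATURE_TYPES
            )
        except Exception as exc:  # noqa: BLE001 - sweep must keep going
            full = None
            wavelet_error = str(exc)
        for ftypes in ftype_sets:
            if full is not None:
                cols = [
                    i for i, fid in enumerate(full.catalog) if fid.ftype in ftypes
                ]
                sub = GroupedFeatureMatrix(
                    X=full.X[:, cols],
                    labels=full.labels,
                    catalog=[full.catalog[i] for i in cols],
                )
            for n_vars in n_variables_grid:
                for kind in kinds:
                    row = {
                        "wavelet": wavelet,
                        "ftypes": "+".join(ftypes),
                        "n_variables": n_vars,
                        "kind": kind,
                    }
                    if full is None:
                        row.update(status="failed", error=wavelet_error)
                        rows.append(row)
                        continue
                    cfg = PipelineConfig(
                        wavelet=wavelet,
                        J=J,
                        ftypes=tuple(ftypes),
                        n_variables=n_vars,
                        kind=kind,
                        shrinkage=shrinkage,
                        selection_within_folds=selection_within_folds,
                    )
                    try:
                        res = run_pipeline(
                            trials, labels, channel_names, cfg, gfm=sub
                        )
                    except Exception as exc:  # noqa: BLE001
                        row.update(status="failed", error=str(exc))
                    else:
                        m = res.metrics
                        row.update(
                            status="ok",
                            error="",
                            accuracy=m.accuracy,
                            sensitivity=m.sensitivity,
                            specificity=m.specificity,
                            precision=m.precision,
                            f_measure=m.f_measure,
                            tp=res.confusion.tp,
                            fn=res.confusion.fn,
                            fp=res.confusion.fp,
                            tn=res.confusion.tn,
                        )
                    rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ElectrodeReport:
    """Channel occurrences among the selected features.

    A variance feature contributes one occurrence to its channel; a
    correlation feature contributes one to each of its two channels, so the
    occurrence counts sum to (variances selected) + 2 * (correlations
    selected).
    """

    counts: dict[str, int]
    unique_channels: int
    total_slots: int
    pair_categories: dict[str, int] = field(default_factory=dict)
    unmapped: list[str] = field(default_factory=list)


def electrode_summary(
    sel: SelectionResult, group_map: Mapping[str, str] | None = None
) -> ElectrodeReport:
    """Summarize which channels the selected features involve.

    ``group_map`` optionally assigns channels to categories (e.g. motor vs
    non-motor cortex); correlation features are then tallied per unordered
    category pair ("motor-motor", "motor-non", ...).  Channels missing from
    the map are counted under "unmapped" and reported.
    """
    if not sel.selected:
        raise ValueError("selection is empty")
    counts: dict[str, int] = {}
    pair_categories: dict[str, int] = {}
    unmapped: set[str] = set()
    total_slots = 0
    for fid in sel.selected:
        for ch in fid.channels:
            counts[ch] = counts.get(ch, 0) + 1
            total_slots += 1
        if group_map is not None and fid.ftype == "correlation":
            cats = []
            for ch in fid.channels:
                if ch in group_map:
                    cats.append(str(group_map[ch]))
                else:
                    cats.append("unmapped")
                    unmapped.add(ch)
            key = "-".join(sorted(cats))
            pair_categories[key] = pair_categories.get(key, 0) + 1
    if unmapped:
        logger.warning("channels absent from group map: %s", sorted(unmapped))
    return ElectrodeReport(
        counts=counts,
        unique_channels=len(counts),
        total_slots=total_slots,
        pair_categories=pair_categories,
        unmapped=sorted(unmapped),
    )


def proportion_comparison(
    successes_a: int,
    n_a: int,
    successes_b: int,
    n_b: int,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float], float]:
    """Two-sample proportion comparison (normal approximation).

    Treats each classification as a Bernoulli trial.  The two-sided p-value
    uses the pooled-variance z statistic under the null of equal
    proportions; the confidence interval for the difference ``p_a - p_b`` is
    the Wald interval at level ``1 - alpha``.

    Returns ``(difference, (ci_low, ci_high), p_value)``.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("both sample sizes must be >= 1")
    for s, n in ((successes_a, n_a), (successes_b, n_b)):
        if not 0 <= s <= n:
            raise ValueError(f"successes {s} outside [0, {n}]")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")

    pa, pb = successes_a / n_a, successes_b / n_b
    diff = pa - pb
    pooled = (successes_a + successes_b) / (n_a + n_b)
    if pooled in (0.0, 1.0):
        p_value = 1.0  # all successes or all failures in both samples
    else:
        _, p_value = proportions_ztest(
            [successes_a, successes_b], [n_a, n_b], alternative="two-sided"
        )
    lo, hi = confint_proportions_2indep(
        successes_a, n_a, successes_b, n_b, method="wald", alpha=alpha
    )
    return diff, (float(lo), float(hi)), float(p_value)
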