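"""Two-regime statistical feature selection.

*Normalized* selection uses the paired neutral-baseline segments: phase 1
keeps a column only if, for each of the four non-neutral conditions, a
two-sided two-sample Student t-test finds it different between the
condition's emotional rows and their aligned baseline rows (p < 0.05 in
all four — the intersection rule); phase 2 then applies a one-way ANOVA
across the five conditions (p < 0.01) to the survivors.

*Non-normalized* selection skips phase 1 and runs only the ANOVA.

No multiple-testing correction is applied in either regime.  Despite the
name, "normalized" refers to baseline-aware *selection*, not to
arithmetic baseline subtraction; an optional subtract-baseline transform
exists behind a flag but is off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix

__all__ = [
    "SelectionResult",
    "phase1_baseline_ttest",
    "phase2_anova",
    "run_selection",
    "MODES",
]

MODES = ("normalized", "non_normalized")


@dataclass
class SelectionResult:
    """Retained columns per band with the p-values behind the decision."""

    mode: str
    family: str
    retained: dict[str, list[str]]  # band -> retained column names
    phase1_p: pd.DataFrame | None  # columns x condition, or None
    phase2_p: pd.Series  # per tested column
    alpha_phase1: float
    alpha_phase2: float
    dropped_undefined: list[str] = field(default_factory=list)

    @property
    def retained_columns(self) -> list[str]:
        return [c for band in self.retained for c in self.retained[band]]

    def counts(self) -> pd.DataFrame:
        """Per-band retained-feature counts, one row per selection phase
        (the layout of a retained-feature summary table)."""
        bands = list(self.retained)
        rows = {}
        if self.phase1_p is not None:
            surv = self._phase1_survivors()
            rows["t-test"] = [
                sum(1 for c in surv if c.split(".")[1] == b) for b in bands
            ]
        rows["ANOVA"] = [len(self.retained[b]) for b in bands]
        frame = pd.DataFrame(rows, index=bands).T
        frame["Total"] = frame.sum(axis=1)
        frame.index.name = f"{self.family}/{self.mode}"
        return frame

    def _phase1_survivors(self) -> list[str]:
        ok = (self.phase1_p < self.alpha_phase1).all(axis=1) & self.phase1_p.notna().all(axis=1)
        return list(self.phase1_p.index[ok])


def _split_by_band(columns: list[str]) -> dict[str, list[str]]:
    bands: dict[str, list[str]] = {}
    for c in columns:
        bands.setdefault(c.split(".")[1], []).append(c)
    return bands


def phase1_baseline_ttest(
    emotional: FeatureMatrix,
    baseline: FeatureMatrix,
    alpha: float = 0.05,
    paired: bool = False,
) -> tuple[pd.Series, pd.DataFrame]:
    """Baseline-contrast t-tests per column, intersected over conditions.

    For each non-neutral condition, that condition's emotional rows are
    compared against their aligned baseline rows with a classic
    pooled-variance two-sample two-sided t-test (``paired=True`` switches
    to a paired test; the rows are aligned trial pairs).  A column
    survives only if p < alpha for *all* non-neutral conditions; neutral
    rows are not tested.  Returns ``(mask, p_values)`` where ``p_values``
    is columns x condition; columns with undefined p (zero variance in
    both groups) are dropped.
    """
    if list(emotional.data.columns) != list(baseline.data.columns):
        raise ValueError("emotional and baseline matrices must share columns")
    if len(emotional.data) != len(baseline.data):
        raise ValueError("emotional and baseline matrices must be row aligned")
    conds = [c for c in pd.unique(emotional.labels["condition"]) if c != "neutral"]
    if not conds:
        raise ValueError("no non-neutral conditions to test")
    pvals = {}
    for cond in conds:
        rows = (emotional.labels["condition"] == cond).to_numpy()
        e = emotional.data.to_numpy()[rows]
        b = baseline.data.to_numpy()[rows]
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if paired:
                res = stats.ttest_rel(e, b, axis=0)
            else:
                res = stats.ttest_ind(e, b, axis=0, equal_var=True)
        pvals[cond] = res.pvalue
    p = pd.DataFrame(pvals, index=emotional.data.columns)
    mask = (p < alpha).all(axis=1) & p.notna().all(axis=1)
    return mask, p


def phase2_anova(
    features: FeatureMatrix,
    alpha: float = 0.01,
    condition_labels: pd.Series | None = None,
) -> tuple[pd.Series, pd.Series]:
    """One-way ANOVA across the condition groups, per column.

    Returns ``(mask, p_values)``; a column is retained iff p < alpha.
    Columns with undefined p (e.g., zero variance everywhere) are
    dropped.  No multiple-testing correction is applied.
    """
    labels = features.labels["condition"] if condition_labels is None else condition_labels
    groups = [
        features.data.to_numpy()[(labels == c).to_numpy()] for c in pd.unique(labels)
    ]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every condition needs at least 2 rows for the ANOVA")
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.f_oneway(*groups, axis=0)
    p = pd.Series(res.pvalue, index=features.data.columns)
    mask = (p < alpha) & p.notna()
    return mask, p


def run_selection(
    features: FeatureMatrix,
    baseline_features: FeatureMatrix | None = None,
    mode: str = "non_normalized",
    alpha_phase1: float = 0.05,
    alpha_phase2: float = 0.01,
    subtract_baseline: bool = False,
    paired: bool = False,
) -> tuple[SelectionResult, FeatureMatrix]:
    """Run a selection regime and return the reduced feature matrix.

    ``normalized`` chains the baseline t-test phase and the ANOVA phase
    (ANOVA on all rows, including neutral, restricted to phase-1
    survivors); ``non_normalized`` runs the ANOVA alone.  Retained
    columns are concatenated across bands in their original order.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode == "normalized" and baseline_features is None:
        raise ValueError("normalized selection requires the baseline feature matrix")

    work = features
    if subtract_baseline:
        if baseline_features is None:
            raise ValueError("subtract_baseline requires the baseline feature matrix")
        work = FeatureMatrix(
            data=features.data - baseline_features.data,
            labels=features.labels,
            family=features.family,
        )

    phase1_p = None
    dropped: list[str] = []
    if mode == "normalized":
        mask1, phase1_p = phase1_baseline_ttest(
            features, baseline_features, alpha=alpha_phase1, paired=paired
        )
        dropped += list(phase1_p.index[phase1_p.isna().any(axis=1)])
        survivors = list(features.data.columns[mask1.to_numpy()])
        if not survivors:
            raise ValueError(
                "phase 1 retained no features; review effect sizes or the alpha threshold"
            )
        work = work.subset(survivors)

    mask2, phase2_p = phase2_anova(work, alpha=alpha_phase2)
    dropped += list(phase2_p.index[phase2_p.isna()])
    final = list(work.data.columns[mask2.to_numpy()])
    if not final:
        raise ValueError(
            "selection retained no features; review effect sizes or the alpha thresholds"
        )

    retained = {band: [] for band in features.band_names}
    for c in final:
        retained[c.split(".")[1]].append(c)

    result = SelectionResult(
        mode=mode,
        family=features.family,
        retained=retained,
        phase1_p=phase1_p,
        phase2_p=phase2_p,
        alpha_phase1=alpha_phase1,
        alpha_phase2=alpha_phase2,
        dropped_undefined=sorted(set(dropped)),
    )
    ordered = [c for c in features.data.columns if c in set(final)]
    return result, work.subset(ordered)
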