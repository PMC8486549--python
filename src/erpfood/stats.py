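"""Grand averages and across-subject paired tests on single-trial features.

The inference unit is the subject: per-feature trial values are first
averaged within each subject × condition, then food and nonfood subject
means are compared with a paired Student t-test (df = n_subjects − 1).
No multiple-testing correction is applied by default — the battery
reports uncorrected per-feature tests — with Bonferroni and
Benjamini–Hochberg available as opt-in flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import FOOD, NONFOOD, EpochSet, FeatureTable
from .features import component_amplitude, wavelet_band_power, wavelet_coherence
from .montage import REPORT_BANDS

CONDITIONS = (FOOD, NONFOOD)


@dataclass
class SubjectConditionSummary:
    """Per-subject condition means of each feature.

    food / nonfood: (n_subjects, n_features) arrays of within-subject
    trial means, aligned on ``subjects`` and ``columns``.
    """

    subjects: list[str]
    columns: list
    food: np.ndarray
    nonfood: np.ndarray

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def summarize_by_subject(features: FeatureTable) -> SubjectConditionSummary:
    """Mean of every feature over each subject's trials of each condition."""
    subjects = sorted({str(s) for s in features.subject_ids})
    sid = features.subject_ids.astype(str)
    lab = features.labels.astype(str)
    per_cond = {}
    for cond in CONDITIONS:
        rows = []
        for s in subjects:
            pick = (sid == s) & (lab == cond)
            if not pick.any():
                raise ValueError(f"subject {s} has no {cond!r} trials")
            rows.append(features.values[pick].mean(axis=0))
        per_cond[cond] = np.vstack(rows)
    return SubjectConditionSummary(
        subjects, list(features.columns), per_cond[FOOD], per_cond[NONFOOD]
    )


@dataclass
class PairedTestResult:
    """Across-subject paired t-test on one feature."""

    feature: str
    mean_food: float
    std_food: float
    mean_nonfood: float
    std_nonfood: float
    t: float
    p: float
    df: int
    degenerate: bool = False


def _paired_t_arrays(food: np.ndarray, nonfood: np.ndarray) -> tuple[float, float, int, bool]:
    n = len(food)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 subjects")
    d = food - nonfood
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        # all subjects show the identical difference; t undefined (not ±inf)
        return (0.0 if d.mean() == 0 else np.nan), (1.0 if d.mean() == 0 else np.nan), df, True
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p), df, False


def paired_t(summary: SubjectConditionSummary, feature_index: int) -> PairedTestResult:
    """Two-sided paired t-test food vs nonfood for one feature column."""
    food = summary.food[:, feature_index]
    nonfood = summary.nonfood[:, feature_index]
    t, p, df, degenerate = _paired_t_arrays(food, nonfood)
    col = summary.columns[feature_index]
    return PairedTestResult(
        feature=col.label() if hasattr(col, "label") else str(col),
        mean_food=float(food.mean()),
        std_food=float(food.std(ddof=1)),
        mean_nonfood=float(nonfood.mean()),
        std_nonfood=float(nonfood.std(ddof=1)),
        t=t,
        p=p,
        df=df,
        degenerate=degenerate,
    )


def paired_tests(features: FeatureTable) -> pd.DataFrame:
    """Paired t-tests for every column of a feature table."""
    summary = summarize_by_subject(features)
    rows = [paired_t(summary, j) for j in range(len(summary.columns))]
    return pd.DataFrame([r.__dict__ for r in rows])


def run_stat_battery(
    epochs: EpochSet,
    components: tuple[str, ...] = ("P300", "LPP"),
    bands: tuple[str, ...] = REPORT_BANDS,
    *,
    include_power: bool = True,
    include_coherence: bool = True,
    correction: str | None = None,
) -> pd.DataFrame:
    """Paired tests for every amplitude, band-power and coherence feature.

    Per component: one test per channel amplitude, per (channel, band)
    power, and per (pair, band) coherence. ``correction`` ∈ {None,
    "bonferroni", "bh"} adds an adjusted-p column; the raw p column is
    always the uncorrected test.
    """
    frames = []
    for comp in components:
        tables = [component_amplitude(epochs, comp)]
        if include_power:
            tables += [wavelet_band_power(epochs, b, comp) for b in bands]
        if include_coherence:
            tables += [wavelet_coherence(epochs, b, comp) for b in bands]
        for table in tables:
            df = paired_tests(table)
            df.insert(0, "component", comp)
            df.insert(1, "family", table.columns[0].family)
            df.insert(2, "band", table.columns[0].band)
            frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if correction is not None:
        from statsmodels.stats.multitest import multipletests

        method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(correction)
        if method is None:
            raise ValueError(f"unknown correction {correction!r}; use 'bonferroni' or 'bh'")
        ok = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method=method)[1]
        out["p_adjusted"] = adj
    return out
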