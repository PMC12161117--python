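"""Group-level statistics: edgewise rank-sum tests with BH-FDR on PLI
connectivity, per-electrode t-tests on the 12 feature families,
feature-cognition Spearman correlations, and summary-statistic demographics
tests (Welch t from mean/SD/n, Pearson chi-square).

The connectivity comparison uses the two-sample Mann-Whitney rank-sum test
(the groups are independent with unequal n), with Benjamini-Hochberg
correction applied within each band across the 171 unique electrode pairs.
Feature t-tests are reported uncorrected at p < 0.05 by default, with an
optional BH-corrected mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import COGNITIVE_SCORES, MONTAGE_19, REGIONS, ConnectivityTensor
from .features import FEATURE_FAMILIES

__all__ = [
    "ranksum_test", "bh_fdr", "edgewise_comparison", "feature_ttests",
    "ttest_from_summary", "chi_square_2x2", "spearman_corr",
    "feature_cognition_correlation", "EdgeComparisonResult",
]


def ranksum_test(x, y):
    """Two-sided Mann-Whitney rank-sum test for independent samples.

    Exact enumeration for small untied samples, normal approximation with
    mid-rank tie correction otherwise (scipy's ``auto`` policy).
    Returns ``(U_statistic, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 values")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up adjusted p-values and rejection mask.

    Adjusted values carry the cumulative-minimum monotonicity enforcement;
    the mask equals the classic step-up rejection set at level ``q``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


@dataclass
class EdgeComparisonResult:
    """Edgewise group comparison of PLI for one or more bands."""

    channel_labels: tuple[str, ...]
    edges: np.ndarray                       # (n_edges, 2) channel indices
    p_raw: dict[str, np.ndarray] = field(default_factory=dict)
    p_fdr: dict[str, np.ndarray] = field(default_factory=dict)
    direction: dict[str, np.ndarray] = field(default_factory=dict)  # +1 BD>HC
    mask: dict[str, np.ndarray] = field(default_factory=dict)
    q: float = 0.05

    def significant_edges(self, band: str) -> list[tuple[str, str]]:
        labels = self.channel_labels
        return [(labels[a], labels[b])
                for (a, b), keep in zip(self.edges, self.mask[band]) if keep]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for band in self.p_raw:
            for k, (a, b) in enumerate(self.edges):
                rows.append({
                    "band": band,
                    "ch_a": self.channel_labels[a],
                    "ch_b": self.channel_labels[b],
                    "p": self.p_raw[band][k],
                    "p_fdr": self.p_fdr[band][k],
                    "direction": "BD>HC" if self.direction[band][k] > 0 else "BD<HC",
                    "significant": bool(self.mask[band][k]),
                })
        return pd.DataFrame(rows)


def _stack_edges(tensors: Sequence[ConnectivityTensor], band: str, ia, ib) -> np.ndarray:
    return np.stack([t.pli[band][ia, ib] for t in tensors])   # (n_subj, n_edges)


def edgewise_comparison(
    bd: Sequence[ConnectivityTensor],
    hc: Sequence[ConnectivityTensor],
    q: float = 0.05,
    bands: Optional[Sequence[str]] = None,
) -> EdgeComparisonResult:
    """Rank-sum test on every unique electrode pair, BH-corrected per band.

    Direction is the sign of the BD-minus-HC median difference.
    """
    if len(bd) < 2 or len(hc) < 2:
        raise ValueError("need at least 2 subjects per group")
    labels = bd[0].channel_labels
    for t in list(bd) + list(hc):
        if t.channel_labels != labels:
            raise ValueError("mismatched montages across subjects")
    n_ch = len(labels)
    ia, ib = np.triu_indices(n_ch, k=1)
    if bands is None:
        bands = [b for b in bd[0].pli if all(b in t.pli for t in list(bd) + list(hc))]
    result = EdgeComparisonResult(channel_labels=labels,
                                  edges=np.column_stack([ia, ib]), q=q)
    for band in bands:
        x = _stack_edges(bd, band, ia, ib)
        y = _stack_edges(hc, band, ia, ib)
        res = sps.mannwhitneyu(x, y, alternative="two-sided", axis=0)
        p_adj, reject = bh_fdr(res.pvalue, q=q)
        result.p_raw[band] = np.asarray(res.pvalue, dtype=float)
        result.p_fdr[band] = p_adj
        result.mask[band] = reject
        result.direction[band] = np.sign(np.median(x, axis=0) - np.median(y, axis=0))
    return result


def ttest_from_summary(m1, sd1, n1, m2, sd2, n2, welch: bool = True):
    """Two-sample t-test from printed summary statistics (mean, SD, n).

    Welch's unequal-variance form by default (it reproduces published
    demographics tables computed by standard software); pooled-variance
    optional.  Returns ``(t, df, p)``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("negative SD")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("both groups degenerate (SD = 0)")
    res = sps.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=not welch)
    if welch:
        v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
    return float(res.statistic), float(df), float(res.pvalue)


def chi_square_2x2(a, b, c, d):
    """Pearson chi-square on a 2x2 count table, df = 1, no continuity
    correction.  Rows are groups, columns categories."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row/column margin")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def spearman_corr(x, y):
    """Spearman rank correlation (mid-ranks for ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def _split_groups(fm: pd.DataFrame):
    if "group" not in fm.columns:
        raise ValueError("feature matrix lacks a 'group' column")
    bd = fm[fm["group"] == "BD"]
    hc = fm[fm["group"] == "HC"]
    if len(bd) < 2 or len(hc) < 2:
        raise ValueError("need at least 2 subjects per group")
    return bd, hc


def feature_ttests(fm: pd.DataFrame, alpha: float = 0.05,
                   welch: bool = False, fdr: bool = False) -> pd.DataFrame:
    """Independent-samples t-test per (feature family, electrode).

    Pooled-variance by default with a Welch option; significance at
    ``alpha`` uncorrected unless ``fdr``.  Cells with zero variance in both
    groups are reported non-significant with a warning.  The returned table
    carries the electrode's lobe (F/P/O/T region grouping).
    """
    bd, hc = _split_groups(fm)
    region_of = {ch: reg for reg, chans in REGIONS.items() for ch in chans}
    rows = []
    degenerate = []
    for fam in FEATURE_FAMILIES:
        for ch in MONTAGE_19:
            col = f"{fam}__{ch}"
            if col not in fm.columns:
                continue
            x, y = bd[col].to_numpy(float), hc[col].to_numpy(float)
            if np.ptp(np.concatenate([x, y])) == 0:
                degenerate.append(col)
                t, p = np.nan, np.nan
            else:
                res = sps.ttest_ind(x, y, equal_var=not welch)
                t, p = float(res.statistic), float(res.pvalue)
            rows.append({"feature": fam, "electrode": ch,
                         "region": region_of[ch], "t": t, "p": p})
    if degenerate:
        warnings.warn(f"constant feature cells marked non-significant: {degenerate}")
    out = pd.DataFrame(rows)
    if fdr:
        p_adj, reject = bh_fdr(np.nan_to_num(out["p"].to_numpy(), nan=1.0), q=alpha)
        out["p_fdr"] = p_adj
        out["significant"] = reject & out["p"].notna().to_numpy()
    else:
        out["significant"] = (out["p"] < alpha).fillna(False)
    return out


def feature_cognition_correlation(fm: pd.DataFrame, alpha: float = 0.05,
                                  scores: Sequence[str] = COGNITIVE_SCORES) -> pd.DataFrame:
    """Spearman correlation of every (score, feature family, electrode) cell.

    Subjects with missing scores are dropped with a warning.  The output
    supports the paradigm ranking via per-paradigm significant-cell counts.
    """
    rows = []
    for score in scores:
        if score not in fm.columns:
            raise ValueError(f"score {score!r} absent from feature matrix")
        sub = fm[fm[score].notna()]
        if len(sub) < len(fm):
            warnings.warn(f"{len(fm) - len(sub)} subjects missing {score}; dropped")
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 subjects with {score}")
        s = sub[score].to_numpy(float)
        for fam in FEATURE_FAMILIES:
            for ch in MONTAGE_19:
                col = f"{fam}__{ch}"
                if col not in fm.columns:
                    continue
                rho, p = sps.spearmanr(sub[col].to_numpy(float), s)
                rows.append({"score": score, "feature": fam, "electrode": ch,
                             "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < alpha
    return out


def significant_cell_count(corr: pd.DataFrame) -> int:
    """Number of significant feature-cognition cells (paradigm-ranking input)."""
    return int(corr["significant"].sum())
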