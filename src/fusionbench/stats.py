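"""Paired evaluation of fusion configurations against a baseline.

Per-pair Dice scores are aggregated across cross-validation folds by
concatenation; each configuration is compared with the reference-modality
baseline through Dice residuals (config minus baseline on the same pair), a
two-sided paired Wilcoxon signed-rank test, Bonferroni correction over the
number of comparisons, and a nonparametric Bland-Altman analysis whose
limits of agreement are the 5th and 95th percentiles of the differences
(not mean +/- 1.96 sd).

Conventions (all deterministic):
* percentiles and quartiles are nearest-rank (1-based ceiling index);
* the median of an even-length sample is the mean of the two central order
  statistics;
* zero differences are dropped before the Wilcoxon test (classic
  convention), with a degenerate flag when nothing remains;
* the exact Wilcoxon null distribution is used for n <= 25 (integer dynamic
  programming over doubled midranks, valid under ties), and the normal
  approximation with tie correction above.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "dice_score",
    "nearest_rank_percentile",
    "median",
    "wilcoxon_signed_rank",
    "bonferroni",
    "bland_altman",
    "aggregate_folds",
    "build_report",
    "EvalTable",
    "StatReport",
    "WilcoxonResult",
    "BlandAltman",
]

EXACT_N_MAX = 25
STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


# ---------------------------------------------------------------------------
# elementary quantities


def dice_score(pred: np.ndarray, truth: np.ndarray) -> float:
    """Overlap 2|X∩Y| / (|X|+|Y|) of two binary masks; 1.0 if both empty."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("mask shapes disagree")
    for m in (pred, truth):
        if not np.isin(np.unique(m), [0, 1]).all():
            raise ValueError("masks must be strictly binary")
    a = int(pred.sum())
    b = int(truth.sum())
    if a + b == 0:
        return 1.0
    inter = int(np.logical_and(pred, truth).sum())
    return 2.0 * inter / (a + b)


def nearest_rank_percentile(values: Sequence[float], q: float) -> float:
    """Nearest-rank percentile: the value at 1-based index ceil(q/100 * n)
    of the sorted sample."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("empty sample")
    idx = max(1, math.ceil(q / 100.0 * n))
    return float(v[min(idx, n) - 1])


def median(values: Sequence[float]) -> float:
    """Sample median; even n averages the two central order statistics."""
    return float(np.median(np.asarray(values, dtype=float)))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


@dataclass(frozen=True)
class WilcoxonResult:
    p: float
    statistic: float          # W+ (sum of ranks of positive differences)
    n_used: int               # pairs remaining after dropping zeros
    n_dropped: int
    method: str               # "exact" | "normal" | "degenerate"

    @property
    def degenerate(self) -> bool:
        return self.method == "degenerate"


def _exact_two_sided_p(ranks2: np.ndarray, w2_obs: float) -> float:
    """Exact two-sided p over all 2^n sign assignments.

    ``ranks2`` are doubled midranks (integers); ``w2_obs`` the doubled
    observed W+.  The null distribution of W+ is symmetric about half the
    total rank sum even under ties, so the two-sided p is twice the smaller
    tail: 2 * P(W+ <= min(w, total - w)).
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w_lo = min(w2_obs, total - w2_obs)
    p = 2.0 * counts[: int(round(w_lo)) + 1].sum()
    return float(min(1.0, p))


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]
                         ) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test of ``x`` vs ``y``.

    Zero differences are dropped; with every difference zero the result is
    degenerate with p = 1.  Exact enumeration is used for n <= 25 (ties
    handled through midranks), the tie-corrected normal approximation above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D and equally long")
    d = x - y
    nz = d != 0
    n_dropped = int((~nz).sum())
    d = d[nz]
    n = d.size
    if n == 0:
        return WilcoxonResult(p=1.0, statistic=0.0, n_used=0,
                              n_dropped=n_dropped, method="degenerate")
    if n < 5:
        raise ValueError(
            f"need >= 5 nonzero differences for the test, got {n}")
    ranks = rankdata(np.abs(d))          # midranks under ties
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        ranks2 = np.round(ranks * 2).astype(int)
        p = _exact_two_sided_p(ranks2, 2 * w_plus)
        return WilcoxonResult(p=p, statistic=w_plus, n_used=n,
                              n_dropped=n_dropped, method="exact")
    mu = n * (n + 1) / 4.0
    _, t_counts = np.unique(ranks, return_counts=True)
    tie_term = float((t_counts ** 3 - t_counts).sum()) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mu) / math.sqrt(sigma2)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(p=p, statistic=w_plus, n_used=n,
                          n_dropped=n_dropped, method="normal")


def bonferroni(raw_p: float, m: int = 6) -> tuple[float, str]:
    """Family-wise correction: corrected = min(1, m * raw_p), with
    significance stars at corrected p < 0.05 (*), < 0.01 (**), < 0.001 (***).
    """
    if not (0.0 <= raw_p <= 1.0):
        raise ValueError("raw_p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    corrected = min(1.0, m * raw_p)
    stars = ""
    for thr, s in STAR_THRESHOLDS:
        if corrected < thr:
            stars = s
            break
    return corrected, stars


# ---------------------------------------------------------------------------
# Bland-Altman


@dataclass(frozen=True)
class BlandAltman:
    bias: float               # median difference
    loa_low: float            # 5th percentile of the differences
    loa_high: float           # 95th percentile
    means: tuple = ()
    diffs: tuple = ()

    def to_dict(self) -> dict:
        return {"bias": self.bias, "loa_low": self.loa_low,
                "loa_high": self.loa_high}


def bland_altman(config_scores: Sequence[float],
                 baseline_scores: Sequence[float],
                 warn_n: int = 20) -> BlandAltman:
    """Nonparametric agreement analysis of paired scores.

    Differences are config minus baseline; the bias is their median and the
    limits of agreement are the nearest-rank 5th and 95th percentiles.
    """
    import warnings

    x = np.asarray(config_scores, dtype=float)
    y = np.asarray(baseline_scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D and equally long")
    if x.size < warn_n:
        warnings.warn(
            f"only {x.size} pairs; percentile limits of agreement are "
            "unstable below 20", stacklevel=2)
    diffs = x - y
    means = (x + y) / 2.0
    return BlandAltman(
        bias=median(diffs),
        loa_low=nearest_rank_percentile(diffs, 5),
        loa_high=nearest_rank_percentile(diffs, 95),
        means=tuple(means), diffs=tuple(diffs))


# ---------------------------------------------------------------------------
# tables and reports


@dataclass
class EvalTable:
    """Per-(pair, config) Dice scores, long format."""

    frame: pd.DataFrame   # subject_id, session_id, config_name, dice

    COLUMNS = ("subject_id", "session_id", "config_name", "dice")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"eval table missing columns {sorted(missing)}")
        if self.frame.duplicated(
                ["subject_id", "session_id", "config_name"]).any():
            raise ValueError("duplicate (pair, config) rows")
        bad = ~self.frame["dice"].between(0.0, 1.0)
        if bad.any():
            raise ValueError("dice values outside [0, 1]")

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "EvalTable":
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    def configs(self) -> list[str]:
        return list(dict.fromkeys(self.frame["config_name"]))

    def scores(self, config_name: str) -> pd.Series:
        df = self.frame[self.frame["config_name"] == config_name]
        return df.set_index(["subject_id", "session_id"])["dice"]

    def with_residuals(self, baseline_name: str) -> pd.DataFrame:
        """Long table plus a residual column (config minus baseline on the
        same pair)."""
        base = self.scores(baseline_name)
        df = self.frame.copy()
        keys = list(zip(df["subject_id"], df["session_id"]))
        df["residual"] = df["dice"].to_numpy() - base.loc[keys].to_numpy()
        return df

    def write(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read(cls, path) -> "EvalTable":
        df = pd.read_csv(path, dtype={"subject_id": str, "session_id": str,
                                      "config_name": str})
        return cls(df)


def aggregate_folds(per_fold_tables: Sequence[EvalTable]) -> EvalTable:
    """Concatenate per-fold test tables into the cohort-level table.

    Folds must have disjoint test pairs; any duplicated (pair, config) is
    rejected.  Downstream medians and p-values are invariant to fold order.
    """
    if not per_fold_tables:
        raise ValueError("no fold tables")
    frame = pd.concat([t.frame for t in per_fold_tables], ignore_index=True)
    return EvalTable(frame)    # __post_init__ rejects duplicates


@dataclass
class StatReport:
    """Per-configuration summary vs the baseline."""

    baseline_name: str
    m: int
    rows: list[dict] = field(default_factory=list)
    # each row: config_name, n, median_dice, iqr_low, iqr_high,
    # median_residual, raw_p, corrected_p, stars, direction, degenerate,
    # frac_dropped, ba_bias, ba_loa_low, ba_loa_high

    def row(self, config_name: str) -> dict:
        for r in self.rows:
            if r["config_name"] == config_name:
                return r
        raise KeyError(config_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def write(self, csv_path=None, json_path=None) -> None:
        if csv_path is not None:
            self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            payload = {"baseline": self.baseline_name, "m": self.m,
                       "configs": self.rows}
            with open(json_path, "w") as fh:
                json.dump(payload, fh, indent=1)

    def ranked(self) -> list[dict]:
        """Non-baseline rows, best median residual first."""
        rows = [r for r in self.rows if r["config_name"] != self.baseline_name]
        return sorted(rows, key=lambda r: -r["median_residual"])


def build_report(table: EvalTable, baseline_name: str = "baseline_ref",
                 m: int = 6) -> StatReport:
    """Full paired evaluation of every configuration in ``table``.

    Each non-baseline configuration is compared with ``baseline_name`` on
    exactly matching pairs (missing pairs are an error: the test is paired).
    """
    if baseline_name not in table.configs():
        raise ValueError(f"baseline {baseline_name!r} absent from table")
    base = table.scores(baseline_name)
    report = StatReport(baseline_name=baseline_name, m=m)
    for name in table.configs():
        sc = table.scores(name)
        if set(sc.index) != set(base.index):
            raise ValueError(
                f"config {name!r} and baseline cover different pairs; "
                "a paired test requires alignment")
        sc = sc.loc[base.index]
        resid = sc.to_numpy() - base.to_numpy()
        if name == baseline_name:
            wil = WilcoxonResult(p=1.0, statistic=0.0, n_used=0,
                                 n_dropped=len(resid), method="degenerate")
        else:
            wil = wilcoxon_signed_rank(sc.to_numpy(), base.to_numpy())
        corrected, stars = bonferroni(wil.p, m)
        ba = bland_altman(sc.to_numpy(), base.to_numpy()) \
            if name != baseline_name else BlandAltman(0.0, 0.0, 0.0)
        med_resid = median(resid)
        report.rows.append(dict(
            config_name=name,
            n=int(sc.size),
            median_dice=median(sc.to_numpy()),
            iqr_low=nearest_rank_percentile(sc.to_numpy(), 25),
            iqr_high=nearest_rank_percentile(sc.to_numpy(), 75),
            median_residual=med_resid,
            raw_p=wil.p,
            corrected_p=corrected,
            stars=stars,
            direction="up" if med_resid > 0 else "down",
            degenerate=wil.degenerate,
            frac_dropped=(wil.n_dropped / max(1, wil.n_dropped + wil.n_used)),
            ba_bias=ba.bias, ba_loa_low=ba.loa_low, ba_loa_high=ba.loa_high,
        ))
    return report
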