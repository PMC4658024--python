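"""Nonparametric comparison harness: Wilcoxon signed rank, Mann-Whitney U,
Cohen's kappa, a seeded Likert-reader simulator, and the four-arm report.

The rank tests switch between exact null enumeration on small samples and a
normal approximation with tie and continuity corrections otherwise; every
result records which branch ran.  Two-sided p-values are defined
symmetrically as ``P(|T - E[T]| >= |t_obs - E[T]|)`` under the exact null,
which reduces to the usual doubled tail for untied data.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .metric import CaseScore, percent_reduction

__all__ = [
    "TestResult",
    "KappaResult",
    "RatingsTable",
    "ArmComparison",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "cohen_kappa",
    "kappa_band",
    "simulate_readers",
    "compare_arms",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str          # "exact" or "normal_approx"


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    band: str


@dataclass
class RatingsTable:
    """Per-case ordinal scores (0..4) of two readers for one endpoint."""

    table: pd.DataFrame     # columns: case_id, stratum, endpoint, reader1, reader2

    def __post_init__(self) -> None:
        for col in ("reader1", "reader2"):
            vals = self.table[col].to_numpy()
            if not np.all((vals == vals.astype(int)) & (vals >= 0) & (vals <= 4)):
                raise ValueError(f"{col}: Likert scores must be integers in 0..4")

    def kappa(self) -> KappaResult:
        return cohen_kappa(self.table["reader1"].to_numpy(),
                           self.table["reader2"].to_numpy())


def _two_sided_from_null(null: np.ndarray, observed: float) -> float:
    center = float(null.mean())
    dev = abs(observed - center)
    return float(np.mean(np.abs(null - center) >= dev - 1e-12))


def wilcoxon_signed_rank(x, y, method: str = "auto") -> TestResult:
    """Paired Wilcoxon signed-rank test, two-sided.

    Zero differences are dropped, ties mid-ranked.  Exact enumeration of
    all 2^n sign assignments for n <= 12 effective pairs; otherwise a
    normal approximation with tie and continuity corrections.  Statistic is
    W = min(W+, W-).  ``method`` forces a branch ("exact"/"approx") for
    cross-validation.
    """
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 1:
        raise ValueError("samples must be non-empty and equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        log.warning("all differences zero: degenerate Wilcoxon, p = 1")
        return TestResult(statistic=0.0, p_value=1.0, method="degenerate")
    r = rankdata(np.abs(d))
    w_plus = float(r[d > 0].sum())
    total = float(r.sum())
    w = min(w_plus, total - w_plus)
    if method == "exact" or (method == "auto" and n <= 12):
        signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
        null = signs @ r
        p = _two_sided_from_null(null, w_plus)
        return TestResult(statistic=w, p_value=p, method="exact")
    mean = total / 2.0
    _, counts = np.unique(r, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(((counts ** 3 - counts) / 48.0).sum())
    dev = max(abs(w_plus - mean) - 0.5, 0.0)    # continuity correction
    z = dev / math.sqrt(var)
    return TestResult(statistic=w, p_value=float(2.0 * norm.sf(z)), method="normal_approx")


_MAX_ENUM = 200_000


def mann_whitney_u(x, y, method: str = "auto") -> TestResult:
    """Two-sample Mann-Whitney U test, two-sided.

    Exact enumeration of group labelings when ``min(n, m) <= 8`` and the
    number of labelings is tractable; otherwise a tie-corrected normal
    approximation with continuity correction.  Statistic is U of ``x``.
    """
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = float(ranks[:n].sum())
    u1 = r1 - n * (n + 1) / 2.0
    if method == "exact" or (method == "auto"
                             and min(n, m) <= 8 and math.comb(n + m, n) <= _MAX_ENUM):
        null = np.array([sum(ranks[list(c)]) for c in
                         itertools.combinations(range(n + m), n)])
        null_u = null - n * (n + 1) / 2.0
        p = _two_sided_from_null(null_u, u1)
        return TestResult(statistic=u1, p_value=p, method="exact")
    mean = n * m / 2.0
    big_n = n + m
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts ** 3 - counts)).sum()) / (big_n * (big_n - 1))
    var = n * m / 12.0 * (big_n + 1 - tie_term)
    if var <= 0:
        return TestResult(statistic=u1, p_value=1.0, method="normal_approx")
    dev = max(abs(u1 - mean) - 0.5, 0.0)
    z = dev / math.sqrt(var)
    return TestResult(statistic=u1, p_value=float(2.0 * norm.sf(z)), method="normal_approx")


_KAPPA_BANDS = (
    (0.20, "slight"), (0.40, "fair"), (0.60, "moderate"),
    (0.80, "substantial"), (1.00, "almost perfect"),
)


def kappa_band(kappa: float) -> str:
    """Conventional agreement label: 0-0.20 slight, 0.21-0.40 fair,
    0.41-0.60 moderate, 0.61-0.80 substantial, 0.81-1.00 almost perfect."""
    if kappa < 0:
        return "poor"
    for hi, name in _KAPPA_BANDS:
        if kappa <= hi + 1e-12:
            return name
    return "almost perfect"


def cohen_kappa(reader1, reader2, n_categories: int = 5) -> KappaResult:
    """Unweighted Cohen's kappa of two ordinal raters.

    Perfect agreement on a single constant category leaves kappa undefined
    (0/0); by convention 1.0 is returned with a warning.
    """
    r1 = np.asarray(reader1, int)
    r2 = np.asarray(reader2, int)
    if r1.size != r2.size or r1.size < 2:
        raise ValueError("need >= 2 paired ratings")
    contingency = np.zeros((n_categories, n_categories))
    for a, b in zip(r1, r2):
        contingency[a, b] += 1
    total = contingency.sum()
    p_o = float(np.trace(contingency)) / total
    marg1 = contingency.sum(axis=1) / total
    marg2 = contingency.sum(axis=0) / total
    p_e = float(marg1 @ marg2)
    if abs(1.0 - p_e) < 1e-12:
        log.warning("kappa undefined (single constant category, perfect agreement); returning 1")
        kappa = 1.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(kappa=float(kappa), band=kappa_band(float(kappa)))


def simulate_readers(case_scores: list[CaseScore], seed: int,
                     quantiles=(0.10, 0.35, 0.65, 0.90),
                     flip_prob: float = 0.2,
                     baseline_scores=None,
                     stratum: str = "", endpoint: str = "artefact") -> RatingsTable:
    """Synthetic Likert readers standing in for the human raters.

    Reader 1 bins each case's streak score into 0..4 at the given quantiles
    of the baseline (NOMAR) score distribution — a monotone calibration —
    and reader 2 repeats reader 1 with a seeded ±1 perturbation applied
    with probability ``flip_prob``.
    """
    scores = np.array([c.mean_score for c in case_scores], float)
    base = scores if baseline_scores is None else np.asarray(baseline_scores, float)
    edges = np.quantile(base, quantiles)
    reader1 = np.digitize(scores, edges)
    rng = np.random.default_rng(seed)
    flips = rng.random(scores.size) < flip_prob
    direction = rng.choice([-1, 1], size=scores.size)
    reader2 = np.clip(reader1 + flips * direction, 0, 4)
    table = pd.DataFrame({
        "case_id": [c.case_id for c in case_scores],
        "stratum": stratum,
        "endpoint": endpoint,
        "reader1": reader1.astype(int),
        "reader2": reader2.astype(int),
    })
    return RatingsTable(table=table)


@dataclass
class ArmComparison:
    """Per-stratum four-arm summary mirroring the study's result tables."""

    stratum: str
    scores: pd.DataFrame            # index case_id, columns = arms
    summary: pd.DataFrame           # per arm: mean, sd, pct_reduction, p_vs_nomar
    p_imar_vs_demar: float
    p_imar_vs_combo: float

    def to_markdown(self) -> str:
        lines = [f"### {self.stratum} (n = {len(self.scores)})", "",
                 self.summary.to_markdown(floatfmt=".4g"), "",
                 f"IMAR vs DEMAR: p = {self.p_imar_vs_demar:.4g}; "
                 f"IMAR vs IMAR+DEMAR: p = {self.p_imar_vs_combo:.4g}"]
        return "\n".join(lines)

    def bar_values(self) -> dict:
        """Fig-5-style per-arm mean streak amplitudes (values only)."""
        return self.summary["mean"].to_dict()


_ARM_ORDER = ("NOMAR", "DEMAR", "IMAR", "IMAR+DEMAR")


def compare_arms(case_scores: list[CaseScore], stratum: str = "") -> ArmComparison:
    """Paired four-arm comparison of one stratum's streak scores.

    Produces per-arm mean ± SD, percent reduction vs NOMAR, and Wilcoxon
    signed-rank p-values for the three paired contrasts of the study layout
    (each arm vs NOMAR; IMAR vs DEMAR; IMAR vs IMAR+DEMAR).
    """
    df = pd.DataFrame([(c.case_id, c.arm_label, c.mean_score) for c in case_scores],
                      columns=["case_id", "arm", "score"])
    wide = df.pivot(index="case_id", columns="arm", values="score")
    missing = [a for a in _ARM_ORDER if a not in wide.columns]
    if missing or wide.isna().any().any():
        bad = missing or wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete arms for comparison: {bad}")
    wide = wide[list(_ARM_ORDER)]
    nomar = wide["NOMAR"].to_numpy()
    rows = {}
    for arm in _ARM_ORDER:
        v = wide[arm].to_numpy()
        rows[arm] = {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "pct_reduction": 0.0 if arm == "NOMAR"
            else percent_reduction(float(v.mean()), float(nomar.mean())),
            "p_vs_nomar": np.nan if arm == "NOMAR"
            else wilcoxon_signed_rank(v, nomar).p_value,
        }
    summary = pd.DataFrame(rows).T
    return ArmComparison(
        stratum=stratum, scores=wide, summary=summary,
        p_imar_vs_demar=wilcoxon_signed_rank(
            wide["IMAR"].to_numpy(), wide["DEMAR"].to_numpy()).p_value,
        p_imar_vs_combo=wilcoxon_signed_rank(
            wide["IMAR"].to_numpy(), wide["IMAR+DEMAR"].to_numpy()).p_value,
    )
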