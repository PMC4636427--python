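"""Information-theoretic model comparison and small nonparametric tests.

This module does not fit models.  It consumes (label, log-likelihood, k,
n) triples — or AICc values directly — from any fitter and implements the
selection arithmetic around them:

    AICc   = -2 logL + 2k + 2k(k+1)/(n - k - 1)
    dAICc  = AICc - min(AICc)
    weight = exp(-dAICc/2) / sum(exp(-dAICc/2))

Candidates with dAICc < 4 are flagged as having considerable support.
Model-averaged coefficients use the full-average convention (a term
absent from a model contributes zero) and the relative importance of a
term is the summed weight of the models containing it.

The nonparametric tests are the ones small telemetry samples call for:
paired Wilcoxon signed-rank and Spearman rank correlation with exact
small-sample null distributions (full enumeration), plus Mann-Whitney;
larger samples fall back to the standard approximations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SUPPORT_DELTA_AICC = 4.0
WILCOXON_EXACT_MAX_N = 15
SPEARMAN_EXACT_MAX_N = 8


@dataclass
class ModelCandidate:
    """One candidate model; AICc and friends are filled by rank_models."""

    label: str
    log_likelihood: float | None = None
    k: int | None = None
    n: int | None = None
    aicc: float | None = None
    delta_aicc: float | None = None
    weight: float | None = None
    supported: bool | None = None
    formula_terms: frozenset = field(default_factory=frozenset)


def aic(log_likelihood: float, k: int) -> float:
    return -2.0 * log_likelihood + 2.0 * k


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; undefined unless n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return aic(log_likelihood, k) + 2.0 * k * (k + 1) / (n - k - 1)


def rank_models(candidates: Sequence[ModelCandidate],
                support_delta: float = SUPPORT_DELTA_AICC) -> list[ModelCandidate]:
    """Fill delta_aicc, weight and the support flag; sort best-first.

    Ties in AICc are broken by label so the output order is deterministic.
    """
    if not candidates:
        raise ValueError("no candidates")
    out = []
    for c in candidates:
        val = c.aicc
        if val is None:
            if c.log_likelihood is None or c.k is None or c.n is None:
                raise ValueError(f"candidate {c.label!r} has neither aicc nor (logL, k, n)")
            val = aicc(c.log_likelihood, c.k, c.n)
        out.append(ModelCandidate(c.label, c.log_likelihood, c.k, c.n, val,
                                  formula_terms=c.formula_terms))
    best = min(c.aicc for c in out)
    rel = [math.exp(-(c.aicc - best) / 2.0) for c in out]
    total = sum(rel)
    for c, r in zip(out, rel):
        c.delta_aicc = c.aicc - best
        c.weight = r / total
        c.supported = c.delta_aicc < support_delta
    return sorted(out, key=lambda c: (c.aicc, c.label))


def rank_models_frame(table: pd.DataFrame,
                      support_delta: float = SUPPORT_DELTA_AICC) -> pd.DataFrame:
    """DataFrame front-end: columns label + (aicc | logLik,k,n) [+ terms]."""
    cands = []
    for _, row in table.iterrows():
        terms = frozenset(str(row["terms"]).split("+")) if "terms" in row and pd.notna(row.get("terms")) else frozenset()
        cands.append(ModelCandidate(
            label=str(row["label"]),
            log_likelihood=row.get("logLik"),
            k=int(row["k"]) if "k" in row and pd.notna(row.get("k")) else None,
            n=int(row["n"]) if "n" in row and pd.notna(row.get("n")) else None,
            aicc=float(row["aicc"]) if "aicc" in row and pd.notna(row.get("aicc")) else None,
            formula_terms=terms))
    ranked = rank_models(cands, support_delta)
    return pd.DataFrame([{
        "label": c.label, "aicc": c.aicc, "delta_aicc": c.delta_aicc,
        "weight": c.weight, "supported": c.supported} for c in ranked])


def model_average(candidates: Sequence[ModelCandidate],
                  coefficients: Mapping[str, Mapping[str, float]]
                  ) -> tuple[dict[str, float], dict[str, float]]:
    """(averaged coefficients, relative term importance).

    *coefficients* maps model label -> {term: estimate}.  Averaging uses
    the full-average convention: a term missing from a model counts as
    zero there.  Relative importance of a term is the summed Akaike
    weight of the models whose coefficient table (or formula_terms)
    contains it.
    """
    if any(c.weight is None for c in candidates):
        candidates = rank_models(candidates)
    terms: set[str] = set()
    for label, coefs in coefficients.items():
        terms |= set(coefs)
    averaged = {}
    importance = {}
    for t in sorted(terms):
        averaged[t] = sum(c.weight * coefficients.get(c.label, {}).get(t, 0.0)
                          for c in candidates)
        importance[t] = sum(c.weight for c in candidates
                            if t in coefficients.get(c.label, {})
                            or t in c.formula_terms)
    return averaged, importance


def term_importance(candidates: Sequence[ModelCandidate], term: str) -> float:
    """Summed weight of the candidates whose formula contains *term*."""
    if any(c.weight is None for c in candidates):
        candidates = rank_models(candidates)
    return sum(c.weight for c in candidates if term in c.formula_terms)


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(paired: Sequence[tuple[float, float]]
                         ) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; (W+, two-sided p).

    Zero differences are dropped; ties get mid-ranks.  With at most 15
    non-zero pairs the null distribution is enumerated exactly over all
    2^n sign assignments (valid under ties as well); beyond that the
    normal approximation with tie correction is used.
    """
    a = np.asarray([p[0] for p in paired], dtype=float)
    b = np.asarray([p[1] for p in paired], dtype=float)
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("degenerate pairs: all differences zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= WILCOXON_EXACT_MAX_N:
        # exact conditional null: every sign pattern equally likely
        stats_all = np.zeros(2 ** n)
        for i, signs in enumerate(itertools.product((0, 1), repeat=n)):
            stats_all[i] = sum(r for s, r in zip(signs, ranks) if s)
        mean = ranks.sum() / 2.0
        p = float(np.mean(np.abs(stats_all - mean) >= abs(w_plus - mean) - 1e-12))
        return w_plus, min(1.0, p)
    _, p = stats.wilcoxon(d, alternative="two-sided", correction=False,
                          method="approx")
    return w_plus, float(p)


def rank_correlation(x: Sequence[float], y: Sequence[float]
                     ) -> tuple[float, float]:
    """Spearman rank correlation; (rho, two-sided p).

    Mid-ranks throughout; exact permutation p over all n! orderings for
    n <= 8, the t-distribution approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of at least 3")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if n <= SPEARMAN_EXACT_MAX_N:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    _, p = stats.spearmanr(x, y)
    return rho, float(p)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Mann-Whitney U; exact where sample sizes allow, else
    the tie-corrected normal approximation (scipy's switching rule)."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
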