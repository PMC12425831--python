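"""Disproportionality statistics over 2x2 contingency tables.

For each term (MedDRA PT, or SOC) the corpus of distinct case-term pairs is
split into a 2x2 table

    ===========  ==============  ==================
                 term present    term absent
    ===========  ==============  ==================
    target drug  a               b
    other drugs  c               d
    ===========  ==============  ==================

and four standard screening statistics are computed:

* **ROR** — reporting odds ratio ``ad/(bc)`` with a Woolf (log-scale)
  95% interval; Haldane–Anscombe +0.5 on all cells when any cell is zero.
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with the
  2x2 chi-square (Yates-corrected by default, plain Pearson by flag).
* **BCPNN IC** — the information component ``log2 P(drug,event) /
  (P(drug)P(event))`` with Bayesian shrinkage: closed-form posterior mean
  and variance of IC under independent Beta posteriors with the standard
  priors (alpha1 = beta1 = 1, alpha = beta = 2, gamma11 = 1 with gamma tuned
  so the prior IC expectation is zero); IC025 = mean − 1.96 sd (a −2 sd
  variant by flag).
* **MGPS EBGM** — the gamma-Poisson shrinker: the observed count a is
  Poisson with mean lambda·E (E the count expected under independence) and
  lambda carries a two-component gamma mixture prior fitted by maximizing
  the negative-binomial-mixture marginal likelihood across all terms.  EBGM
  is the posterior geometric mean of lambda and EBGM05 its posterior 5th
  percentile (2.5th by flag).

A term is a *signal* only when all four criteria hold simultaneously:
a >= 3, ROR CI lower bound > 1, (PRR >= 2 and chi2 >= 4), IC025 > 0, and
EBGM05 > 2.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, special, stats

from .types import CaseRecord, MeddraMap

__all__ = [
    "ContingencyTable",
    "PriorHyperparams",
    "Thresholds",
    "SignalRow",
    "case_pt_pairs",
    "case_soc_pairs",
    "build_tables",
    "ror",
    "prr_chi2",
    "bcpnn_ic",
    "expected_count",
    "mgps_fit",
    "mgps_marginal_loglik",
    "ebgm",
    "joint_signal",
    "compute_signal_rows",
    "rank_signals",
    "DUMOUCHEL_INIT",
]

LN2 = math.log(2.0)
_Z95 = 1.96


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.N == 0:
            raise ValueError("empty contingency table")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class PriorHyperparams:
    """Two-component gamma mixture prior on the observed/expected ratio."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p_mix: float
    converged: bool = True
    loglik: float = math.nan

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0.0 <= self.p_mix <= 1.0:
            raise ValueError("p_mix must lie in [0, 1]")


# DuMouchel's classic starting values for the mixture fit.
DUMOUCHEL_INIT = PriorHyperparams(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


@dataclass(frozen=True)
class Thresholds:
    """Joint positivity rule; all criteria must hold simultaneously."""

    min_a: int = 3
    ror_ci_low: float = 1.0  # exclusive lower bound
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0  # exclusive
    ebgm05_min: float = 2.0  # exclusive


@dataclass
class SignalRow:
    term: str
    level: str  # "PT" or "SOC"
    a: int
    ror: float
    ror_ci95: tuple[float, float]
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    is_signal: bool = False
    table: ContingencyTable | None = None


def case_pt_pairs(records: Iterable[CaseRecord]) -> set[tuple[int, str]]:
    """Distinct (caseid, PT) pairs: a case counts once per distinct PT."""
    return {(r.caseid, pt) for r in records for pt in r.pts}


def case_soc_pairs(records: Iterable[CaseRecord], mapping: MeddraMap) -> set[tuple[int, str]]:
    """Distinct (caseid, SOC) pairs; unmapped PTs fall under ``unmapped``."""
    return {(r.caseid, mapping.soc_of(pt) or "unmapped") for r in records for pt in r.pts}


def build_tables(
    pairs: Iterable[tuple[int, str]], target_caseids: set[int]
) -> dict[str, ContingencyTable]:
    """One 2x2 table per observed term, from distinct case-term pairs.

    Margins are shared: a+b is the total number of target pairs and c+d the
    total number of non-target pairs, so N is identical across terms.
    """
    pairs = set(pairs)
    n_target = sum(1 for cid, _ in pairs if cid in target_caseids)
    n_other = len(pairs) - n_target
    a_counts: dict[str, int] = {}
    c_counts: dict[str, int] = {}
    for cid, term in pairs:
        if cid in target_caseids:
            a_counts[term] = a_counts.get(term, 0) + 1
        else:
            c_counts[term] = c_counts.get(term, 0) + 1
    tables = {}
    for term in sorted(set(a_counts) | set(c_counts)):
        a = a_counts.get(term, 0)
        c = c_counts.get(term, 0)
        tables[term] = ContingencyTable(a=a, b=n_target - a, c=c, d=n_other - c)
    return tables


def ror(table: ContingencyTable) -> tuple[float, tuple[float, float]]:
    """Reporting odds ratio with Woolf 95% CI.

    When any cell is zero the Haldane–Anscombe +0.5 correction is applied to
    every cell, keeping the estimate and interval finite.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(value) - _Z95 * se)
    hi = math.exp(math.log(value) + _Z95 * se)
    return value, (lo, hi)


def prr_chi2(table: ContingencyTable, variant: str = "yates") -> tuple[float, float]:
    """Proportional reporting ratio and the 2x2 chi-square.

    PRR keeps its conventional definition: a zero non-target event count with
    a > 0 yields +inf rather than a corrected finite value.  ``variant`` is
    ``"yates"`` (continuity-corrected, the default) or ``"pearson"``.
    """
    if variant not in ("yates", "pearson"):
        raise ValueError(f"unknown chi2 variant {variant!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0:
        raise ValueError("PRR requires both drug margins to be positive")
    rate_t = a / (a + b)
    rate_o = c / (c + d) if (c + d) else 0.0
    if rate_o == 0.0:
        prr = math.inf if a > 0 else 0.0
    else:
        prr = rate_t / rate_o

    n = table.N
    observed = (a, b, c, d)
    row = (a + b, a + b, c + d, c + d)
    col = (a + c, b + d, a + c, b + d)
    chi2 = 0.0
    degenerate = any(m == 0 for m in (a + b, c + d, a + c, b + d))
    if degenerate:
        chi2 = math.nan
    else:
        for o, r_m, c_m in zip(observed, row, col):
            e = r_m * c_m / n
            dev = abs(o - e)
            if variant == "yates":
                dev = max(dev - 0.5, 0.0)
            chi2 += dev * dev / e
    return prr, chi2


def bcpnn_ic(table: ContingencyTable, variant: str = "z196") -> tuple[float, float]:
    """Information component: closed-form posterior mean and lower bound.

    The joint, drug and event reporting probabilities carry Beta posteriors
    (priors: gamma11 = 1 for the joint cell with gamma chosen so the prior IC
    expectation is zero; alpha1 = beta1 = 1 against alpha = beta = 2 for the
    margins).  Posterior moments of IC = (ln p11 − ln p1. − ln p.1)/ln 2
    follow exactly from digamma/trigamma identities for log-Beta moments.
    ``variant``: ``"z196"`` -> IC025 = mean − 1.96 sd; ``"sd2"`` -> −2 sd.
    """
    if variant not in ("z196", "sd2"):
        raise ValueError(f"unknown ic025 variant {variant!r}")
    a = table.a
    n = table.N
    n1 = table.a + table.b  # target-drug margin
    n2 = table.a + table.c  # event margin
    a1 = b1 = 1.0
    aa = bb = 2.0
    g11 = 1.0
    g = g11 * (n + aa) * (n + bb) / ((n1 + a1) * (n2 + b1))

    mean_ln = (
        special.digamma(g11 + a)
        - special.digamma(g + n)
        - (special.digamma(a1 + n1) - special.digamma(aa + n))
        - (special.digamma(b1 + n2) - special.digamma(bb + n))
    )
    var_ln = (
        special.polygamma(1, g11 + a)
        - special.polygamma(1, g + n)
        + special.polygamma(1, a1 + n1)
        - special.polygamma(1, aa + n)
        + special.polygamma(1, b1 + n2)
        - special.polygamma(1, bb + n)
    )
    ic = float(mean_ln) / LN2
    sd = math.sqrt(max(float(var_ln), 0.0)) / LN2
    z = _Z95 if variant == "z196" else 2.0
    return ic, ic - z * sd


def expected_count(table: ContingencyTable) -> float:
    """Count expected under row/column independence: (a+b)(a+c)/N."""
    return (table.a + table.b) * (table.a + table.c) / table.N


def _nb_logpmf(a: np.ndarray, alpha: float, beta: float, e: np.ndarray) -> np.ndarray:
    # marginal of Poisson(lambda*E) with lambda ~ Gamma(alpha, rate beta)
    return stats.nbinom.logpmf(a, alpha, beta / (beta + e))


def mgps_marginal_loglik(theta: PriorHyperparams, a: np.ndarray, e: np.ndarray) -> float:
    """Marginal log-likelihood of counts under the mixture prior."""
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    lp1 = _nb_logpmf(a, theta.alpha1, theta.beta1, e)
    lp2 = _nb_logpmf(a, theta.alpha2, theta.beta2, e)
    p = np.clip(theta.p_mix, 1e-12, 1 - 1e-12)
    return float(np.logaddexp(np.log(p) + lp1, np.log1p(-p) + lp2).sum())


def mgps_fit(
    tables: Iterable[ContingencyTable],
    init: PriorHyperparams = DUMOUCHEL_INIT,
    single_component: bool = False,
) -> PriorHyperparams:
    """Fit the two-component gamma mixture prior across all terms.

    Maximizes the negative-binomial-mixture marginal likelihood in
    unconstrained (log / logit) parameter space with Nelder–Mead.  With
    ``single_component=True`` the mixture weight is pinned at 1 and only the
    first component is fitted (a plain gamma-Poisson shrinker).
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("mgps_fit needs at least two distinct terms")
    a = np.array([t.a for t in tables], dtype=float)
    e = np.array([expected_count(t) for t in tables], dtype=float)

    def unpack(x: np.ndarray) -> PriorHyperparams:
        if single_component:
            a1, b1 = np.exp(x)
            return PriorHyperparams(a1, b1, init.alpha2, init.beta2, 1.0)
        a1, b1, a2, b2 = np.exp(x[:4])
        p = 1.0 / (1.0 + math.exp(-x[4]))
        return PriorHyperparams(a1, b1, a2, b2, p)

    # Box the transformed parameters: shapes/rates in [e^-12, e^12].  The
    # marginal likelihood can climb indefinitely toward point-mass components
    # when the empirical lambda distribution is nearly discrete; the box keeps
    # the optimum finite while still allowing essentially degenerate priors.
    _BOX = 12.0

    def neg_ll(x: np.ndarray) -> float:
        if np.any(np.abs(x) > _BOX):
            return math.inf
        with np.errstate(over="ignore"):
            try:
                return -mgps_marginal_loglik(unpack(x), a, e)
            except (ValueError, OverflowError):
                return math.inf

    if single_component:
        x0 = np.log([init.alpha1, init.beta1])
    else:
        x0 = np.array(
            [
                math.log(init.alpha1),
                math.log(init.beta1),
                math.log(init.alpha2),
                math.log(init.beta2),
                math.log(init.p_mix / (1 - init.p_mix)),
            ]
        )
    res = optimize.minimize(
        neg_ll,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 8000, "maxfev": 8000},
    )
    bounds = [(-_BOX, _BOX)] * len(x0)
    polish = optimize.minimize(neg_ll, np.clip(res.x, -_BOX, _BOX),
                               method="L-BFGS-B", bounds=bounds,
                               options={"maxiter": 500, "ftol": 1e-13})
    if polish.fun < res.fun:
        res = polish
    theta = unpack(res.x)
    return PriorHyperparams(
        theta.alpha1,
        theta.beta1,
        theta.alpha2,
        theta.beta2,
        theta.p_mix,
        converged=bool(res.success),
        loglik=-float(res.fun),
    )


def ebgm(
    table: ContingencyTable, theta: PriorHyperparams, quantile: float = 0.05
) -> tuple[float, float]:
    """Posterior geometric mean of lambda and its lower posterior quantile.

    The posterior of lambda given a is again a two-component gamma mixture
    with shapes ``alpha_j + a``, rates ``beta_j + E`` and weights
    proportional to the component marginal likelihoods.  EBGM =
    ``2**E[log2 lambda | a]``; the lower bound inverts the mixture CDF
    numerically at *quantile* (0.05 by default, 0.025 by flag).
    """
    if not 0.0 < quantile < 0.5:
        raise ValueError("quantile must be in (0, 0.5)")
    a = float(table.a)
    e = expected_count(table)
    shapes = np.array([theta.alpha1 + a, theta.alpha2 + a])
    rates = np.array([theta.beta1 + e, theta.beta2 + e])
    lw = np.array(
        [
            math.log(max(theta.p_mix, 1e-300)) + float(_nb_logpmf(np.array([a]), theta.alpha1, theta.beta1, np.array([e]))[0]),
            math.log(max(1 - theta.p_mix, 1e-300)) + float(_nb_logpmf(np.array([a]), theta.alpha2, theta.beta2, np.array([e]))[0]),
        ]
    )
    w = np.exp(lw - special.logsumexp(lw))

    elog = float(np.dot(w, special.digamma(shapes) - np.log(rates)))
    ebgm_value = math.exp(elog)

    comp_q = stats.gamma.ppf(quantile, shapes, scale=1.0 / rates)
    # the mixture quantile lies between the component quantiles; pad the
    # bracket slightly so degenerate weights cannot break the sign change
    lo = float(comp_q.min()) * (1 - 1e-9)
    hi = float(comp_q.max()) * (1 + 1e-9)

    def f(x: float) -> float:
        return float(np.dot(w, stats.gamma.cdf(x, shapes, scale=1.0 / rates))) - quantile

    if hi - lo < 1e-12 * max(hi, 1.0):
        q = 0.5 * (lo + hi)
    else:
        flo, fhi = f(lo), f(hi)
        if flo >= 0.0:
            q = lo
        elif fhi <= 0.0:
            q = hi
        else:
            q = optimize.brentq(f, lo, hi, xtol=1e-14, rtol=1e-14)
    return ebgm_value, float(q)


def joint_signal(row: SignalRow, thresholds: Thresholds = Thresholds()) -> bool:
    """True iff every one of the four algorithm criteria passes."""
    return bool(
        row.a >= thresholds.min_a
        and row.ror_ci95[0] > thresholds.ror_ci_low
        and row.prr >= thresholds.prr_min
        and row.chi2 >= thresholds.chi2_min
        and row.ic025 > thresholds.ic025_min
        and row.ebgm05 > thresholds.ebgm05_min
    )


def compute_signal_rows(
    tables: Mapping[str, ContingencyTable],
    level: str = "PT",
    thresholds: Thresholds = Thresholds(),
    chi2_variant: str = "yates",
    ic025_variant: str = "z196",
    ebgm_quantile: float = 0.05,
    theta: PriorHyperparams | None = None,
) -> list[SignalRow]:
    """All four statistics plus the joint verdict for every term.

    The MGPS prior is fitted once across all terms of the level unless a
    pre-fitted ``theta`` is supplied.
    """
    if theta is None:
        theta = mgps_fit(tables.values()) if len(tables) >= 2 else DUMOUCHEL_INIT
    rows = []
    for term in sorted(tables):
        t = tables[term]
        r, ci = ror(t)
        prr, chi2 = prr_chi2(t, variant=chi2_variant)
        ic, ic025 = bcpnn_ic(t, variant=ic025_variant)
        eb, eb05 = ebgm(t, theta, quantile=ebgm_quantile)
        row = SignalRow(
            term=term,
            level=level,
            a=t.a,
            ror=r,
            ror_ci95=ci,
            prr=prr,
            chi2=chi2,
            ic=ic,
            ic025=ic025,
            ebgm=eb,
            ebgm05=eb05,
            table=t,
        )
        row.is_signal = joint_signal(row, thresholds)
        rows.append(row)
    return rows


def rank_signals(rows: Sequence[SignalRow], key: str = "frequency", k: int | None = None) -> list[SignalRow]:
    """Top-k rows, descending by frequency (a) or by EBGM05.

    Ties break on the other key descending, then on the term name.
    """
    if key == "frequency":
        sort_key = lambda r: (-r.a, -r.ebgm05, r.term)
    elif key == "ebgm05":
        sort_key = lambda r: (-r.ebgm05, -r.a, r.term)
    else:
        raise ValueError(f"unknown ranking key {key!r}")
    ranked = sorted(rows, key=sort_key)
    return ranked if k is None else ranked[:k]
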