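"""Over-representation statistics for predicted protein classes.

The enrichment p-value for a gene set is the upper tail of the
hypergeometric distribution,

    p = 1 - sum_{i=0}^{k-1} C(M, i) C(N-M, n-i) / C(N, n),

where N is the background size, M the background members annotated to the
set, n the query size and k the annotated query members.  Binomial
coefficients are evaluated in log space (lgamma) so N ~ 20,000 backgrounds
do not overflow.  Sets are restricted to 10-500 members after intersection
with the background, p-values are Benjamini-Hochberg adjusted, and sets are
significant at adjusted p < 0.05 by default.

A 2x2 contingency analysis (e.g. AR/AD proteins inside/outside the
mitochondrion) reports the odds ratio (a/b)/(c/d), a two-sided Fisher exact
p-value by enumeration over all tables with the observed margins, and a
Woolf log-normal 95% CI (Haldane 0.5 correction when a cell is zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EnrichmentCounts", "EnrichmentConfig", "ContingencyTable", "EnrichmentResult",
    "hypergeom_p", "bh_adjust", "run_enrichment", "odds_ratio_fisher",
    "read_gmt", "write_gmt",
]


@dataclass
class EnrichmentCounts:
    N: int  # background size
    M: int  # background members annotated to the set
    n: int  # query size
    k: int  # annotated query members

    def __post_init__(self):
        if not (0 <= self.M <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"invalid counts {self}")
        if not (0 <= self.k <= min(self.M, self.n)):
            raise ValueError(f"k={self.k} outside [0, min(M, n)] for {self}")


@dataclass
class EnrichmentConfig:
    min_set_size: int = 10
    max_set_size: int = 500
    alpha: float = 0.05
    background: str = "all-annotated"  # or "explicit"

    def __post_init__(self):
        if not (0 < self.min_set_size <= self.max_set_size):
            raise ValueError("need 0 < min_set_size <= max_set_size")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class ContingencyTable:
    a: int  # e.g. AR inside
    b: int  # AR outside
    c: int  # AD inside
    d: int  # AD outside

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class EnrichmentResult:
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def _log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _hypergeom_logpmf(i: int, N: int, M: int, n: int) -> float:
    return _log_comb(M, i) + _log_comb(N - M, n - i) - _log_comb(N, n)


def hypergeom_p(counts: EnrichmentCounts) -> float:
    """Upper-tail hypergeometric p-value: P(X >= k)."""
    N, M, n, k = counts.N, counts.M, counts.n, counts.k
    if k == 0:
        return 1.0
    # sum the upper tail directly: no 1-minus-lower cancellation, so small
    # p-values keep full lgamma precision
    terms = [_hypergeom_logpmf(i, N, M, n) for i in range(k, min(M, n) + 1)]
    return float(min(1.0, math.exp(_logsumexp(terms))))


def _logsumexp(terms) -> float:
    terms = [t for t in terms if t > -math.inf]
    if not terms:
        return -math.inf
    m = max(terms)
    return m + math.log(sum(math.exp(t - m) for t in terms))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: one set per line — name, description, tab-separated members."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno}")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "synthetic"):
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def run_enrichment(query, gene_sets: dict[str, set[str]], background=None,
                   config: EnrichmentConfig | None = None) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in the query.

    Background defaults to the union of all gene-set members; an explicit
    list overrides it.  Sets are size-filtered after intersection with the
    background, BH adjustment runs across the surviving sets, and rows are
    sorted by adjusted then raw p, then set name.
    """
    config = config or EnrichmentConfig()
    if not gene_sets:
        raise ValueError("no gene sets given")
    query = set(query)
    if not query:
        raise ValueError("empty query")
    if background is None:
        bg = set().union(*gene_sets.values())
    else:
        bg = set(background)
    if not bg:
        raise ValueError("empty background")
    if not query <= bg:
        raise ValueError(f"query not contained in background: e.g. {sorted(query - bg)[:3]}")
    rows = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & bg
        if not (config.min_set_size <= len(members) <= config.max_set_size):
            continue
        counts = EnrichmentCounts(N=len(bg), M=len(members), n=len(query),
                                  k=len(query & members))
        rows.append({"set": name, "N": counts.N, "M": counts.M, "n": counts.n,
                     "k": counts.k, "p": hypergeom_p(counts)})
    table = pd.DataFrame(rows)
    if not table.empty:
        table["q"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["q"] < config.alpha
        table = table.sort_values(["q", "p", "set"]).reset_index(drop=True)
    return table


def odds_ratio_fisher(table: ContingencyTable, haldane: bool = True) -> dict:
    """Odds ratio (a/b)/(c/d), two-sided Fisher exact p, Woolf 95% CI.

    The two-sided p sums hypergeometric probabilities of every table with
    the observed margins that is no more probable than the observed one.
    With a zero cell the OR and CI use the Haldane 0.5 correction unless
    disabled, in which case a zero denominator is an error.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    zero = min(a, b, c, d) == 0
    if zero and not haldane:
        raise ZeroDivisionError("zero cell without Haldane correction")
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if zero else (a, b, c, d)
    oratio = (aa / bb) / (cc / dd)
    # Fisher two-sided by enumeration over the hypergeometric family
    n1, n0 = a + b, c + d  # row margins
    m1 = a + c  # first-column margin
    N = n1 + n0
    logp_obs = _hypergeom_logpmf(a, N, m1, n1)
    total = 0.0
    for x in range(max(0, n1 - (N - m1)), min(n1, m1) + 1):
        lp = _hypergeom_logpmf(x, N, m1, n1)
        if lp <= logp_obs + 1e-7:  # relative tolerance, as in standard practice
            total += math.exp(lp)
    p = min(1.0, total)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo = math.exp(math.log(oratio) - 1.959963984540054 * se)
    hi = math.exp(math.log(oratio) + 1.959963984540054 * se)
    return {"odds_ratio": float(oratio), "p": float(p), "ci95": (float(lo), float(hi))}
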