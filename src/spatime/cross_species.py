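"""Cross-species sharing of pseudotime-associated genes.

Homology classes are reduced to strict one-to-one ortholog pairs; the
comparison background keeps pairs expressed (detected in at least 1% of
cells) and MI-significant in both species; the overlap between the two
species' top-hit sets inside that background is tested with an upper-tail
hypergeometric probability. The tail sum runs in log space (log-gamma
binomial coefficients combined with log-sum-exp) so that p-values far
below the double underflow threshold of naive summation remain exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import gammaln, logsumexp

CLASS_COL = "DB Class Key"
ORG_COL = "Common Organism Name"
SYMBOL_COL = "Symbol"


def one_to_one_orthologs(table: pd.DataFrame) -> list[tuple[str, str]]:
    """Strict one-to-one pairs from a homology table (class, organism,
    symbol rows). Classes with more than one gene in either organism are
    dropped, as is any symbol appearing in more than one class. Requires
    exactly two organism labels."""
    table = table[[CLASS_COL, ORG_COL, SYMBOL_COL]].drop_duplicates()
    organisms = sorted(table[ORG_COL].unique())
    if len(organisms) != 2:
        raise ValueError(f"expected exactly 2 organisms, found {organisms}")
    org_a, org_b = organisms  # alphabetical; "human" < "mouse, laboratory"

    dup_symbols = set(
        table.loc[table.duplicated([ORG_COL, SYMBOL_COL], keep=False), SYMBOL_COL]
    )
    counts = table.groupby([CLASS_COL, ORG_COL]).size().unstack(fill_value=0)
    strict = counts.index[(counts.get(org_a, 0) == 1) & (counts.get(org_b, 0) == 1)]
    sub = table[table[CLASS_COL].isin(strict)]
    pairs = []
    for key, grp in sub.groupby(CLASS_COL, sort=True):
        syms = dict(zip(grp[ORG_COL], grp[SYMBOL_COL]))
        a, b = syms[org_a], syms[org_b]
        if a in dup_symbols or b in dup_symbols:
            continue
        # return (mouse, human) ordering when recognizable, else (org_a, org_b)
        if "mouse" in org_b.lower():
            pairs.append((b, a))
        else:
            pairs.append((a, b))
    return pairs


def detection_fraction(expr, genes: list[str]) -> pd.Series:
    """Fraction of cells with a nonzero count, per requested gene
    (NaN for genes absent from the matrix)."""
    import anndata as ad

    assert isinstance(expr, ad.AnnData)
    X = expr.X
    frac = (
        np.asarray((X > 0).mean(axis=0)).ravel()
        if sparse.issparse(X)
        else (np.asarray(X) > 0).mean(axis=0)
    )
    lookup = pd.Series(frac, index=expr.var_names)
    return lookup.reindex(genes)


@dataclass
class BackgroundSet:
    pairs: list[tuple[str, str]]
    n_dropped_missing: int
    n_dropped_expression: int
    n_dropped_significance: int

    @property
    def size(self) -> int:
        return len(self.pairs)


def build_background(
    pairs: list[tuple[str, str]],
    expr_a,
    expr_b,
    mi_a: pd.DataFrame,
    mi_b: pd.DataFrame,
    min_expr_frac: float = 0.01,
) -> BackgroundSet:
    """One-to-one pairs that are detected in >= ``min_expr_frac`` of cells
    AND MI-significant (q < 0.05) in both species."""
    genes_a = [p[0] for p in pairs]
    genes_b = [p[1] for p in pairs]
    frac_a = detection_fraction(expr_a, genes_a).to_numpy()
    frac_b = detection_fraction(expr_b, genes_b).to_numpy()
    sig_a = mi_a.set_index("gene")["significant"].reindex(genes_a).to_numpy()
    sig_b = mi_b.set_index("gene")["significant"].reindex(genes_b).to_numpy()

    missing = np.isnan(frac_a) | np.isnan(frac_b)
    expressed = (frac_a >= min_expr_frac) & (frac_b >= min_expr_frac) & ~missing
    significant = (sig_a == True) & (sig_b == True) & ~missing  # noqa: E712

    keep = expressed & significant
    return BackgroundSet(
        pairs=[p for p, k in zip(pairs, keep) if k],
        n_dropped_missing=int(missing.sum()),
        n_dropped_expression=int((~missing & ~expressed).sum()),
        n_dropped_significance=int((~missing & expressed & ~significant).sum()),
    )


# ------------------------------------------------------------ overlap test


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail_log(N: int, K: int, n: int, k: int) -> float:
    """ln P(X >= k) for X ~ Hypergeometric(N, K, n), via log-gamma pmf
    terms combined with log-sum-exp."""
    upper = min(K, n)
    i = np.arange(k, upper + 1)
    if len(i) == 0:
        return -np.inf
    log_pmf = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
    return float(logsumexp(log_pmf))


@dataclass
class OverlapTest:
    """Printed-statistic record for cross-species top-hit sharing."""

    N: int
    K: int
    n: int
    k: int
    expected: float
    p: float
    log10_p: float

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "K": self.K,
            "n": self.n,
            "k": self.k,
            "expected": self.expected,
            "p": self.p,
            "log10_p": self.log10_p,
        }


def overlap_test(N: int, K: int, n: int, k: int) -> OverlapTest:
    """Upper-tail hypergeometric overlap test.

    N: background size; K: species-A top genes in background; n: species-B
    top genes in background; k: observed intersection. Expected overlap is
    K*n/N; p = P(X >= k) computed in log space.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K, n <= N")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K, n)={min(K, n)}]")
    if N == 0:  # empty background: the only outcome is k=0, so P(X >= 0) = 1
        return OverlapTest(N=0, K=0, n=0, k=0, expected=0.0, p=1.0, log10_p=0.0)
    log_p = hypergeom_upper_tail_log(N, K, n, k)
    p = float(np.exp(log_p))
    return OverlapTest(
        N=N,
        K=K,
        n=n,
        k=k,
        expected=K * n / N,
        p=p,
        log10_p=float(log_p / np.log(10.0)),
    )


def overlap_from_sets(
    background: list[tuple[str, str]],
    top_a: set[str],
    top_b: set[str],
) -> OverlapTest:
    """Overlap test from gene sets: top sets are intersected with the
    background before forming K, n and k."""
    bg_a = {p[0] for p in background}
    bg_b = {p[1] for p in background}
    in_a = {p for p in background if p[0] in (top_a & bg_a)}
    in_b = {p for p in background if p[1] in (top_b & bg_b)}
    return overlap_test(
        N=len(background), K=len(in_a), n=len(in_b), k=len(in_a & in_b)
    )
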