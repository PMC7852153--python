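"""Annotation-term enrichment and qPCR validation arithmetic.

Enrichment is the plain upper-tail hypergeometric test of a DE set against a
universe with a user-supplied gene → term mapping, BH-corrected across terms.
No transcript-length bias correction is applied, so term lists from
length-aware tools will differ. qPCR helpers cover relative quantification by
2^−ΔΔCt and cross-platform fold-change concordance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cis import pearson_r
from .diffexpr import bh_adjust


@dataclass(frozen=True)
class EnrichmentResult:
    """One term: k of n DE genes hit a term covering K of N universe genes."""

    term: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float = float("nan")
    significant: bool = False


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeometric_enrichment(
    de_set, universe, term_map, alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Term enrichment of ``de_set`` within ``universe``.

    ``term_map`` maps term id → iterable of universe genes. Per term the
    upper-tail hypergeometric p is computed, BH-adjusted across all tested
    terms; results are sorted by p and flagged significant at q < alpha.
    Raises when the DE set is not a subset of the universe.
    """
    de = set(de_set)
    uni = set(universe)
    stray = de - uni
    if stray:
        raise ValueError(f"DE genes outside the universe: {sorted(stray)}")
    N, n = len(uni), len(de)
    rows = []
    for term in sorted(term_map):
        members = set(term_map[term]) & uni
        K = len(members)
        k = len(members & de)
        rows.append((term, k, K, hypergeometric_p(k, K, n, N)))
    if not rows:
        return []
    q = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(term, k, K, n, N, p, qv, bool(qv < alpha))
        for (term, k, K, p), qv in zip(rows, q)
    ]
    results.sort(key=lambda r: (r.p, r.term))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "N": [r.N for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "significant": [r.significant for r in results],
        }
    )


def read_term_map(path) -> dict[str, set[str]]:
    """Two-column tab-delimited (gene, term) file → term → gene set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], comment="#")
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        out.setdefault(str(term), set()).add(str(gene))
    return out


def delta_delta_ct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression 2^−ΔΔCt with ΔΔCt = (Ct_target − Ct_ref)_treated −
    (Ct_target − Ct_ref)_control. The control condition against itself is 1."""
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))


def platform_concordance(fc_seq, fc_qpcr) -> float:
    """Pearson r between log2 fold changes of two platforms (e.g. RNA-seq vs
    RT-qPCR) over their shared features; needs at least 3 in common."""
    shared = sorted(set(fc_seq) & set(fc_qpcr))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared features, got {len(shared)}")
    x = np.log2([float(fc_seq[f]) for f in shared])
    y = np.log2([float(fc_qpcr[f]) for f in shared])
    r = pearson_r(x, y)
    if r is None:
        raise ValueError("zero variance in one platform's fold changes")
    return r
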