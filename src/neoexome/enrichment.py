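"""Gene-set over-representation by the EASE score (modified Fisher's exact).

The EASE score is the one-sided upper-tail Fisher p-value of the 2x2
query-vs-pathway table computed after removing one gene from the overlap cell
— a deliberately conservative variant of the classical test (removing a
success always weakens the evidence, so EASE p >= Fisher p). Significance is
judged per pathway at alpha = 0.05 with no multiple-testing correction by
default; a Benjamini-Hochberg adjustment is available but off, matching the
per-pathway testing convention of the functional-annotation service this
mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

ALPHA = 0.05


@dataclass
class EnrichmentResult:
    sample_id: str
    pathway: str
    k: int  # overlap genes
    n: int  # query-list size
    K: int  # pathway size within the background
    N: int  # background size
    p_ease: float
    significant: bool


def _check_margins(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n, K) <= N and n <= N and K <= N):
        raise ValueError(f"inconsistent 2x2 margins k={k}, n={n}, K={K}, N={N}")


def fisher_p(k: int, n: int, K: int, N: int) -> float:
    """Classical one-sided upper-tail Fisher p: P[X >= k], X ~ Hypergeom(N, K, n)."""
    _check_margins(k, n, K, N)
    return float(hypergeom.sf(k - 1, N, K, n))


def ease_p(k, n: int, K: int, N: int):
    """EASE score: upper-tail hypergeometric p with one overlap gene removed.

    ``P[X >= k - 1]`` for X ~ Hypergeom(N, K, n). For k = 1 the decrement
    removes the only success and the score is 1 by convention; k = 0 also
    returns 1 (no overlap, nothing to test). ``k`` may be an array of overlap
    counts sharing the same margins.
    """
    karr = np.asarray(k)
    for kk in np.atleast_1d(karr):
        _check_margins(int(kk), n, K, N)
    p = np.where(karr <= 1, 1.0, hypergeom.sf(np.maximum(karr, 2) - 2, N, K, n))
    return float(p) if karr.ndim == 0 else p


def enrich_sample(
    genes: list[str],
    collection: GeneSetCollection,
    sample_id: str = "",
    background_size: int | None = None,
    alpha: float = ALPHA,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """EASE over-representation of a sample's HFI gene list in every gene set.

    Only sets overlapping the query (k >= 1) are reported, sorted ascending by
    p. The background defaults to the collection's distinct-gene universe.
    """
    if not genes:
        raise ValueError("empty gene list")
    query = {g.upper() for g in genes}
    N = background_size if background_size is not None else collection.background_size
    if N <= 0:
        raise ValueError("empty background")
    n = len(query)
    results: list[EnrichmentResult] = []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(query & members)
        if k < 1:
            continue
        p = ease_p(k, n, K, N)
        results.append(EnrichmentResult(sample_id, name, k, n, K, N, p, p < alpha))
    results.sort(key=lambda r: (r.p_ease, r.pathway))
    if bh_correct and results:
        rejected, p_adj, _, _ = multipletests([r.p_ease for r in results], alpha=alpha, method="fdr_bh")
        for r, p, rej in zip(results, p_adj, rejected):
            r.p_ease, r.significant = float(p), bool(rej)
        results.sort(key=lambda r: (r.p_ease, r.pathway))
    return results


def compare_groups(
    results_by_sample: dict[str, list[EnrichmentResult]],
    groups: dict[str, str],
) -> pd.DataFrame:
    """Per-pathway counts of samples reaching significance in each group.

    ``groups`` maps sample id -> group label (e.g. pCR / non-pCR, or
    diagnostic / residual). No pooled statistic is computed: the table reports
    "significant in a/b samples" per group, which is how the per-sample
    enrichment runs are compared.
    """
    labels = sorted(set(groups.values()))
    for sid in results_by_sample:
        if sid not in groups:
            raise ValueError(f"sample {sid!r} has no group label")
    denom = {g: sum(1 for s in results_by_sample if groups[s] == g) for g in labels}
    pathways = sorted({r.pathway for rs in results_by_sample.values() for r in rs})
    rows = []
    for pw in pathways:
        row: dict[str, object] = {"pathway": pw}
        for g in labels:
            hits = sum(
                1
                for sid, rs in results_by_sample.items()
                if groups[sid] == g and any(r.pathway == pw and r.significant for r in rs)
            )
            row[f"{g}_significant"] = hits
            row[f"{g}_total"] = denom[g]
        rows.append(row)
    return pd.DataFrame(rows)


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def alteration_grid(genes_by_sample: dict[str, list[str]]) -> pd.DataFrame:
    """Gene x sample presence grid (OncoPrint-style input table)."""
    samples = list(genes_by_sample)
    genes = sorted({g.upper() for gs in genes_by_sample.values() for g in gs})
    data = {
        s: [1 if g in {x.upper() for x in genes_by_sample[s]} else 0 for g in genes]
        for s in samples
    }
    return pd.DataFrame(data, index=genes)
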