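"""Term enrichment (GO/KEGG-style) for gene lists.

Significance of the overlap between a gene list and each term's gene set is
the upper-tail-inclusive hypergeometric probability P(X >= k) for
X ~ Hypergeometric(N, K, n); p-values across terms are BH-corrected. Term
content is user-supplied (gene_id, term_id, label, namespace TSV) — no live
database is consulted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import ValidationError


@dataclass
class TermMap:
    genes_by_term: dict[str, set[str]]
    labels: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.genes_by_term.items():
            if not genes:
                raise ValidationError(f"term {term!r} has an empty gene set")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "TermMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"gene_id", "term_id"}
        if not required <= set(df.columns):
            raise ValidationError(f"term map must have columns {sorted(required)}")
        genes: dict[str, set[str]] = {}
        labels: dict[str, str] = {}
        namespaces: dict[str, str] = {}
        for row in df.itertuples(index=False):
            genes.setdefault(row.term_id, set()).add(row.gene_id)
            if "term_label" in df.columns:
                labels[row.term_id] = row.term_label
            if "namespace" in df.columns:
                namespaces[row.term_id] = row.namespace
        return cls(genes, labels, namespaces)


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail inclusive P(X >= k), X ~ Hypergeometric(N, K, n).

    k: list genes in the term; K: background genes in the term; n: list size;
    N: background size.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValidationError(f"inconsistent hypergeometric arguments k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (clipped at 1, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    gene_list: set[str] | list[str],
    background: set[str] | list[str],
    terms: TermMap,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``gene_list`` against ``background``.

    Returns one row per term intersecting the background: k, n, K, N, p,
    BH q, enrichment score (k/n)/(K/N), and a ``significant`` flag (p < p_max,
    raw p, as enrichment figures conventionally use). Sorted by p.
    """
    genes = set(gene_list)
    bg = set(background)
    if not genes <= bg:
        raise ValidationError("gene list must be a subset of the background universe")
    if not genes:
        import warnings

        warnings.warn("empty gene list; returning empty enrichment table")
        return pd.DataFrame(
            columns=["term", "label", "namespace", "k", "n", "K", "N", "p", "q", "score",
                     "significant"]
        )
    n, N = len(genes), len(bg)
    rows = []
    for term, members in sorted(terms.genes_by_term.items()):
        K = len(members & bg)
        if K == 0:
            continue
        k = len(members & genes)
        p = hypergeom_pvalue(k, K, n, N)
        score = (k / n) / (K / N) if k else 0.0
        rows.append(
            {
                "term": term,
                "label": terms.labels.get(term, ""),
                "namespace": terms.namespaces.get(term, ""),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": p,
                "score": score,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["p"] < p_max
    return out.sort_values(["p", "term"]).reset_index(drop=True)[
        ["term", "label", "namespace", "k", "n", "K", "N", "p", "q", "score", "significant"]
    ]
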