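"""Candidate-gene prioritization by annotation-term similarity.

Ranks case genes by functional similarity to a literature-derived training
set across several annotation categories (pathways, biological processes,
phenotype, literature, protein interactions, co-expression), and performs
hypergeometric term enrichment of gene sets with Benjamini-Hochberg control
within category.

The similarity engine is deliberately transparent: per category, an
enriched "profile" of terms over-represented in the training set is built
by one-sided hypergeometric tests, each gene is scored by the Jaccard index
between its term set and that profile, and per-category scores are
aggregated as the mean of within-category percentile ranks. Precomputed
ranks from an external prioritization service can be supplied instead
(see :func:`rank_case_genes`'s ``precomputed`` argument).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata
from statsmodels.stats.multitest import multipletests

DESIGNATIONS = ("training", "case", "control", "excluded")


@dataclass
class GeneCatalog:
    """Gene -> term-set map per annotation category, with gene designations.

    ``terms[gene][category]`` is a frozenset of term ids; ``designation``
    partitions genes into training / case / control / excluded.
    """

    categories: list[str]
    terms: dict[str, dict[str, frozenset[str]]]
    designation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {d for d in self.designation.values()} - set(DESIGNATIONS)
        if bad:
            raise ValueError(f"unknown gene designations: {sorted(bad)}")
        for g in self.designation:
            if g not in self.terms:
                raise ValueError(f"designated gene {g!r} has no term sets")

    @property
    def genes(self) -> list[str]:
        return sorted(self.terms)

    def genes_with(self, designation: str) -> list[str]:
        return sorted(g for g, d in self.designation.items() if d == designation)

    def term_set(self, gene: str, category: str) -> frozenset[str]:
        return self.terms.get(gene, {}).get(category, frozenset())

    def term_universe(self, category: str) -> set[str]:
        out: set[str] = set()
        for per_cat in self.terms.values():
            out |= per_cat.get(category, frozenset())
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, designation: dict[str, str] | None = None) -> "GeneCatalog":
        """Build from a long table with columns (gene, category, term)."""
        required = {"gene", "category", "term"}
        if not required <= set(frame.columns):
            raise ValueError(f"catalog table needs columns {sorted(required)}")
        terms: dict[str, dict[str, set[str]]] = {}
        for gene, category, term in frame[["gene", "category", "term"]].itertuples(index=False):
            terms.setdefault(gene, {}).setdefault(category, set()).add(term)
        frozen = {g: {c: frozenset(s) for c, s in per.items()} for g, per in terms.items()}
        categories = sorted(frame["category"].unique())
        return cls(categories=categories, terms=frozen, designation=designation or {})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "category": c, "term": t}
            for g, per in sorted(self.terms.items())
            for c, ts in sorted(per.items())
            for t in sorted(ts)
        ]
        return pd.DataFrame(rows, columns=["gene", "category", "term"])


def _hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """One-sided upper tail P(X >= k), X ~ Hypergeom(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def training_profile(catalog: GeneCatalog, category: str, alpha: float = 0.05) -> frozenset[str]:
    """Terms over-represented in the training genes for one category.

    A term enters the profile when its one-sided hypergeometric enrichment p
    (training genes annotated with the term, against the background of all
    catalog genes) is below ``alpha``.
    """
    if category not in catalog.categories:
        raise ValueError(f"unknown category {category!r}")
    training = catalog.genes_with("training")
    annotated = [g for g in training if catalog.term_set(g, category)]
    if len(annotated) < 2:
        raise ValueError(f"need >= 2 annotated training genes in {category!r}")
    universe = catalog.term_universe(category)
    if not universe:
        raise ValueError(f"category {category!r} is empty")
    all_genes = catalog.genes
    N = len(all_genes)
    n = len(annotated)
    profile = set()
    for term in universe:
        K = sum(1 for g in all_genes if term in catalog.term_set(g, category))
        k = sum(1 for g in annotated if term in catalog.term_set(g, category))
        if _hypergeom_tail(k, N, K, n) < alpha:
            profile.add(term)
    return frozenset(profile)


def similarity_score(gene_terms: frozenset[str], profile: frozenset[str]) -> float:
    """Jaccard index between a gene's term set and the enriched profile."""
    if not profile:
        return 0.0
    if not gene_terms:
        warnings.warn("unannotated gene scored 0", stacklevel=2)
        return 0.0
    inter = len(gene_terms & profile)
    union = len(gene_terms | profile)
    return inter / union


def rank_case_genes(
    catalog: GeneCatalog,
    alpha: float = 0.05,
    precomputed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rank case genes by similarity to the training set.

    Combined score = mean over categories of the within-category percentile
    rank of the Jaccard score against the training profile. Ties are broken
    by gene id (lexicographic), and training genes are excluded from the
    output. Returns a frame sorted by rank with per-category scores.

    When ``precomputed`` is given (columns ``gene``, ``score`` or ``rank``),
    it is used verbatim — preserving fidelity when ranks from an external
    prioritization service are available.
    """
    case = catalog.genes_with("case")
    if not case:
        raise ValueError("catalog designates no case genes")
    if precomputed is not None:
        frame = precomputed.copy()
        if "score" in frame.columns:
            frame = frame.sort_values(["score", "gene"], ascending=[False, True])
        elif "rank" in frame.columns:
            frame = frame.sort_values(["rank", "gene"])
        else:
            raise ValueError("precomputed ranks need a 'score' or 'rank' column")
        frame = frame[frame["gene"].isin(case)].reset_index(drop=True)
        frame["rank"] = np.arange(1, len(frame) + 1)
        return frame[["rank", "gene"] + [c for c in frame.columns if c not in ("rank", "gene")]]

    case_sorted = sorted(case)  # category- and input-order invariant
    per_cat_pct = {}
    per_cat_score = {}
    for cat in sorted(catalog.categories):
        profile = training_profile(catalog, cat, alpha=alpha)
        scores = np.array([similarity_score(catalog.term_set(g, cat), profile) for g in case_sorted])
        # percentile rank in [0, 1]; average ranks for ties
        per_cat_score[cat] = scores
        per_cat_pct[cat] = rankdata(scores, method="average") / len(scores)
    combined = np.mean(np.column_stack(list(per_cat_pct.values())), axis=1)

    frame = pd.DataFrame({"gene": case_sorted, "score": combined})
    for cat in sorted(catalog.categories):
        frame[f"jaccard_{cat}"] = per_cat_score[cat]
    frame = frame.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame.reset_index(drop=True)


def term_enrichment(
    gene_set: set[str] | list[str],
    catalog: GeneCatalog,
    fdr_q: float = 0.05,
    flag_alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric term enrichment of a gene set against the catalog background.

    Per term: p = upper hypergeometric tail of the overlap between
    ``gene_set`` and the term's annotated genes; q = Benjamini-Hochberg
    within category. Rows with p below ``flag_alpha`` are flagged.
    """
    genes = set(gene_set)
    if not genes:
        raise ValueError("gene_set is empty")
    background = catalog.genes
    if len(background) < len(genes):
        raise ValueError("term universe smaller than gene_set")
    N = len(background)
    n = len(genes & set(background))
    rows = []
    for cat in sorted(catalog.categories):
        for term in sorted(catalog.term_universe(cat)):
            members = {g for g in background if term in catalog.term_set(g, cat)}
            K = len(members)
            k = len(members & genes)
            rows.append({"term": term, "category": cat, "k": k, "K": K, "p": _hypergeom_tail(k, N, K, n)})
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    for cat, idx in table.groupby("category").groups.items():
        table.loc[idx, "q"] = multipletests(table.loc[idx, "p"], method="fdr_bh")[1]
    table["significant"] = table["p"] < flag_alpha
    table["pass_fdr"] = table["q"] < fdr_q
    return table.sort_values(["category", "p", "term"]).reset_index(drop=True)
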