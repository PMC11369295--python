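"""GO-term over/under-representation of an associated-gene set.

Classic (term-by-term) two-sided Fisher's exact test of the study set against
the analyzed-gene background, followed by multiple-testing correction over
the analyzed terms and a summary tallying significant terms by their
highest-level parents (the ontology root's direct children).

Annotations supplied as a flat gene->term table are propagated up the
term->ancestor transitive closure (the true-path rule), so a gene annotated
to a term counts for every ancestor of that term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSet",
    "fisher_enrichment",
    "fisher_exact_two_sided",
    "correct_terms",
    "summarize_parents",
]


@dataclass
class AnnotationSet:
    """Gene->terms annotations plus the term->ancestors transitive closure."""

    gene_to_terms: dict[str, set[str]]
    term_ancestors: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_frames(cls, gene2go: pd.DataFrame, ancestors: pd.DataFrame, names=None):
        """Build from two-column (gene_id, term_id) and (term_id, ancestor_id)
        tables; the ancestor closure is checked for cycles."""
        g2t: dict[str, set[str]] = {}
        for g, t in gene2go.itertuples(index=False):
            g2t.setdefault(g, set()).add(t)
        anc: dict[str, set[str]] = {}
        for t, a in ancestors.itertuples(index=False):
            anc.setdefault(t, set()).add(a)
        for t, ancs in anc.items():
            if t in ancs:
                raise ValueError(f"cyclic ancestor relation at term {t}")
        return cls(g2t, anc, dict(names) if names else {})

    def propagated(self, genes) -> dict[str, set[str]]:
        """term -> set of genes annotated to it or any descendant."""
        members: dict[str, set[str]] = {}
        for g in genes:
            for t in self.gene_to_terms.get(g, ()):
                members.setdefault(t, set()).add(g)
                for a in self.term_ancestors.get(t, ()):
                    members.setdefault(a, set()).add(g)
        return members

    def roots(self) -> set[str]:
        """Terms that appear as ancestors but have no ancestors themselves."""
        all_anc = set().union(*self.term_ancestors.values()) if self.term_ancestors else set()
        return {a for a in all_anc if not self.term_ancestors.get(a)}

    def highest_level_parents(self, term: str) -> set[str]:
        """Ancestors of ``term`` (or the term itself) directly below a root."""
        roots = self.roots()
        candidates = self.term_ancestors.get(term, set()) | {term}
        out = set()
        for c in candidates:
            anc_c = self.term_ancestors.get(c, set())
            if anc_c and anc_c <= roots:
                out.add(c)
        return out


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric point probabilities over the support that do not
    exceed the observed one (with the conventional (1 + 1e-7) tie guard),
    conditioning on all margins.
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


def fisher_enrichment(
    study,
    background,
    ann: AnnotationSet,
    min_term_size: int = 5,
) -> pd.DataFrame:
    """Per-term two-sided Fisher exact test of study vs background genes.

    Terms with fewer than ``min_term_size`` annotated background genes are
    excluded from the analyzed-term set (and hence from the correction
    denominator).  Direction is 'over' when the study fraction exceeds the
    background fraction, 'under' when below, 'none' at a tie.

    Returns one row per analyzed term with the 2x2 counts
    (a = study & term, b = study - term, c = term - study, d = rest).
    """
    study = set(study)
    background = set(background)
    extra = study - background
    if extra:
        raise ValueError(f"study genes missing from background: {sorted(extra)[:5]}")
    members = ann.propagated(background)
    n_bg = len(background)
    n_study = len(study)
    rows = []
    for term in sorted(members):
        term_genes = members[term]
        k = len(term_genes)
        if k < min_term_size:
            continue
        a = len(term_genes & study)
        b = n_study - a
        c = k - a
        d = n_bg - n_study - c
        p = fisher_exact_two_sided(a, b, c, d)
        study_frac = a / n_study if n_study else 0.0
        bg_frac = k / n_bg
        direction = "over" if study_frac > bg_frac else ("under" if study_frac < bg_frac else "none")
        rows.append((term, ann.term_names.get(term, ""), a, b, c, d, direction, p))
    out = pd.DataFrame(
        rows, columns=["term_id", "name", "a", "b", "c", "d", "direction", "p"]
    ).set_index("term_id")
    out.attrs["n_analyzed_terms"] = len(out)
    return out


def correct_terms(
    rows: pd.DataFrame, alpha: float = 0.05, method: str = "bonferroni"
) -> pd.DataFrame:
    """Flag terms significant after correction over the analyzed terms.

    ``method`` is 'bonferroni' (default), 'holm' or 'bh'.
    """
    if rows.empty:
        raise ValueError("no analyzed terms to correct")
    method_map = {"bonferroni": "bonferroni", "holm": "holm", "bh": "fdr_bh"}
    reject, p_adj, *_ = multipletests(
        rows["p"].to_numpy(), alpha=alpha, method=method_map[method]
    )
    out = rows.copy()
    out["p_adjusted"] = p_adj
    out["significant"] = reject
    out.attrs["n_analyzed_terms"] = rows.attrs.get("n_analyzed_terms", len(rows))
    out.attrs["cutoff"] = alpha / len(rows) if method == "bonferroni" else np.nan
    return out


def summarize_parents(significant_terms, ann: AnnotationSet) -> pd.Series:
    """Tally significant terms by highest-level parent (root children).

    A term reaching several root children contributes to each; a term with
    no path to a root child is counted under ``unmapped`` with a warning.
    """
    counts: dict[str, int] = {}
    for term in significant_terms:
        parents = ann.highest_level_parents(term)
        if not parents:
            logger.warning("term %s has no root-child ancestor; counted as unmapped", term)
            parents = {"unmapped"}
        for p in parents:
            label = ann.term_names.get(p, p)
            counts[label] = counts.get(label, 0) + 1
    return pd.Series(counts, dtype=int).sort_values(ascending=False)
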