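"""Candidate-gene annotation statistics.

Three small analyses follow the frequency/trait pipeline: hypergeometric
enrichment of annotation categories (e.g. protein domains) among candidate
genes with Bonferroni correction over the categories observed in the hit set;
hyper-divergence classification of strains by interval overlap between a
locus and each strain's hyper-divergent regions; and a Welch t-test splitting
trait values by any per-strain grouping (e.g. divergent vs non-divergent).

Genes are counted at most once per category even if a domain occurs several
times in one protein. Intervals are 0-based half-open; an overlap of a single
base counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError


@dataclass
class EnrichmentResult:
    category: str
    k_hit: int
    n_hit: int
    K_bg: int
    N_bg: int
    fold: float
    p: float
    alpha_bonferroni: float
    significant: bool
    filtered_low_count: bool


def hypergeom_enrichment(background: pd.DataFrame, hits: Iterable[str], *,
                         alpha: float = 0.05,
                         min_hit_count: int = 5) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment per category among ``hits``.

    ``background`` is a (gene_id, category) table over the genome-wide
    universe; genes may carry several categories but each gene counts once
    per category. Hit genes absent from the background are reported with a
    warning and dropped. p = P(X >= k_hit) for X ~ Hypergeom(N_bg, K_bg,
    n_hit). The Bonferroni threshold divides ``alpha`` by the number of
    categories observed in the hit set; categories seen fewer than
    ``min_hit_count`` times among hits are flagged and excluded from
    significance calls.
    """
    required = {"gene_id", "category"}
    if not required <= set(background.columns):
        raise FormatError(f"background needs columns {sorted(required)}")
    bg = background.drop_duplicates(["gene_id", "category"])
    bg_genes = set(bg["gene_id"])
    hits = set(hits)
    if not hits:
        raise ValueError("hit set is empty")
    orphans = hits - bg_genes
    if orphans:
        warnings.warn(f"{len(orphans)} hit gene(s) absent from background; "
                      f"intersecting (e.g. {sorted(orphans)[:3]})")
        hits = hits & bg_genes
        if not hits:
            raise ValueError("no hit genes remain after intersecting with background")

    N_bg = len(bg_genes)
    n_hit = len(hits)
    K_by_cat = bg.groupby("category")["gene_id"].nunique()
    hit_bg = bg[bg["gene_id"].isin(hits)]
    k_by_cat = hit_bg.groupby("category")["gene_id"].nunique()

    categories = sorted(k_by_cat.index)
    missing_cats = [c for c in categories if c not in K_by_cat.index]
    if missing_cats:  # cannot happen when hits come from background, but be loud
        raise FormatError(f"categories in hits absent from background: {missing_cats}")
    threshold = alpha / len(categories)
    out = []
    for cat in categories:
        k, K = int(k_by_cat[cat]), int(K_by_cat[cat])
        p = float(stats.hypergeom.sf(k - 1, N_bg, K, n_hit))
        fold = (k / n_hit) / (K / N_bg)
        low = k < min_hit_count
        out.append(EnrichmentResult(
            category=cat, k_hit=k, n_hit=n_hit, K_bg=K, N_bg=N_bg,
            fold=float(fold), p=p, alpha_bonferroni=threshold,
            significant=bool(p < threshold and not low),
            filtered_low_count=low))
    return out


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def bonferroni_threshold(n_categories: int, alpha: float = 0.05, *,
                         sig_figs: int | None = 2) -> float:
    """``alpha / n_categories``, optionally rounded to 2 significant figures
    for reporting (0.05 / 102 -> 0.00049); full precision with
    ``sig_figs=None``."""
    if n_categories < 1:
        raise ValueError("n_categories must be >= 1")
    t = alpha / n_categories
    if sig_figs is None:
        return t
    return float(f"{t:.{sig_figs}g}")


def _check_interval(start: int, end: int, what: str) -> None:
    if start >= end:
        raise FormatError(f"malformed {what} interval: start {start} >= end {end}")


def classify_hyperdivergent(region_table: pd.DataFrame,
                            locus: tuple[str, int, int]) -> pd.Series:
    """Per-strain call: does any of the strain's regions overlap the locus?

    ``region_table`` columns: strain_id, chrom, start, end (0-based
    half-open). ``locus`` is (chrom, start, end). A strain is hyper-divergent
    at the locus iff some region intersects it by at least one base.
    """
    required = {"strain_id", "chrom", "start", "end"}
    if not required <= set(region_table.columns):
        raise FormatError(f"region table needs columns {sorted(required)}")
    chrom, lstart, lend = locus
    _check_interval(lstart, lend, "locus")
    calls: dict[str, bool] = {s: False for s in region_table["strain_id"].unique()}
    for row in region_table.itertuples(index=False):
        _check_interval(int(row.start), int(row.end), "region")
        if row.chrom != chrom:
            continue
        if max(int(row.start), lstart) < min(int(row.end), lend):
            calls[row.strain_id] = True
    return pd.Series(calls, name="hyperdivergent").sort_index()


@dataclass
class GroupSplit:
    group_means: dict
    group_sizes: dict
    t_statistic: float | None
    p_value: float | None


def split_trait_by_group(traits: pd.DataFrame, groups: Mapping[str, object] | pd.Series,
                         value_col: str = "slope") -> GroupSplit:
    """Welch two-sample t-test of a trait between two strain groups.

    ``groups`` maps strain_id to one of exactly two labels. Groups with fewer
    than two strains yield means but no test (degenerate-test warning).
    """
    groups = pd.Series(groups)
    df = traits.set_index("strain_id") if "strain_id" in traits.columns else traits
    values = df[value_col].reindex(groups.index).dropna()
    groups = groups.reindex(values.index)
    labels = sorted(groups.unique(), key=str)
    if len(labels) != 2:
        raise ValueError(f"need exactly two group labels, got {labels}")
    a = values[groups == labels[0]].to_numpy(float)
    b = values[groups == labels[1]].to_numpy(float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    means = {labels[0]: float(np.mean(a)), labels[1]: float(np.mean(b))}
    sizes = {labels[0]: int(a.size), labels[1]: int(b.size)}
    if a.size < 2 or b.size < 2:
        warnings.warn("a group has <2 strains; t-test not computed")
        return GroupSplit(means, sizes, None, None)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupSplit(means, sizes, float(t), float(p))
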