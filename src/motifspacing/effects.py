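"""Cross-sample effect sizes on ChIP-seq tag counts.

Binding strength is compared between a reference and an alternate sample
(e.g. two mouse strains) at aligned regions.  Per region the statistic is
the absolute log2 fold change of library-size-normalised tag counts; per
impact category the effect size is Cohen's d of those absolute fold
changes against the variant-free reference category, with a Mann-Whitney U
test for distributional difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variants import ImpactCategory

DEFAULT_SCALE = 1e7


class EffectsError(ValueError):
    pass


def normalize_tags(raw, library_size: float, scale: float = DEFAULT_SCALE):
    """Library-size normalisation: raw * scale / library_size."""
    if library_size <= 0:
        raise EffectsError("library size must be positive")
    return np.asarray(raw, dtype=float) * (scale / library_size)


def quantify_window(positions, center: int, halfwidth: int = 150) -> int:
    """Count tag positions in the half-open window
    [center - halfwidth, center + halfwidth)."""
    pos = np.asarray(positions)
    return int(((pos >= center - halfwidth) & (pos < center + halfwidth)).sum())


def log2_fold_change(a, b, pseudo: float = 1.0):
    """log2((a + pseudo) / (b + pseudo)); the pseudocount keeps zero-tag
    regions finite."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.log2((a + pseudo) / (b + pseudo))


def cohens_d(group1, group2, absolute: bool = True) -> float:
    """Cohen's d with the pooled standard deviation.

    When ``absolute`` the inputs are |.|-transformed first, so d compares
    magnitudes of change irrespective of direction.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise EffectsError("each group needs at least 2 values")
    if absolute:
        x, y = np.abs(x), np.abs(y)
    n1, n2 = x.size, y.size
    s1, s2 = x.var(ddof=1), y.var(ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    if pooled == 0:
        if x.mean() == y.mean():
            return 0.0
        raise EffectsError("pooled SD is zero with unequal means: d undefined")
    return float((x.mean() - y.mean()) / pooled)


def mann_whitney(group1, group2) -> float:
    """Two-sided Mann-Whitney U p-value; exact for combined n <= 20,
    normal approximation with tie correction otherwise."""
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EffectsError("groups must be nonempty")
    method = "exact" if x.size + y.size <= 20 and not _has_ties(x, y) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def _has_ties(x, y) -> bool:
    allv = np.concatenate([x, y])
    return np.unique(allv).size < allv.size


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties and a
    t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise EffectsError("need equal-length vectors with at least 3 points")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise EffectsError("rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class EffectSizeResult:
    category: str
    n: int
    median_abs_log2fc: float
    cohens_d: float
    mann_whitney_p: float


def strain_effect_table(
    tags_ref,
    tags_alt,
    categories,
    reference_category: str = ImpactCategory.VARIANT_FREE.value,
    pseudo: float = 1.0,
) -> pd.DataFrame:
    """Per-category effect sizes of genetic variation on binding.

    ``tags_ref`` / ``tags_alt`` are normalised tag counts at regions aligned
    across the two samples; ``categories`` is the per-region impact
    category.  For each category the |log2FC| distribution is compared to
    the reference (variant-free) category with Cohen's d on absolute values
    and a Mann-Whitney U test.  Categories with fewer than 2 regions are
    omitted with a warning.
    """
    tags_ref = np.asarray(tags_ref, dtype=float)
    tags_alt = np.asarray(tags_alt, dtype=float)
    cats = np.asarray([c.value if isinstance(c, ImpactCategory) else str(c) for c in categories])
    if not (tags_ref.size == tags_alt.size == cats.size):
        raise EffectsError("tags and categories must align")
    abs_fc = np.abs(log2_fold_change(tags_alt, tags_ref, pseudo=pseudo))
    ref_vals = abs_fc[cats == reference_category]
    if ref_vals.size < 2:
        raise EffectsError(
            f"reference category '{reference_category}' has fewer than 2 regions"
        )
    rows = []
    for cat in pd.unique(cats):
        vals = abs_fc[cats == cat]
        if vals.size < 2:
            warnings.warn(f"category {cat} has fewer than 2 regions; omitted")
            continue
        if cat == reference_category:
            d, p = float("nan"), float("nan")
        else:
            d = cohens_d(vals, ref_vals, absolute=True)
            p = mann_whitney(vals, ref_vals)
        rows.append(
            EffectSizeResult(
                category=cat,
                n=int(vals.size),
                median_abs_log2fc=float(np.median(vals)),
                cohens_d=d,
                mann_whitney_p=p,
            ).__dict__
        )
    return pd.DataFrame(rows)
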