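"""GO Slim category statistics on CpGo/e.

Sequences are binned into broad GO-Slim functional categories (a
sequence may fall into several bins, but at most once per bin), each
bin is summarised by mean CpGo/e ± standard error, and category
differences are tested by one-way ANOVA followed by Tukey's HSD
pairwise comparisons (Tukey–Kramer form for unequal bin sizes).

Because a sequence contributes one observation to every bin it belongs
to, observations are not strictly independent across bins; that
structure mirrors the binning rule and is recorded in output metadata.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dinucleotide import DinucleotideProfile, InsufficientDataError
from .seq_io import AnnotationTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CategoryStats:
    """Per-bin summary: size, mean CpGo/e, standard error of the mean.

    ``se`` is sample sd / sqrt(n); it is ``None`` for singleton bins.
    """

    slim_term: str
    n: int
    mean_cpg_oe: float
    se: float | None


@dataclass
class PairwiseMatrix:
    """Tukey-adjusted p-values and mean differences over category pairs."""

    p_values: pd.DataFrame      # symmetric, NaN diagonal
    mean_diffs: pd.DataFrame    # row mean - column mean
    f_stat: float
    anova_p: float
    alpha: float
    significant: list[tuple[str, str]] = field(default_factory=list)
    independence_note: str = (
        "sequences occurring in several bins contribute one observation "
        "per bin; observations are treated as independent across bins"
    )


def bin_by_slim(profiles: list[DinucleotideProfile],
                annotations: AnnotationTable) -> tuple[dict[str, set[str]], set[str]]:
    """Map each GO-Slim term to the set of sequence ids it contains.

    A sequence joins every slim bin that any of its GO terms maps to,
    at most once per bin (set semantics enforce this). Returns
    ``(bins, unbinned)`` where ``unbinned`` collects profiled sequences
    with no mapped slim term.
    """
    bins: dict[str, set[str]] = {}
    profiled_ids = [p.sequence_id for p in profiles]
    id_set = set(profiled_ids)
    rows = annotations.rows
    mapped = rows[rows["go_id"].isin(annotations.slim_map)]
    for seq_id, go_id in mapped.itertuples(index=False):
        if seq_id not in id_set:
            continue
        bins.setdefault(annotations.slim_map[go_id], set()).add(seq_id)
    binned = set().union(*bins.values()) if bins else set()
    unbinned = id_set - binned
    logger.info("binned %d/%d sequences into %d GO-Slim categories",
                len(binned), len(id_set), len(bins))
    return bins, unbinned


def category_summary(bins: dict[str, set[str]],
                     profiles: list[DinucleotideProfile]) -> list[CategoryStats]:
    """Mean ± SE of CpGo/e per GO-Slim bin (defined ratios only).

    Bins left empty after dropping undefined ratios are removed with a
    warning.
    """
    ratio = {p.sequence_id: p.cpg_oe for p in profiles}
    out: list[CategoryStats] = []
    for term in sorted(bins):
        vals = np.array([ratio[s] for s in bins[term]
                         if ratio.get(s) is not None], dtype=float)
        if vals.size == 0:
            logger.warning("GO-Slim bin %r has no defined CpGo/e values; dropped",
                           term)
            continue
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else None
        out.append(CategoryStats(term, int(vals.size), mean, se))
    return out


def summary_to_frame(summaries: list[CategoryStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"slim_term": s.slim_term, "n": s.n, "mean_cpg_oe": s.mean_cpg_oe,
          "se": s.se} for s in summaries]
    )


def tukey_pairwise_p(groups: dict[str, np.ndarray]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tukey–Kramer adjusted p-values for all group pairs.

    Uses the studentized-range distribution with the within-group mean
    square from the one-way ANOVA; the Kramer form
    ``sqrt(MSW/2 * (1/n_i + 1/n_j))`` handles unequal group sizes.
    """
    names = list(groups)
    k = len(names)
    ns = np.array([groups[g].size for g in names])
    means = np.array([groups[g].mean() for g in names])
    df_within = int(ns.sum() - k)
    ssw = sum(float(((groups[g] - groups[g].mean()) ** 2).sum()) for g in names)
    msw = ssw / df_within
    p = pd.DataFrame(np.nan, index=names, columns=names)
    d = pd.DataFrame(np.nan, index=names, columns=names)
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        if msw <= 0.0:
            pij = 0.0 if diff != 0.0 else 1.0
        else:
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se
            pij = float(stats.studentized_range.sf(q, k, df_within))
            pij = min(max(pij, 0.0), 1.0)
        p.iloc[i, j] = p.iloc[j, i] = pij
        d.iloc[i, j] = diff
        d.iloc[j, i] = -diff
    return p, d


def anova_tukey(bins: dict[str, set[str]],
                profiles: list[DinucleotideProfile],
                alpha: float = 0.05) -> PairwiseMatrix:
    """One-way fixed-effects ANOVA over GO-Slim bins plus Tukey HSD matrix.

    Only defined CpGo/e values enter; bins with fewer than 2 such values
    are excluded. Pairs with adjusted p < ``alpha`` are flagged.
    """
    ratio = {p.sequence_id: p.cpg_oe for p in profiles}
    groups: dict[str, np.ndarray] = {}
    for term in sorted(bins):
        vals = np.array([ratio[s] for s in bins[term]
                         if ratio.get(s) is not None], dtype=float)
        if vals.size >= 2:
            groups[term] = vals
    if len(groups) < 2:
        raise InsufficientDataError(
            f"need >= 2 bins with >= 2 defined values, got {len(groups)}"
        )
    f_stat, anova_p = stats.f_oneway(*groups.values())
    p, d = tukey_pairwise_p(groups)
    sig = [
        (a, b)
        for a, b in itertools.combinations(p.index, 2)
        if p.loc[a, b] < alpha
    ]
    return PairwiseMatrix(p_values=p, mean_diffs=d, f_stat=float(f_stat),
                          anova_p=float(anova_p), alpha=alpha, significant=sig)
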