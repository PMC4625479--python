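"""Binned statistics relating spatial interaction strength, genomic distance
and sequence identity to GO function similarity.

Gene pairs carry a contact count (0 marks a non-interacting pair), a
per-category function similarity, a genomic distance (undefined across
chromosomes) and two sequence identities. Function similarity is discretised
into ten bins: bin b in 1..9 covers [(b-1)/10, b/10) and bin 10 covers
[0.9, 1] inclusive — "near-identical function". Undefined fields exclude a
pair from any statistic touching them, category by category.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import PairKey, pair_key
from .genome import GeneCatalog

__all__ = [
    "N_BINS",
    "assign_similarity_bin",
    "bin_statistics",
    "welch_t_test",
    "distance_decile_bins",
    "sample_noninteracting_pairs",
    "sample_distance_matched_pairs",
    "correlation_report",
    "normalize_counts_for_plot",
    "FactorThresholds",
    "identify_high_similarity_pairs",
    "split_by_median_distance",
]

logger = logging.getLogger(__name__)

N_BINS = 10


def assign_similarity_bin(score: float) -> int:
    """Similarity bin 1..10; bin 10 is the closed interval [0.9, 1]."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"similarity score outside [0, 1]: {score}")
    return min(int(math.floor(score * 10)) + 1, N_BINS)


def _bins_of(scores: pd.Series) -> pd.Series:
    out = (np.floor(scores * 10) + 1).clip(upper=N_BINS)
    return out.astype(int)


def _sim_col(category: str) -> str:
    return f"sim_{category}"


def bin_statistics(
    pairs: pd.DataFrame, value: str, category: str
) -> pd.DataFrame:
    """Per-similarity-bin summary of a value column.

    ``value`` is one of the pair table's numeric columns (e.g.
    ``contact_count``, ``distance``, ``lcs_identity``). Pairs with undefined
    similarity in the category or undefined value are excluded. Returns a
    frame indexed 1..10 with mean, median, q25, q75 and n; empty bins keep
    n = 0 and NaN statistics rather than fabricated values.
    """
    sim = pairs[_sim_col(category)]
    sub = pairs.loc[sim.notna() & pairs[value].notna(), [value, _sim_col(category)]]
    if ((sub[_sim_col(category)] < 0) | (sub[_sim_col(category)] > 1)).any():
        raise ValueError("similarity scores outside [0, 1]")
    bins = _bins_of(sub[_sim_col(category)])
    grouped = sub[value].groupby(bins)
    out = pd.DataFrame(
        {
            "mean": grouped.mean(),
            "median": grouped.median(),
            "q25": grouped.quantile(0.25),
            "q75": grouped.quantile(0.75),
            "n": grouped.size(),
        }
    ).reindex(range(1, N_BINS + 1))
    out["n"] = out["n"].fillna(0).astype(int)
    out.index.name = "bin"
    return out


def welch_t_test(group_a, group_b) -> dict[str, float]:
    """Welch two-sample t-test (unequal variances), two-sided.

    Returns the t statistic, Welch-Satterthwaite degrees of freedom and the
    two-sided p-value. Both groups need n >= 2 and at least one must have
    nonzero variance.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            # identical constants: no difference, by convention t=0, p=1
            return {"t": 0.0, "df": float(len(a) + len(b) - 2), "p_value": 1.0}
        raise ValueError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return {"t": float(res.statistic), "df": float(df), "p_value": float(res.pvalue)}


def distance_decile_bins(pairs: pd.DataFrame, category: str) -> pd.DataFrame:
    """Ten equal-count genomic-distance bins with mean similarity per bin.

    Intra-chromosomal pairs only (defined distance and similarity). Pairs
    are ranked by (distance, gene_a, gene_b) — a stable rule that fixes
    ties — and split into ten contiguous rank ranges whose sizes differ by
    at most one, the remainder going to the lowest bins.
    """
    sim = pairs[_sim_col(category)]
    sub = pairs.loc[pairs["distance"].notna() & sim.notna()].copy()
    n = len(sub)
    if n < N_BINS:
        raise ValueError(f"need at least {N_BINS} pairs with defined distance, got {n}")
    sub = sub.sort_values(["distance", "gene_a", "gene_b"], kind="mergesort")
    base, rem = divmod(n, N_BINS)
    sizes = [base + 1 if i < rem else base for i in range(N_BINS)]
    labels = np.repeat(np.arange(1, N_BINS + 1), sizes)
    sub["distance_bin"] = labels
    grouped = sub.groupby("distance_bin")
    out = pd.DataFrame(
        {
            "mean_similarity": grouped[_sim_col(category)].mean(),
            "mean_distance": grouped["distance"].mean(),
            "min_distance": grouped["distance"].min(),
            "max_distance": grouped["distance"].max(),
            "n": grouped.size(),
        }
    )
    out.index.name = "distance_bin"
    return out


def sample_noninteracting_pairs(
    catalog: GeneCatalog,
    pairs: dict[PairKey, int],
    n: int = 20000,
    seed: int | np.random.Generator = 0,
) -> list[PairKey]:
    """Uniform sample of unordered gene pairs with zero observed contacts.

    Sampling is without replacement and reproducible under ``seed``. When
    fewer than ``n`` zero-contact pairs exist, all of them are returned with
    a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gene_ids = sorted(g.gene_id for g in catalog)
    total = len(gene_ids) * (len(gene_ids) - 1) // 2
    n_zero = total - len(pairs)
    if n_zero <= n:
        logger.warning(
            "only %d zero-contact pairs exist (requested %d); returning all", n_zero, n
        )
        out = []
        for i, a in enumerate(gene_ids):
            for b in gene_ids[i + 1 :]:
                if (a, b) not in pairs:
                    out.append((a, b))
        return out
    chosen: set[PairKey] = set()
    m = len(gene_ids)
    while len(chosen) < n:
        take = (n - len(chosen)) * 2 + 16
        ii = rng.integers(0, m, size=take)
        jj = rng.integers(0, m, size=take)
        for i, j in zip(ii, jj):
            if i == j:
                continue
            key = pair_key(gene_ids[i], gene_ids[j])
            if key in pairs or key in chosen:
                continue
            chosen.add(key)
            if len(chosen) == n:
                break
    return sorted(chosen)


def sample_distance_matched_pairs(
    reference_pairs: list[PairKey],
    catalog: GeneCatalog,
    pairs: dict[PairKey, int],
    tolerance_bp: int = 35,
    seed: int | np.random.Generator = 0,
) -> list[PairKey]:
    """One zero-contact pair per reference pair, matched on genomic distance.

    For each intra-chromosomal reference pair at distance d, a zero-contact
    same-chromosome pair with |d' - d| <= tolerance_bp is drawn at random;
    references with no candidate in tolerance are skipped and logged. The
    tolerance default mirrors the very tight 35 bp matching window used in
    the analyses this reproduces.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_chrom: dict[str, tuple[list[str], np.ndarray]] = {}
    for chrom in catalog.chromosomes:
        glist = catalog.genes_on(chrom)
        by_chrom[chrom] = ([g.gene_id for g in glist], np.array([g.start for g in glist]))
    chroms = catalog.chromosomes
    matched: list[PairKey] = []
    used: set[PairKey] = set()
    skipped = 0
    for ref in reference_pairs:
        ga, gb = catalog[ref[0]], catalog[ref[1]]
        if ga.chromosome != gb.chromosome:
            skipped += 1
            continue
        d = abs(ga.start - gb.start)
        found = None
        for chrom in rng.permutation(chroms):
            ids, starts = by_chrom[chrom]
            order = rng.permutation(len(ids))
            for i in order:
                lo = np.searchsorted(starts, starts[i] + d - tolerance_bp, side="left")
                hi = np.searchsorted(starts, starts[i] + d + tolerance_bp, side="right")
                for j in range(lo, hi):
                    if j == i:
                        continue
                    key = pair_key(ids[i], ids[j])
                    if key in pairs or key in used:
                        continue
                    found = key
                    break
                if found:
                    break
            if found:
                break
        if found is None:
            skipped += 1
        else:
            used.add(found)
            matched.append(found)
    if skipped:
        logger.warning("distance matching: %d reference pairs had no candidate", skipped)
    return matched


def correlation_report(pairs: pd.DataFrame, x: str, y: str) -> dict[str, float | int | None]:
    """Pearson correlation between two pair-table columns over defined rows."""
    sub = pairs.loc[pairs[x].notna() & pairs[y].notna(), [x, y]]
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 pairs with both {x} and {y} defined, got {n}")
    if sub[x].nunique() == 1 or sub[y].nunique() == 1:
        return {"r": None, "n": n}  # constant input: correlation undefined
    r, _ = stats.pearsonr(sub[x], sub[y])
    return {"r": float(r), "n": n}


def normalize_counts_for_plot(counts, drop_top: int = 20) -> np.ndarray:
    """Min-max scale counts to [0, 1] after dropping the ``drop_top`` largest.

    Mirrors the display normalisation of interaction counts: extreme
    outliers are removed first, the remainder scaled to [0, 1]. When all
    remaining values are equal they map to 0 by convention.
    """
    arr = np.asarray(counts, dtype=float)
    if len(arr) <= drop_top:
        raise ValueError(f"need more than {drop_top} values, got {len(arr)}")
    if drop_top > 0:
        keep = np.sort(np.argsort(arr, kind="stable")[:-drop_top])
        arr = arr[keep]
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


@dataclass(frozen=True)
class FactorThresholds:
    """Thresholds used to flag interacting pairs with near-identical function.

    Defaults follow the reported settings: at least 50 contacts, genomic
    distance at most 1 Mb (BP, MF) or 2 Mb (CC), sequence identity at
    least 25 %.
    """

    min_interactions: int = 50
    max_distance_bp: dict[str, int] | int = None  # type: ignore[assignment]
    min_identity: float = 0.25

    def __post_init__(self) -> None:
        if self.max_distance_bp is None:
            object.__setattr__(
                self,
                "max_distance_bp",
                {"BP": 1_000_000, "MF": 1_000_000, "CC": 2_000_000},
            )
        if self.min_interactions < 1 or self.min_identity <= 0:
            raise ValueError("factor thresholds must be positive")

    def distance_limit(self, category: str) -> int:
        if isinstance(self.max_distance_bp, dict):
            return self.max_distance_bp[category]
        return self.max_distance_bp


def identify_high_similarity_pairs(
    pairs: pd.DataFrame,
    thresholds: FactorThresholds,
    category: str,
    identity_col: str = "lcs_identity",
) -> dict[str, set[PairKey]]:
    """Pairs with similarity >= 0.9 recovered by each factor and jointly.

    Restricted to pairs with similarity >= 0.9 in the category, returns the
    subsets passing the interaction-count, distance and identity thresholds
    and their three-way intersection.
    """
    sim = pairs[_sim_col(category)]
    high = pairs.loc[sim.notna() & (sim >= 0.9)]
    keys = [pair_key(a, b) for a, b in zip(high["gene_a"], high["gene_b"])]
    high = high.assign(_key=keys)
    by_int = set(high.loc[high["contact_count"] >= thresholds.min_interactions, "_key"])
    by_dist = set(
        high.loc[
            high["distance"].notna()
            & (high["distance"] <= thresholds.distance_limit(category)),
            "_key",
        ]
    )
    by_ident = set(
        high.loc[
            high[identity_col].notna() & (high[identity_col] >= thresholds.min_identity),
            "_key",
        ]
    )
    return {
        "by_interactions": by_int,
        "by_distance": by_dist,
        "by_identity": by_ident,
        "intersection_all": by_int & by_dist & by_ident,
    }


def split_by_median_distance(pairs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split intra-chromosomal pairs at the median genomic distance.

    Short-range pairs have distance <= median (ties go short), long-range
    pairs distance > median.
    """
    sub = pairs.loc[pairs["distance"].notna()]
    if len(sub) < 2:
        raise ValueError("need at least 2 intra-chromosomal pairs")
    median = sub["distance"].median()
    short = sub.loc[sub["distance"] <= median]
    long = sub.loc[sub["distance"] > median]
    return short, long
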