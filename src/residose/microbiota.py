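"""Compositional summaries and nonparametric tests for taxa count tables.

Works on a samples x taxa count matrix (16S ASV/OTU-style feature table)
with a taxonomy lineage per taxon and per-sample metadata (group, sex,
time point, animal id).  Provides:

* per-sample relative abundance (closure to 1),
* collapsing counts to phylum or genus level (unclassified genera are
  labelled "unclassified <parent family or class>"),
* group composition summaries as mean ± SD percent relative abundance
  with a mean-abundance filter (the conventional >1% cut),
* the Firmicutes/Bacteroidota (F/B) ratio with phylum-name synonyms,
* alpha diversity (Shannon in nats, observed richness) and Bray–Curtis
  beta diversity,
* exact (full-enumeration) Wilcoxon signed-rank and Mann–Whitney U tests
  for paired / unpaired sample comparisons, with a tie-corrected normal
  approximation beyond the enumeration limit.

Two-sided exact p-values use the symmetric-distance convention: the
probability, over all equally likely sign assignments (or labelings), of a
statistic at least as far from the null center as the observed one.  For
tie-free data this coincides with the classical doubled one-tail value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis as _braycurtis

__all__ = [
    "TaxaTable",
    "CompositionSummary",
    "DiversityResult",
    "TestResult",
    "TAXON_SYNONYMS",
    "LINEAGE_LEVELS",
    "load_taxa_table",
    "write_taxa_table",
    "relative_abundance",
    "collapse_to_level",
    "group_composition",
    "fb_ratio",
    "shannon",
    "observed",
    "bray_curtis",
    "beta_diversity_matrix",
    "alpha_diversity",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
]

logger = logging.getLogger(__name__)

LINEAGE_LEVELS = ("phylum", "class", "family", "genus")

#: Interchangeable phylum spellings (old/new nomenclature).
TAXON_SYNONYMS: dict[str, str] = {
    "bacteroidetes": "Bacteroidota",
    "bacteroidota": "Bacteroidota",
    "firmicutes": "Firmicutes",
    "bacillota": "Firmicutes",
}

#: Default enumeration cutoff: 2^12 sign patterns / C(24,12) labelings.
DEFAULT_EXACT_LIMIT = 12


def canonical_taxon(name: str) -> str:
    return TAXON_SYNONYMS.get(name.strip().lower(), name.strip())


@dataclass
class TaxaTable:
    """Samples x taxa counts plus taxonomy and sample metadata.

    ``counts``: integer DataFrame, samples as rows, taxa as columns.
    ``taxonomy``: DataFrame indexed by taxon with columns phylum, class,
    family, genus (unclassified levels carry their parent label).
    ``sample_meta``: DataFrame indexed by sample id with columns group,
    sex, time_point, animal_id.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.taxonomy.index)
        if missing:
            raise ValueError(f"taxa without taxonomy: {sorted(missing)[:5]} ...")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def drop_empty_samples(self) -> "TaxaTable":
        keep = self.counts.sum(axis=1) > 0
        if not keep.all():
            logger.warning(
                "excluding %d zero-sum sample(s): %s",
                (~keep).sum(), list(self.counts.index[~keep]),
            )
        return TaxaTable(
            self.counts.loc[keep], self.taxonomy, self.sample_meta.loc[keep]
        )


@dataclass(frozen=True)
class CompositionSummary:
    """Per-group mean ± SD percent relative abundance, filtered."""

    means: pd.DataFrame   # groups x taxa, percent
    sds: pd.DataFrame     # groups x taxa, percent
    abundance_filter: float  # percent threshold; below-threshold taxa pooled


@dataclass(frozen=True)
class DiversityResult:
    alpha: pd.DataFrame   # per sample: shannon (nats), observed_taxa
    beta: pd.DataFrame    # Bray-Curtis sample x sample


@dataclass(frozen=True)
class TestResult:
    method: str      # "wilcoxon_signed_rank" | "mann_whitney_u"
    statistic: float
    p_value: float
    mode: str        # "exact" | "approximate"


# ---------------------------------------------------------------------------
# compositional summaries


def relative_abundance(table: TaxaTable) -> pd.DataFrame:
    """Per-sample proportions; zero-sum samples are excluded with a warning."""
    table = table.drop_empty_samples()
    counts = table.counts.astype(float)
    return counts.div(counts.sum(axis=1), axis=0)


def collapse_to_level(table: TaxaTable, level: str) -> TaxaTable:
    """Sum counts over taxa sharing a lineage label at ``level``.

    Total counts per sample are conserved.  The collapsed table's taxonomy
    keeps the levels at or above ``level``.
    """
    if level not in LINEAGE_LEVELS:
        raise ValueError(f"level must be one of {LINEAGE_LEVELS}")
    labels = table.taxonomy.loc[table.counts.columns, level]
    if labels.isna().any():
        bad = list(labels.index[labels.isna()])[:5]
        raise ValueError(f"missing {level} taxonomy for {bad}")
    collapsed = table.counts.T.groupby(labels.values).sum().T
    keep = LINEAGE_LEVELS[: LINEAGE_LEVELS.index(level) + 1]
    tax = (
        table.taxonomy.assign(_label=labels.reindex(table.taxonomy.index))
        .dropna(subset=["_label"])
        .groupby("_label")[list(keep)]
        .first()
    )
    tax.index.name = None
    tax[level] = tax.index
    for lvl in LINEAGE_LEVELS:
        if lvl not in tax.columns:
            tax[lvl] = tax[level]
    return TaxaTable(collapsed, tax[list(LINEAGE_LEVELS)], table.sample_meta)


def group_composition(
    table: TaxaTable,
    by: Sequence[str] = ("group",),
    threshold: float = 1.0,
) -> CompositionSummary:
    """Mean and sample SD of percent relative abundance per group.

    Groups are defined by the metadata keys in ``by``.  Taxa whose group
    mean abundance is at or below ``threshold`` percent are pooled into an
    ``"other"`` column (threshold 0 disables pooling).  Groups of size 1
    report SD 0 with a warning.
    """
    rel = relative_abundance(table) * 100.0
    meta = table.sample_meta.loc[rel.index]
    key = meta[list(by)].astype(str).agg("/".join, axis=1)
    means = rel.groupby(key).mean()
    sds = rel.groupby(key).std(ddof=1)
    sizes = rel.groupby(key).size()
    if (sizes == 1).any():
        logger.warning(
            "group(s) of size 1, SD reported as 0: %s", list(sizes.index[sizes == 1])
        )
    sds = sds.fillna(0.0)

    if threshold > 0:
        out_m = {}
        out_s = {}
        for g in means.index:
            keep = means.loc[g] > threshold
            pooled = rel.loc[key == g, means.columns[~keep]].sum(axis=1)
            m = means.loc[g, keep.index[keep]].to_dict()
            s = sds.loc[g, keep.index[keep]].to_dict()
            if (~keep).any():
                m["other"] = float(pooled.mean())
                s["other"] = float(pooled.std(ddof=1)) if len(pooled) > 1 else 0.0
            out_m[g] = m
            out_s[g] = s
        means = pd.DataFrame.from_dict(out_m, orient="index").fillna(0.0)
        sds = pd.DataFrame.from_dict(out_s, orient="index").fillna(0.0)
    return CompositionSummary(means=means, sds=sds, abundance_filter=threshold)


def fb_ratio(phylum_abundances: Mapping[str, float] | pd.Series) -> float:
    """Firmicutes / Bacteroidota ratio from phylum-level abundances.

    Accepts counts, proportions or percentages (the ratio is
    scale-invariant) keyed by phylum name; old and new spellings
    (Bacteroidetes/Bacteroidota, Firmicutes/Bacillota) are synonyms.
    """
    if isinstance(phylum_abundances, pd.Series):
        phylum_abundances = phylum_abundances.to_dict()
    canon: dict[str, float] = {}
    for name, v in phylum_abundances.items():
        canon[canonical_taxon(str(name))] = canon.get(canonical_taxon(str(name)), 0.0) + float(v)
    try:
        f = canon["Firmicutes"]
        b = canon["Bacteroidota"]
    except KeyError as exc:
        raise ValueError(f"missing phylum for F/B ratio: {exc}") from None
    if b <= 0:
        raise ZeroDivisionError("F/B ratio undefined: zero Bacteroidota abundance")
    return f / b


# ---------------------------------------------------------------------------
# diversity


def shannon(abundances: Sequence[float]) -> float:
    """Shannon index in nats: −Σ p ln p over p > 0 (input counts or
    proportions; normalised internally)."""
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any() or x.sum() <= 0:
        raise ValueError("abundances must be non-negative with positive sum")
    p = x / x.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def observed(counts: Sequence[float]) -> int:
    """Observed richness: number of taxa with count > 0."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    return int((x > 0).sum())


def bray_curtis(a: Sequence[float], b: Sequence[float]) -> float:
    """Bray–Curtis dissimilarity Σ|aᵢ−bᵢ| / Σ(aᵢ+bᵢ) ∈ [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.sum() + b.sum() == 0:
        raise ZeroDivisionError("Bray-Curtis undefined for two all-zero samples")
    return float(_braycurtis(a, b))


def alpha_diversity(table: TaxaTable) -> pd.DataFrame:
    counts = table.drop_empty_samples().counts
    return pd.DataFrame(
        {
            "shannon": [shannon(row) for _, row in counts.iterrows()],
            "observed_taxa": [observed(row) for _, row in counts.iterrows()],
        },
        index=counts.index,
    )


def beta_diversity_matrix(table: TaxaTable) -> pd.DataFrame:
    counts = table.drop_empty_samples().counts
    n = len(counts)
    mat = np.zeros((n, n))
    arr = counts.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _braycurtis(arr[i], arr[j])
    return pd.DataFrame(mat, index=counts.index, columns=counts.index)


def diversity(table: TaxaTable) -> DiversityResult:
    """Alpha (Shannon, observed richness) and beta (Bray–Curtis) diversity."""
    return DiversityResult(alpha=alpha_diversity(table), beta=beta_diversity_matrix(table))


# ---------------------------------------------------------------------------
# exact nonparametric tests


def _two_sided_p(dist: np.ndarray, observed_stat: float, center: float) -> float:
    """P(|T − center| ≥ |t − center|) over the enumerated null distribution."""
    d = np.abs(dist - center)
    return float(np.mean(d >= abs(observed_stat - center) - 1e-9))


def wilcoxon_signed_rank(
    paired_a: Sequence[float],
    paired_b: Sequence[float],
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; ties among |differences| get average
    ranks.  For n (nonzero differences) up to ``exact_limit`` the null
    distribution of W+ is built by enumerating all 2ⁿ sign assignments;
    beyond that a tie-corrected normal approximation with continuity
    correction is used.  All differences zero returns p = 1 by convention.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        logger.info("wilcoxon_signed_rank: all differences zero, p=1")
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, "exact")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    center = total / 2.0

    if n <= exact_limit:
        dist = np.zeros(1)
        for r in ranks:
            dist = np.concatenate([dist, dist + r])
        p = _two_sided_p(dist, w_plus, center)
        return TestResult("wilcoxon_signed_rank", w_plus, p, "exact")

    # normal approximation with tie correction
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var == 0:
        return TestResult("wilcoxon_signed_rank", w_plus, 1.0, "approximate")
    z = (abs(w_plus - center) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
    return TestResult("wilcoxon_signed_rank", w_plus, p, "approximate")


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> TestResult:
    """Two-sided Mann–Whitney U test for two independent samples.

    For min(n, m) ≤ ``exact_limit`` the exact null distribution of U over
    all C(n+m, n) equally likely labelings of the pooled (average-rank)
    values is computed by a subset-sum count recursion (polynomial in n+m,
    ties included); beyond the limit a tie-corrected normal approximation
    with continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[:n].sum())
    u1 = r1 - n * (n + 1) / 2.0
    center = n * m / 2.0

    if min(n, m) <= exact_limit:
        # counts[k, s]: subsets of size k with doubled-rank-sum s
        # (ranks doubled so tied average ranks stay integral)
        r2 = np.rint(2 * ranks).astype(int)
        max_sum = int(r2.sum())
        counts = np.zeros((n + 1, max_sum + 1))
        counts[0, 0] = 1.0
        for r in r2:
            for k in range(n, 0, -1):  # descending: each item used at most once
                counts[k, r:] += counts[k - 1, : max_sum + 1 - r]
        dist_counts = counts[n]
        sums = np.arange(max_sum + 1) / 2.0
        u_vals = sums - n * (n + 1) / 2.0
        mask = np.abs(u_vals - center) >= abs(u1 - center) - 1e-9
        p = float(dist_counts[mask].sum() / dist_counts.sum())
        return TestResult("mann_whitney_u", u1, p, "exact")

    N = n + m
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (N * (N - 1))
    var = n * m / 12.0 * (N + 1 - tie_term)
    if var == 0:
        return TestResult("mann_whitney_u", u1, 1.0, "approximate")
    z = (abs(u1 - center) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
    return TestResult("mann_whitney_u", u1, p, "approximate")


# ---------------------------------------------------------------------------
# I/O


def _lineage_to_levels(lineage: str) -> dict[str, str]:
    """Parse a semicolon lineage (phylum;class;family;genus) filling
    unclassified tails with 'unclassified <parent>'."""
    parts = [p.strip() for p in str(lineage).split(";")]
    out: dict[str, str] = {}
    parent = parts[0] if parts and parts[0] else "unknown"
    for i, lvl in enumerate(LINEAGE_LEVELS):
        name = parts[i] if i < len(parts) and parts[i] else ""
        if name:
            out[lvl] = name
            parent = name
        else:
            out[lvl] = f"unclassified {parent}"
    return out


def load_taxa_table(path: str | PathLike, meta_path: str | PathLike) -> TaxaTable:
    """Read a feature table (taxa as rows, samples as columns).

    First column: taxon id.  Optional ``taxonomy`` column holds the
    semicolon-joined lineage phylum;class;family;genus (missing tail
    levels become "unclassified <parent>").  ``meta_path`` is a delimited
    file keyed by sample id with columns group, sex, time_point, animal_id.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if "taxonomy" in df.columns:
        lineages = df.pop("taxonomy")
    else:
        lineages = pd.Series(df.index, index=df.index)
    counts = df.T
    counts = counts.astype(float).round().astype(int)
    counts.index.name = None
    counts.columns.name = None
    tax = pd.DataFrame(
        [_lineage_to_levels(lineages.loc[t]) for t in counts.columns],
        index=counts.columns,
    )
    meta = pd.read_csv(meta_path, sep=None, engine="python", index_col=0)
    meta = meta.reindex(counts.index)
    if meta.isna().all(axis=1).any():
        missing = list(meta.index[meta.isna().all(axis=1)])[:5]
        raise ValueError(f"samples without metadata: {missing}")
    return TaxaTable(counts=counts, taxonomy=tax, sample_meta=meta)


def write_taxa_table(table: TaxaTable, path: str | PathLike, meta_path: str | PathLike) -> None:
    """Write a TaxaTable back to the feature-table layout of
    :func:`load_taxa_table`."""
    df = table.counts.T.copy()
    df.insert(
        len(df.columns),
        "taxonomy",
        [";".join(table.taxonomy.loc[t, list(LINEAGE_LEVELS)]) for t in df.index],
    )
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")
    meta = table.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t")
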