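"""Differential-expression filtering on processed microarray-style signal matrices.

The expression substrate is a genes x samples matrix of linear-scale signals
with Affymetrix-style per-sample detection calls (Present / Absent / Marginal)
and a group label per sample.  Genes pass the differential-expression (DEG)
filter when three criteria hold simultaneously:

* mean fold change between group means at least ``min_abs_fc`` in magnitude,
* unpaired two-sided Welch t-test p-value at most ``max_p``,
* change-call concordance (fraction of all cross-group sample pairings that
  agree in direction with the gene's overall change) at least
  ``min_call_concordance``.

Fold changes are reported signed: ``mean_b/mean_a`` when up-regulated in group
B, ``-mean_a/mean_b`` when down-regulated, so a halving prints as -2 rather
than 0.5.  Benjamini-Hochberg q-values are computed and reported alongside raw
p-values; the primary filter uses raw p.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import pct_half_up

logger = logging.getLogger(__name__)

VALID_CALLS = frozenset({"P", "A", "M"})

#: categories of previously reported Myc relationships used by the
#: target-breakdown table: direct targets (T), relatives of targets (rT),
#: responsive genes (R), relatives of responsive genes (rR); anything
#: unannotated is "new".
CATEGORIES = ("T", "rT", "R", "rR", "new")


class ExpressionError(ValueError):
    """Raised for malformed expression inputs."""


@dataclass
class ExpressionMatrix:
    """Linear-scale signals plus detection calls and sample grouping.

    Parameters
    ----------
    signals : DataFrame
        genes x samples, non-negative linear-scale values.
    detection_calls : DataFrame
        Same shape/labels as ``signals``; entries in {P, A, M}.
    groups : mapping
        sample id -> group label; every sample must be assigned.
    """

    signals: pd.DataFrame
    detection_calls: pd.DataFrame
    groups: dict[str, str]
    all_absent_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        sig, calls = self.signals, self.detection_calls
        if not sig.index.equals(calls.index) or not sig.columns.equals(calls.columns):
            raise ExpressionError("signals and detection_calls are not aligned")
        if sig.index.has_duplicates:
            raise ExpressionError("duplicate gene ids")
        bad = sig.lt(0)
        if bad.any().any():
            g = sig.index[bad.any(axis=1)][0]
            raise ExpressionError(f"negative signal for gene {g!r}")
        for gene, sample in zip(*np.where(~calls.isin(VALID_CALLS))):
            raise ExpressionError(
                "unknown detection call "
                f"{calls.iat[gene, sample]!r} at gene {calls.index[gene]!r}, "
                f"sample {calls.columns[sample]!r}"
            )
        missing = set(sig.columns) - set(self.groups)
        if missing:
            raise ExpressionError(f"samples without group label: {sorted(missing)}")
        # genes called Absent everywhere are retained but flagged
        self.all_absent_genes = list(sig.index[(calls == "A").all(axis=1)])
        if self.all_absent_genes:
            logger.warning("%d gene(s) absent in every sample", len(self.all_absent_genes))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.signals.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.signals.columns)

    def group_samples(self, label: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == label]


@dataclass(frozen=True)
class DEGCriteria:
    """Thresholds of the DEG filter; ``direction`` restricts the sign."""

    min_abs_fc: float
    max_p: float
    min_call_concordance: float
    direction: str = "both"

    def __post_init__(self) -> None:
        if not self.min_abs_fc > 1:
            raise ExpressionError("min_abs_fc must exceed 1")
        if not 0 < self.max_p <= 1:
            raise ExpressionError("max_p must be in (0, 1]")
        if not 0 < self.min_call_concordance <= 1:
            raise ExpressionError("min_call_concordance must be in (0, 1]")
        if self.direction not in {"up", "down", "both"}:
            raise ExpressionError(f"unknown direction {self.direction!r}")


#: the stringent tumor-contrast profile: FC >= 3, p <= 0.05, 100% concordant calls
TUMOR_CRITERIA = DEGCriteria(min_abs_fc=3.0, max_p=0.05, min_call_concordance=1.0)
#: the relaxed non-tumor transgenic profile: FC >= 2.5, p <= 0.05, >= 87.5% concordance
TRANSGENIC_CRITERIA = DEGCriteria(min_abs_fc=2.5, max_p=0.05, min_call_concordance=0.875)


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    mean_fc: float
    p_value: float
    fdr_q: float
    call_concordance: float
    direction: str

    def __post_init__(self) -> None:
        if abs(self.mean_fc) < 1:
            raise ExpressionError("signed fold change magnitude below 1")
        if (self.mean_fc > 0) != (self.direction == "up"):
            raise ExpressionError("direction inconsistent with fold-change sign")


@dataclass(frozen=True)
class VennCounts:
    unique_a: int
    unique_b: int
    common: int


@dataclass
class CategoryBreakdown:
    """Per-category gene counts, site-bearing counts and percentages."""

    counts: dict[str, int]
    site_counts: dict[str, int]
    percentages: dict[str, float]
    total: int
    total_sites: int
    total_percentage: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c, self.counts[c], self.site_counts[c], self.percentages[c])
            for c in CATEGORIES
        ]
        rows.append(("total", self.total, self.total_sites, self.total_percentage))
        return pd.DataFrame(rows, columns=["category", "n_genes", "n_with_sites", "pct"])


def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def load_expression(
    signals_path: str | Path,
    calls_path: str | Path,
    groups_path: str | Path,
) -> ExpressionMatrix:
    """Load the signal matrix, the calls matrix and the sample-group table.

    All three are TSV; the matrices share the layout gene id in the first
    column, one column per sample.  The groups file has two columns
    (sample id, group label).
    """
    signals = _read_table(signals_path).astype(float)
    calls = _read_table(calls_path).astype(str)
    gdf = pd.read_csv(groups_path, sep="\t", header=None, comment="#", dtype=str)
    if list(gdf.iloc[0]) == ["sample_id", "group"]:  # optional header row
        gdf = gdf.iloc[1:]
    groups = dict(zip(gdf.iloc[:, 0], gdf.iloc[:, 1]))
    return ExpressionMatrix(signals=signals, detection_calls=calls, groups=groups)


def signed_fold_change(mean_a: float, mean_b: float) -> float:
    """Signed ratio convention: b/a when >= 1, else -(a/b)."""
    ratio = mean_b / mean_a
    return ratio if ratio >= 1 else -1.0 / ratio


def pairwise_concordance(a: np.ndarray, b: np.ndarray, up: bool) -> float:
    """Fraction of all (a_i, b_j) sample pairings changed in the stated direction."""
    diffs = b[None, :] - a[:, None]
    agree = diffs > 0 if up else diffs < 0
    return float(agree.mean())


def compute_deg(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    criteria: DEGCriteria,
) -> list[DEGRecord]:
    """Apply the three-part DEG filter to the contrast group_a -> group_b.

    Returns one record per passing gene.  Genes with a zero denominator mean or
    with zero within-group variance in both groups are skipped with a warning
    (fold change / p-value undefined).
    """
    samples_a = expr.group_samples(group_a)
    samples_b = expr.group_samples(group_b)
    for label, ss in ((group_a, samples_a), (group_b, samples_b)):
        if len(ss) < 2:
            raise ExpressionError(f"group {label!r} has fewer than 2 samples")

    A = expr.signals[samples_a].to_numpy(float)
    B = expr.signals[samples_b].to_numpy(float)
    genes = expr.gene_ids

    rows: list[tuple[str, float, float, float, str]] = []
    for i, gene in enumerate(genes):
        a, b = A[i], B[i]
        ma, mb = a.mean(), b.mean()
        if ma == 0 or mb == 0:
            warnings.warn(f"gene {gene!r} skipped: zero group mean", stacklevel=2)
            continue
        if a.var() == 0 and b.var() == 0:
            warnings.warn(f"gene {gene!r} skipped: zero variance in both groups", stacklevel=2)
            continue
        fc = signed_fold_change(ma, mb)
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        conc = pairwise_concordance(a, b, up=fc > 0)
        rows.append((gene, fc, p, conc, "up" if fc > 0 else "down"))

    if not rows:
        return []
    qvals = multipletests([r[2] for r in rows], method="fdr_bh")[1]

    out = []
    for (gene, fc, p, conc, direction), q in zip(rows, qvals):
        if abs(fc) < criteria.min_abs_fc:
            continue
        if p > criteria.max_p:
            continue
        if conc < criteria.min_call_concordance:
            continue
        if criteria.direction != "both" and direction != criteria.direction:
            continue
        out.append(DEGRecord(gene, fc, p, float(q), conc, direction))
    return out


def deg_table(records: Sequence[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.mean_fc, r.p_value, r.fdr_q, r.call_concordance, r.direction) for r in records],
        columns=["gene_id", "mean_fc", "p_value", "fdr_q", "call_concordance", "direction"],
    )


def compare_deg_sets(set_a: Iterable[str], set_b: Iterable[str]) -> VennCounts:
    """Two-set Venn counts (unique to A, unique to B, common)."""
    sa, sb = set(set_a), set(set_b)
    common = len(sa & sb)
    return VennCounts(len(sa) - common, len(sb) - common, common)


def categorize_targets(
    degs: Sequence[DEGRecord] | Sequence[str],
    known_targets: Mapping[str, str],
    site_bearing: Iterable[str],
) -> CategoryBreakdown:
    """Break a DEG list into known-target categories with binding-site percentages.

    ``known_targets`` maps gene -> one of T/rT/R/rR (direct targets, their
    relatives, responsive genes, their relatives); unannotated genes are
    counted as "new".  Percentages are the share of each category's genes that
    carry at least one Myc binding site, rounded half-up to one decimal.
    """
    bad = set(known_targets.values()) - set(CATEGORIES[:4])
    if bad:
        raise ExpressionError(f"unknown target categories: {sorted(bad)}")
    gene_ids = [d.gene_id if isinstance(d, DEGRecord) else d for d in degs]
    if not gene_ids:
        warnings.warn("empty DEG list: zero breakdown", stacklevel=2)
    sites = set(site_bearing)

    counts = {c: 0 for c in CATEGORIES}
    site_counts = {c: 0 for c in CATEGORIES}
    for g in gene_ids:
        cat = known_targets.get(g, "new")
        counts[cat] += 1
        if g in sites:
            site_counts[cat] += 1
    percentages = {c: pct_half_up(site_counts[c], counts[c], 1) for c in CATEGORIES}
    total = sum(counts.values())
    total_sites = sum(site_counts.values())
    return CategoryBreakdown(
        counts=counts,
        site_counts=site_counts,
        percentages=percentages,
        total=total,
        total_sites=total_sites,
        total_percentage=pct_half_up(total_sites, total, 1),
    )


def breakdown_from_counts(
    counts: Mapping[str, int], site_counts: Mapping[str, int]
) -> CategoryBreakdown:
    """Build a CategoryBreakdown directly from printed per-category counts."""
    counts = {c: int(counts.get(c, 0)) for c in CATEGORIES}
    site_counts = {c: int(site_counts.get(c, 0)) for c in CATEGORIES}
    for c in CATEGORIES:
        if site_counts[c] > counts[c]:
            raise ExpressionError(f"category {c}: site-bearing count exceeds gene count")
    total = sum(counts.values())
    total_sites = sum(site_counts.values())
    return CategoryBreakdown(
        counts=counts,
        site_counts=site_counts,
        percentages={c: pct_half_up(site_counts[c], counts[c], 1) for c in CATEGORIES},
        total=total,
        total_sites=total_sites,
        total_percentage=pct_half_up(total_sites, total, 1),
    )


# convenient alias for the background ("NO"-set) filter used when defining the
# unregulated gene universe: |log2 FC| > 0.5 and -log10 p > 3 marks a gene as
# regulated and hence removed from the background.
def is_background_gene(log2_fc: float, p_value: float) -> bool:
    neglog10p = -np.log10(p_value) if p_value > 0 else np.inf
    return not (abs(log2_fc) > 0.5 and neglog10p > 3)
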