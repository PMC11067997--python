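"""Z-chromosome dosage-compensation analysis on expression tables.

Works on a gene x sample abundance matrix (TPM-like, length-scaled) with a
chromosome class per gene (A = autosomal, Z = Z-linked) and a zygosity class
per sample (hem = hemizygous female, het = heterozygous male, hom =
homozygous male). Proper male-mode compensation keeps the Z:A median ratio
similar in hem and het samples; failed compensation in homozygotes shows up
as an elevated Z:A ratio and an elevated hom/hem relative expression for
Z-linked genes.

Gene-level summaries take the mean over replicate samples within a class
before medians are taken across genes; ratios with a zero denominator are
excluded (and counted) rather than treated as infinite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedStatisticError, ValidationError

__all__ = [
    "ExpressionTable",
    "ZaSummary",
    "filter_expression",
    "za_medians",
    "pairwise_relative_expression",
    "wilcoxon_za",
    "za_cutoff_sweep",
]

_CLASSES = ("hem", "het", "hom")


@dataclass
class ExpressionTable:
    """Gene x sample abundances with chromosome and zygosity classes."""

    values: pd.DataFrame  # genes x samples, nonnegative
    gene_class: pd.Series  # gene -> "A" | "Z"
    sample_class: pd.Series  # sample -> "hem" | "het" | "hom"

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            bad = self.values.index[(self.values < 0).any(axis=1)][0]
            raise ValidationError(f"negative abundance for gene {bad!r}")
        missing = set(self.values.index) - set(self.gene_class.index)
        if missing:
            raise ValidationError(f"genes without chromosome class: {sorted(missing)[:5]}")
        missing = set(self.values.columns) - set(self.sample_class.index)
        if missing:
            raise ValidationError(f"samples without zygosity class: {sorted(missing)[:5]}")
        bad = set(self.gene_class.loc[self.values.index]) - {"A", "Z"}
        if bad:
            raise ValidationError(f"unknown gene classes: {sorted(bad)}")
        bad = set(self.sample_class.loc[self.values.columns]) - set(_CLASSES)
        if bad:
            raise ValidationError(f"unknown sample classes: {sorted(bad)}")

    @property
    def n_genes(self) -> dict[str, int]:
        gc = self.gene_class.loc[self.values.index]
        return {"A": int((gc == "A").sum()), "Z": int((gc == "Z").sum())}

    def replicate_counts(self) -> dict[str, int]:
        sc = self.sample_class.loc[self.values.columns]
        return {c: int((sc == c).sum()) for c in _CLASSES}

    def class_means(self) -> pd.DataFrame:
        """Per-gene mean abundance within each zygosity class."""
        sc = self.sample_class.loc[self.values.columns]
        return self.values.T.groupby(sc.values).mean().T


def filter_expression(
    table: ExpressionTable, min_abund: float = 1.0, min_samples: int = 3
) -> ExpressionTable:
    """Keep genes strictly above ``min_abund`` in at least ``min_samples`` samples."""
    if min_abund < 0 or min_samples < 0:
        raise ValidationError("thresholds must be nonnegative")
    keep = (table.values > min_abund).sum(axis=1) >= min_samples
    return ExpressionTable(
        values=table.values.loc[keep],
        gene_class=table.gene_class,
        sample_class=table.sample_class,
    )


@dataclass
class ZaSummary:
    """Per-class medians, Z:A ratios and rank-sum tests."""

    median_a: dict[str, float]
    median_z: dict[str, float]
    za_ratio: dict[str, float]
    n_genes: dict[str, int]
    wilcoxon: dict[str, dict] = field(default_factory=dict)


def za_medians(table: ExpressionTable) -> ZaSummary:
    """Median A and Z expression per zygosity class and the Z:A ratios.

    Per gene, replicate samples within a class are averaged first; the
    median is then taken across genes, separately for autosomal and
    Z-linked sets.
    """
    gc = table.gene_class.loc[table.values.index]
    if (gc == "A").sum() == 0 or (gc == "Z").sum() == 0:
        raise UndefinedStatisticError("need at least one gene in each of A and Z")
    means = table.class_means()
    med_a: dict[str, float] = {}
    med_z: dict[str, float] = {}
    ratio: dict[str, float] = {}
    for c in means.columns:
        med_a[c] = float(means.loc[gc == "A", c].median())
        med_z[c] = float(means.loc[gc == "Z", c].median())
        if med_a[c] == 0:
            raise UndefinedStatisticError(f"zero autosomal median in class {c!r}")
        ratio[c] = med_z[c] / med_a[c]
    return ZaSummary(median_a=med_a, median_z=med_z, za_ratio=ratio, n_genes=table.n_genes)


def pairwise_relative_expression(
    table: ExpressionTable, class1: str, class2: str
) -> dict:
    """Per-gene expression ratio class1/class2 for A and Z genes separately.

    Genes with zero mean in the denominator class are excluded from the
    distributions; the exclusion count is reported.
    """
    for c in (class1, class2):
        if c not in _CLASSES:
            raise ValidationError(f"unknown zygosity class {c!r}")
    counts = table.replicate_counts()
    if counts[class1] < 1 or counts[class2] < 1:
        raise ValidationError(f"both classes need >= 1 replicate: {counts}")
    means = table.class_means()
    gc = table.gene_class.loc[table.values.index]
    nonzero = means[class2] > 0
    ratios = means.loc[nonzero, class1] / means.loc[nonzero, class2]
    out = {
        "class1": class1,
        "class2": class2,
        "excluded_zero_denominator": int((~nonzero).sum()),
        "ratios_a": ratios[gc.loc[ratios.index] == "A"],
        "ratios_z": ratios[gc.loc[ratios.index] == "Z"],
    }
    out["median_a"] = float(out["ratios_a"].median())
    out["median_z"] = float(out["ratios_z"].median())
    return out


def wilcoxon_za(ratios_a, ratios_z, m_tests: int = 3) -> dict:
    """Two-sample rank-sum test of A vs Z log2-ratio distributions.

    Bonferroni adjustment with ``m_tests`` (default 3, one per zygosity
    pair comparison).
    """
    a = np.log2(np.asarray(ratios_a, dtype=float))
    z = np.log2(np.asarray(ratios_z, dtype=float))
    a = a[np.isfinite(a)]
    z = z[np.isfinite(z)]
    if a.size < 3 or z.size < 3:
        raise ValidationError("need >= 3 finite values per group")
    stat, p = stats.mannwhitneyu(z, a, alternative="two-sided")
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "p_adjusted": min(1.0, m_tests * float(p)),
        "m_tests": m_tests,
    }


def za_cutoff_sweep(
    table: ExpressionTable,
    min_samples_grid=range(1, 13),
    min_abund_grid=(0.0, 1.0, 2.0),
) -> pd.DataFrame:
    """Z:A median ratios per zygosity class over a filtering-cutoff grid.

    Returns a long-format frame with columns min_abund, min_samples,
    n_genes_a, n_genes_z and one ratio column per class present.
    """
    min_samples_grid = list(min_samples_grid)
    min_abund_grid = list(min_abund_grid)
    if not min_samples_grid or not min_abund_grid:
        raise ValidationError("cutoff grids must be nonempty")
    rows = []
    for ab in min_abund_grid:
        for ms in min_samples_grid:
            sub = filter_expression(table, min_abund=ab, min_samples=ms)
            row = {"min_abund": ab, "min_samples": ms}
            row["n_genes_a"] = sub.n_genes["A"]
            row["n_genes_z"] = sub.n_genes["Z"]
            try:
                summary = za_medians(sub)
                for c, r in summary.za_ratio.items():
                    row[f"za_{c}"] = r
            except UndefinedStatisticError:
                pass
            rows.append(row)
    return pd.DataFrame(rows)
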