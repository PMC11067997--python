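"""Genetic models and tests for the zygosity-based sex determination rule.

Covers: expected offspring class proportions for supported crosses,
classification of individuals from molecular markers (W presence, number of
distinct alleles, Z dose), Mendelian segregation goodness-of-fit,
Hardy-Weinberg homozygote-deficit testing, the exact test for W-linked
marker segregation, and the knockdown contingency test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidCrossError, UndefinedStatisticError, ValidationError
from .simcore import Individual

__all__ = [
    "ZygoteClass",
    "CrossExpectation",
    "expected_offspring",
    "classify_individual",
    "SegregationResult",
    "segregation_chisq",
    "hw_homozygote_deficit",
    "fisher_exact_2x2",
    "knockdown_contingency",
]


@dataclass(frozen=True)
class ZygoteClass:
    """One offspring class: karyotype, genotype, expected share, viability."""

    karyotype: str
    alleles: tuple[str, ...]
    proportion: float
    viable: bool

    @property
    def label(self) -> str:
        if len(self.alleles) == 1:
            kind = "hem"
        elif self.alleles[0] == self.alleles[1]:
            kind = "hom"
        else:
            kind = "het"
        return f"{self.karyotype}-{kind}:{'/'.join(self.alleles)}"


@dataclass(frozen=True)
class CrossExpectation:
    classes: tuple[ZygoteClass, ...]

    @property
    def inviable_fraction(self) -> float:
        return sum(c.proportion for c in self.classes if not c.viable)

    def proportions(self) -> dict[str, float]:
        return {c.label: c.proportion for c in self.classes}


def expected_offspring(mother: Individual, father: Individual) -> CrossExpectation:
    """Offspring class table for a WZ or Z0 mother crossed to a ZZ male.

    Segregation is equal on both sides: a WZ mother transmits W or her Z
    allele with probability 1/2 each; a Z0 mother transmits her Z or a
    nullo-Z egg with probability 1/2 each (the unpaired Z univalent is
    assumed to segregate randomly); the father transmits either allele with
    probability 1/2. ZZ zygotes with identical alleles are inviable.
    """
    if mother.karyotype not in {"WZ", "Z0"} or len(mother.alleles) != 1:
        raise InvalidCrossError(f"unsupported mother: {mother.karyotype} {mother.alleles}")
    if father.karyotype != "ZZ" or father.sex != "male":
        raise InvalidCrossError(f"unsupported father: {father.karyotype} {father.alleles}")
    (m,) = mother.alleles
    f1, f2 = father.alleles
    fem_karyo = "WZ" if mother.karyotype == "WZ" else "Z0"

    buckets: dict[tuple[str, tuple[str, ...]], float] = {}
    for pat in (f1, f2):  # sperm, 1/2 each
        # egg with W (or nullo for Z0): daughter carries the paternal allele
        key = (fem_karyo, (pat,))
        buckets[key] = buckets.get(key, 0.0) + 0.25
        # egg with maternal Z: ZZ son (or inviable homozygote)
        zz = tuple(sorted((m, pat)))
        key = ("ZZ", zz)
        buckets[key] = buckets.get(key, 0.0) + 0.25

    classes = tuple(
        ZygoteClass(
            karyotype=k,
            alleles=a,
            proportion=p,
            viable=not (len(a) == 2 and a[0] == a[1]),
        )
        for (k, a), p in sorted(buckets.items())
    )
    total = sum(c.proportion for c in classes)
    assert abs(total - 1.0) < 1e-12
    return CrossExpectation(classes=classes)


def classify_individual(
    w_present: bool | None, n_distinct_alleles: int, z_dose: int | None = None
) -> str:
    """Sex/viability class from molecular markers.

    Decision table: (W, 1 allele) -> WZ-female; (W, 2) -> WZZ-male;
    (no W, 2) -> ZZ-het-male; (no W, 1, dose 1) -> Z0-female;
    (no W, 1, dose 2) -> ZZ-hom-inviable; insufficient inputs -> ambiguous.
    """
    if n_distinct_alleles not in (1, 2):
        raise ValidationError(f"n_distinct_alleles must be 1 or 2, got {n_distinct_alleles}")
    if z_dose is not None and z_dose not in (1, 2):
        raise ValidationError(f"z_dose must be 1, 2 or None, got {z_dose}")
    if w_present is None:
        return "ambiguous"
    if w_present:
        return "WZ-female" if n_distinct_alleles == 1 else "WZZ-male"
    if n_distinct_alleles == 2:
        return "ZZ-het-male"
    if z_dose == 1:
        return "Z0-female"
    if z_dose == 2:
        return "ZZ-hom-inviable"
    return "ambiguous"


@dataclass(frozen=True)
class SegregationResult:
    chisq: float
    df: int
    p_value: float
    violations: tuple[str, ...]  # classes with expectation 0 but observations > 0


def segregation_chisq(
    observed: dict[str, int], expectation: CrossExpectation, n_total: int | None = None
) -> SegregationResult:
    """Pearson goodness-of-fit of observed class counts to a cross expectation.

    Classes with expected proportion zero are treated as hard constraints of
    the genetic rule: nonzero observations there are reported as violations
    rather than absorbed into the chi-square.
    """
    props = expectation.proportions()
    violations = tuple(
        sorted(lab for lab, n in observed.items() if n > 0 and props.get(lab, 0.0) == 0.0)
    )
    labels = [lab for lab, p in props.items() if p > 0.0]
    obs = np.array([observed.get(lab, 0) for lab in labels], dtype=float)
    if n_total is None:
        n_total = int(obs.sum())
    if n_total == 0:
        raise UndefinedStatisticError("no observations in classes with positive expectation")
    exp = np.array([props[lab] for lab in labels]) * n_total
    chisq, p = stats.chisquare(obs, exp)
    return SegregationResult(
        chisq=float(chisq), df=len(labels) - 1, p_value=float(p), violations=violations
    )


def hw_homozygote_deficit(
    female_freqs: dict[str, float] | np.ndarray,
    n_males: int,
    observed_hom: int,
) -> dict:
    """Test the observed homozygote/heterozygote split in adult males against
    Hardy-Weinberg expectation, with allele frequencies estimated from
    females (where every allele is directly observable on the single Z).

    Expected homozygote proportion is sum(p_i^2). Returns the expected
    homozygote count, chi-square (df=1), p-value, and an ``underpowered``
    flag when the expected count is below 1.
    """
    p = np.asarray(
        list(female_freqs.values()) if isinstance(female_freqs, dict) else female_freqs,
        dtype=float,
    )
    if p.size == 0 or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValidationError("allele frequencies must sum to 1")
    if n_males <= 0:
        raise ValidationError("n_males must be positive")
    if not 0 <= observed_hom <= n_males:
        raise ValidationError("observed_hom outside [0, n_males]")
    p_hom = float(np.sum(p**2))
    expected_hom = p_hom * n_males
    obs = np.array([observed_hom, n_males - observed_hom], dtype=float)
    exp = np.array([expected_hom, n_males - expected_hom])
    if expected_hom == 0.0:
        chisq, pval = 0.0, 1.0
    else:
        chisq, pval = (float(x) for x in stats.chisquare(obs, exp))
    return {
        "expected_hom": expected_hom,
        "expected_hom_proportion": p_hom,
        "observed_hom": observed_hom,
        "chisq": chisq,
        "p_value": pval,
        "underpowered": expected_hom < 1.0,
    }


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Two-sided probability is the sum of hypergeometric point probabilities
    not exceeding that of the observed table (the standard definition; for
    complete sex-linked segregation of a marker in 8 daughters vs 8 sons
    this gives 2/12870 ~ 0.000155).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("table must be 2x2 with nonnegative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise UndefinedStatisticError("Fisher exact test undefined with a zero margin")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def knockdown_contingency(
    control: tuple[int, int], treated: tuple[int, int], *, yates: bool = False
) -> dict:
    """Pearson chi-square comparing success proportions in two groups.

    ``control`` and ``treated`` are (successes, total). The default applies
    no continuity correction; set ``yates=True`` for the corrected variant.
    """
    (s1, n1), (s2, n2) = control, treated
    if n1 <= 0 or n2 <= 0 or not (0 <= s1 <= n1 and 0 <= s2 <= n2):
        raise ValidationError("totals must be positive and successes within totals")
    table = np.array([[s1, n1 - s1], [s2, n2 - s2]])
    chisq, p, df, _ = stats.chi2_contingency(table, correction=yates)
    return {"chisq": float(chisq), "df": int(df), "p_value": float(p)}
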