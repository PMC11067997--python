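"""Forward simulator of zygosity-based sex determination.

The model: sex is set by the zygosity of a single Z-linked locus. Zygotes
carrying one allele (WZ or Z0 karyotype) develop as females, zygotes carrying
two *distinct* alleles (ZZ) develop as males, and zygotes homozygous for the
locus die as embryos. Homozygote lethality generates negative
frequency-dependent balancing selection: rare alleles are favoured, and
equilibrium allele frequencies approach 1/k for k alleles.

Alleles are concrete coding haplotypes: a conserved exon-8 flank, a
hypervariable region (HVR) of 7-24 residues drawn from a restricted
amino-acid alphabet encoded by ANT/NAT codons, and a polymorphic exon 9.
Mutation acts by single-codon HVR slippage (expansion/contraction), HVR
point substitution within the ANT/NAT codon set, and nonsynonymous point
substitution in exon 9.

The simulator also generates brood outcome tables (Mendelian segregation
with homozygotes flagged as inviable "black eggs") and gene-expression
matrices in which homozygotes fail male-mode dosage compensation, so that
every downstream analysis module can be exercised on data with known truth.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from ._codons import CODON_TO_AA, NUCLEOTIDES, STOP_CODONS, translate
from .errors import InvalidConfigError, InvalidCrossError, ValidationError

__all__ = [
    "HVR_CODONS",
    "HVR_RESIDUES",
    "HaplotypeRecord",
    "SimConfig",
    "Individual",
    "BroodRecord",
    "SimState",
    "generate_founder_alleles",
    "mutate_haplotype",
    "simulate_population",
    "simulate_brood",
    "simulate_expression_matrix",
]

#: Codons used inside the HVR. All match the ANT or NAT pattern; together
#: they encode N, H, S and Y. Trp (also seen in real HVRs) is encoded only
#: by TGG, which breaks the ANT/NAT pattern, so it is accepted on input but
#: never generated.
HVR_CODONS: tuple[str, ...] = ("AAT", "CAT", "AGT", "TAT")

#: Amino acids permitted inside the HVR.
HVR_RESIDUES: frozenset[str] = frozenset("NHSWY")

_E8_FLANK_CODONS = 20
_E9_CODONS = 97


def _is_ant_or_nat(codon: str) -> bool:
    return codon[2] == "T" and (codon[0] == "A" or codon[1] == "A")


@dataclass(frozen=True)
class HaplotypeRecord:
    """One allele of the sex locus: an E8-HVR-E9 coding haplotype.

    ``hvr_span`` is a half-open interval in codon units into ``nt_seq``.
    """

    allele_id: str
    nt_seq: str
    hvr_span: tuple[int, int]
    population: str | None = None

    @property
    def aa_seq(self) -> str:
        return translate(self.nt_seq)

    @property
    def hvr_nt(self) -> str:
        return self.nt_seq[self.hvr_span[0] * 3 : self.hvr_span[1] * 3]

    @property
    def hvr_aa(self) -> str:
        return self.aa_seq[self.hvr_span[0] : self.hvr_span[1]]

    @property
    def hvr_len(self) -> int:
        return self.hvr_span[1] - self.hvr_span[0]

    def validate(self, hvr_len_bounds: tuple[int, int] = (7, 24)) -> None:
        """Raise :class:`ValidationError` on any structural violation."""
        if len(self.nt_seq) % 3:
            raise ValidationError(
                f"{self.allele_id}: length {len(self.nt_seq)} not a codon multiple"
            )
        n_codons = len(self.nt_seq) // 3
        lo, hi = self.hvr_span
        if not (0 <= lo <= hi <= n_codons):
            raise ValidationError(f"{self.allele_id}: hvr_span {self.hvr_span} out of range")
        lo_b, hi_b = hvr_len_bounds
        if not (lo_b <= hi - lo <= hi_b):
            raise ValidationError(
                f"{self.allele_id}: HVR length {hi - lo} outside bounds {hvr_len_bounds}"
            )
        for i in range(lo, hi):
            codon = self.nt_seq[i * 3 : i * 3 + 3]
            aa = CODON_TO_AA.get(codon)
            if aa not in HVR_RESIDUES:
                raise ValidationError(
                    f"{self.allele_id}: HVR codon {i} ({codon}) encodes {aa!r}, "
                    f"outside {{N,H,S,W,Y}}"
                )
            if not _is_ant_or_nat(codon):
                raise ValidationError(
                    f"{self.allele_id}: HVR codon {i} ({codon}) does not match ANT/NAT"
                )
        if "*" in self.aa_seq[:-1]:
            raise ValidationError(f"{self.allele_id}: internal stop codon")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the forward simulation.

    Rates are per generation: ``mu_point`` per HVR codon, ``mu_e9`` per
    exon-9 codon, ``mu_slip`` per transmitted allele copy. ``z0_rate`` is the
    probability that a W-bearing egg loses its W and yields a Z0 female
    (wild frequency ~0.4%).
    """

    n_females: int = 500
    n_males: int = 500
    k: int = 18
    mu_point: float = 1e-4
    mu_slip: float = 1e-3
    mu_e9: float = 1e-5
    hvr_len_bounds: tuple[int, int] = (7, 24)
    z0_rate: float = 0.004
    generations: int = 100
    seed: int = 0
    brood_size: int = 40

    def __post_init__(self) -> None:
        for name in ("mu_point", "mu_slip", "mu_e9", "z0_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} outside [0, 1]")
        if self.k < 2:
            raise InvalidConfigError(f"k={self.k}: at least 2 founder alleles required")
        lo, hi = self.hvr_len_bounds
        if not (1 <= lo <= hi <= 64):
            raise InvalidConfigError(f"hvr_len_bounds={self.hvr_len_bounds} outside [1, 64]")
        if min(self.n_females, self.n_males, self.generations, self.brood_size) < 1:
            raise InvalidConfigError("population sizes, generations and brood_size must be >= 1")


@dataclass(frozen=True)
class Individual:
    """A (possibly inviable) zygote or adult.

    Sex is derived from the alleles: one allele -> female, two distinct ->
    male, two identical -> inviable.
    """

    karyotype: str  # WZ | Z0 | ZZ | WZZ
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.karyotype not in {"WZ", "Z0", "ZZ", "WZZ"}:
            raise ValidationError(f"unknown karyotype {self.karyotype!r}")
        n = len(self.alleles)
        if self.karyotype in {"WZ", "Z0"} and n != 1:
            raise ValidationError(f"{self.karyotype} requires exactly 1 allele, got {n}")
        if self.karyotype in {"ZZ", "WZZ"} and n != 2:
            raise ValidationError(f"{self.karyotype} requires exactly 2 alleles, got {n}")

    @property
    def sex(self) -> str:
        if len(self.alleles) == 1:
            return "female"
        return "inviable" if self.alleles[0] == self.alleles[1] else "male"

    @property
    def zygosity(self) -> str:
        """hem (one allele), het (two distinct) or hom (two identical)."""
        if len(self.alleles) == 1:
            return "hem"
        return "hom" if self.alleles[0] == self.alleles[1] else "het"


#: Zygote classes produced by supported crosses.
ZYGOTE_CLASSES = ("WZ-hem", "Z0-hem", "ZZ-het", "ZZ-hom")


@dataclass
class BroodRecord:
    """Egg-category counts for one brood."""

    mother: Individual
    father: Individual
    n_eggs: int
    class_counts: dict[str, int]
    hatched: int
    black_egg: int
    white_egg: int = 0
    collapsed: int = 0

    def validate(self) -> None:
        if sum(self.class_counts.values()) != self.n_eggs:
            raise ValidationError("zygote class counts do not sum to egg total")
        if self.hatched + self.black_egg + self.white_egg + self.collapsed != self.n_eggs:
            raise ValidationError("outcome counts do not sum to egg total")


@dataclass
class SimState:
    """Result of a forward simulation.

    ``generation_counts`` holds, per generation, allele-copy counts over all
    adults (females contribute one copy, males two). ``inviable_fraction``
    is the realised fraction of zygotes discarded as homozygous each
    generation.
    """

    config: SimConfig
    registry: dict[str, HaplotypeRecord]
    generation_counts: list[Counter]
    inviable_fraction: list[float]
    females: list[Individual] = field(default_factory=list)
    males: list[Individual] = field(default_factory=list)
    extinct: bool = False
    extinct_generation: int | None = None

    @property
    def final_counts(self) -> Counter:
        return self.generation_counts[-1]


# ---------------------------------------------------------------------------
# haplotype generation and mutation


def _random_sense_codon(rng: np.random.Generator) -> str:
    while True:
        codon = "".join(rng.choice(list(NUCLEOTIDES), size=3))
        if codon not in STOP_CODONS:
            return codon


def generate_founder_alleles(
    k: int, config: SimConfig | None = None, rng: np.random.Generator | None = None
) -> list[HaplotypeRecord]:
    """Draw ``k`` mutually distinct (at amino-acid level) founder haplotypes.

    All founders share conserved E8/E9 backbone sequences (drawn once per
    call) and differ in HVR length/composition and at a handful of exon-9
    replacement sites, mimicking a sample where diversity concentrates in
    the HVR and exon 9.
    """
    if k < 2:
        raise InvalidConfigError(f"k={k}: at least 2 founder alleles required")
    if config is None:
        config = SimConfig(k=max(k, 2))
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.hvr_len_bounds

    e8 = "".join(_random_sense_codon(rng) for _ in range(_E8_FLANK_CODONS))
    e9_base = [_random_sense_codon(rng) for _ in range(_E9_CODONS)]

    records: list[HaplotypeRecord] = []
    seen_aa: set[str] = set()
    attempts = 0
    while len(records) < k:
        attempts += 1
        if attempts > 100 * k:
            raise InvalidConfigError("could not generate k distinct founder alleles")
        hvr_len = int(rng.integers(lo, hi + 1))
        hvr = "".join(rng.choice(HVR_CODONS, size=hvr_len))
        e9 = list(e9_base)
        for pos in rng.choice(_E9_CODONS, size=6, replace=False):
            e9[pos] = _nonsyn_variant(e9_base[pos], rng)
        nt = e8 + hvr + "".join(e9)
        rec = HaplotypeRecord(
            allele_id=f"A{len(records):03d}",
            nt_seq=nt,
            hvr_span=(_E8_FLANK_CODONS, _E8_FLANK_CODONS + hvr_len),
        )
        if rec.aa_seq in seen_aa:
            continue
        seen_aa.add(rec.aa_seq)
        records.append(rec)
    return records


def _nonsyn_variant(codon: str, rng: np.random.Generator) -> str:
    """A random single-nucleotide nonsynonymous (non-stop) neighbour."""
    aa = CODON_TO_AA[codon]
    choices = []
    for pos in range(3):
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in CODON_TO_AA and CODON_TO_AA[mutant] != aa:
                choices.append(mutant)
    return choices[int(rng.integers(len(choices)))]


def mutate_haplotype(
    h: HaplotypeRecord, config: SimConfig, rng: np.random.Generator
) -> HaplotypeRecord:
    """Apply one generation of mutation to a transmitted allele copy.

    Slippage (rate ``mu_slip`` per copy) duplicates or deletes one random
    HVR codon; draws that would cross the configured length bounds are
    rejected (no-op), so a bell-shaped length distribution emerges from the
    stepwise walk. HVR point mutation (rate ``mu_point`` per HVR codon)
    replaces a codon with a different member of the ANT/NAT set. Exon-9
    mutation (rate ``mu_e9`` per codon) applies a nonsynonymous
    single-nucleotide change. With all rates zero the input is returned
    unchanged.
    """
    lo_b, hi_b = config.hvr_len_bounds
    lo, hi = h.hvr_span
    codons = [h.nt_seq[i * 3 : i * 3 + 3] for i in range(len(h.nt_seq) // 3)]
    changed = False

    if config.mu_slip > 0 and rng.random() < config.mu_slip:
        expand = bool(rng.integers(2))
        length = hi - lo
        if expand and length < hi_b:
            idx = lo + int(rng.integers(length))
            codons.insert(idx, codons[idx])
            hi += 1
            changed = True
        elif not expand and length > lo_b:
            idx = lo + int(rng.integers(length))
            del codons[idx]
            hi -= 1
            changed = True
        # draw rejected at the bound: no-op

    if config.mu_point > 0:
        for i in range(lo, hi):
            if rng.random() < config.mu_point:
                alts = [c for c in HVR_CODONS if c != codons[i]]
                codons[i] = alts[int(rng.integers(len(alts)))]
                changed = True

    if config.mu_e9 > 0:
        for i in range(hi, len(codons)):
            if rng.random() < config.mu_e9:
                codons[i] = _nonsyn_variant(codons[i], rng)
                changed = True

    if not changed:
        return h
    return replace(h, nt_seq="".join(codons), hvr_span=(lo, hi))


# ---------------------------------------------------------------------------
# population simulation


class _Registry:
    """Allele bookkeeping: identity is amino-acid identity."""

    def __init__(self) -> None:
        self.records: dict[str, HaplotypeRecord] = {}
        self._by_aa: dict[str, str] = {}
        self._next = 0

    def add(self, rec: HaplotypeRecord) -> str:
        aa = rec.aa_seq
        if aa in self._by_aa:
            return self._by_aa[aa]
        if rec.allele_id in self.records:
            rec = replace(rec, allele_id=f"A{len(self.records):03d}n{self._next}")
            self._next += 1
        self.records[rec.allele_id] = rec
        self._by_aa[aa] = rec.allele_id
        return rec.allele_id


def simulate_population(config: SimConfig, *, max_rounds: int = 50) -> SimState:
    """Run the forward simulation under the zygosity rule.

    Discrete non-overlapping generations, random mating, equal fecundity.
    Each generation, zygotes are drawn (mother, father, segregation) until
    the female and male quotas are filled; homozygous ZZ zygotes are
    discarded before adulthood. If no viable zygote can be produced the
    state is returned with ``extinct=True`` rather than raising.
    """
    rng = np.random.default_rng(config.seed)
    registry = _Registry()
    founders = generate_founder_alleles(config.k, config, rng)
    ids = [registry.add(f) for f in founders]

    nF, nM = config.n_females, config.n_males
    # founder adults: uniform allele draws; males forced heterozygous
    fem_alleles = [str(a) for a in rng.choice(ids, size=nF)]
    fem_karyo = ["WZ"] * nF
    male_pairs = []
    while len(male_pairs) < nM:
        a, b = (str(x) for x in rng.choice(ids, size=2))
        if a != b:
            male_pairs.append((a, b))

    per_copy_rate = (
        config.mu_slip
        + config.mu_point * config.hvr_len_bounds[1]
        + config.mu_e9 * _E9_CODONS
    )

    generation_counts: list[Counter] = []
    inviable_fraction: list[float] = []

    def record_counts() -> None:
        c: Counter = Counter(fem_alleles)
        for a, b in male_pairs:
            c[a] += 1
            c[b] += 1
        generation_counts.append(c)

    record_counts()
    inviable_fraction.append(0.0)

    extinct = False
    extinct_at: int | None = None
    for gen in range(1, config.generations + 1):
        new_fem: list[tuple[str, str]] = []  # (karyotype, allele)
        new_male: list[tuple[str, str]] = []
        zygotes = 0
        inviable = 0
        rounds = 0
        while (len(new_fem) < nF or len(new_male) < nM) and rounds < max_rounds:
            rounds += 1
            need = (nF - len(new_fem)) + (nM - len(new_male))
            batch = max(4 * need, 64)
            mothers = rng.integers(len(fem_alleles), size=batch)
            fathers = rng.integers(len(male_pairs), size=batch)
            egg_w = rng.random(batch) < 0.5
            sperm_first = rng.integers(2, size=batch)
            w_lost = rng.random(batch) < config.z0_rate
            for i in range(batch):
                zygotes += 1
                mi, fi = mothers[i], fathers[i]
                m_karyo = fem_karyo[mi]
                pat = male_pairs[fi][sperm_first[i]]
                if m_karyo == "WZ":
                    egg = "W" if egg_w[i] else fem_alleles[mi]
                    if egg == "W" and w_lost[i]:
                        egg = None  # W loss -> Z0 route
                else:  # Z0 mother: Z univalent segregates 1/2 : 1/2
                    egg = fem_alleles[mi] if egg_w[i] else None
                if egg == "W":
                    if len(new_fem) < nF:
                        new_fem.append(("WZ", pat))
                elif egg is None:
                    if len(new_fem) < nF:
                        new_fem.append(("Z0", pat))
                else:
                    if egg == pat:
                        inviable += 1
                        continue
                    if len(new_male) < nM:
                        new_male.append((egg, pat))
                if len(new_fem) >= nF and len(new_male) >= nM:
                    break
        if len(new_fem) < nF or len(new_male) < nM:
            extinct = True
            extinct_at = gen
            break

        # mutation on transmitted copies
        if per_copy_rate > 0:
            n_copies = nF + 2 * nM
            n_mut = rng.binomial(n_copies, min(per_copy_rate, 1.0))
            for idx in rng.choice(n_copies, size=n_mut, replace=False):
                idx = int(idx)
                if idx < nF:
                    rec = registry.records[new_fem[idx][1]]
                    mutated = mutate_haplotype(rec, config, rng)
                    if mutated is not rec:
                        new_fem[idx] = (new_fem[idx][0], registry.add(mutated))
                else:
                    j, slot = divmod(idx - nF, 2)
                    pair = list(new_male[j])
                    rec = registry.records[pair[slot]]
                    mutated = mutate_haplotype(rec, config, rng)
                    if mutated is not rec:
                        pair[slot] = registry.add(mutated)
                        if pair[0] == pair[1]:
                            continue  # mutation to partner's allele: keep original
                        new_male[j] = (pair[0], pair[1])

        fem_karyo = [kf for kf, _ in new_fem]
        fem_alleles = [a for _, a in new_fem]
        male_pairs = new_male
        record_counts()
        inviable_fraction.append(inviable / zygotes if zygotes else 0.0)

    females = [Individual(k, (a,)) for k, a in zip(fem_karyo, fem_alleles)]
    males = [Individual("ZZ", pair) for pair in male_pairs]
    for ind in males:
        assert ind.sex == "male", "homozygote survived to adulthood"
    return SimState(
        config=config,
        registry=registry.records,
        generation_counts=generation_counts,
        inviable_fraction=inviable_fraction,
        females=females,
        males=males,
        extinct=extinct,
        extinct_generation=extinct_at,
    )


# ---------------------------------------------------------------------------
# broods and expression


def simulate_brood(
    mother: Individual,
    father: Individual,
    n_eggs: int,
    rng: np.random.Generator,
) -> BroodRecord:
    """Draw one brood under Mendelian segregation of the zygosity rule.

    Homozygous ZZ zygotes appear as unhatched black eggs; all other classes
    hatch.
    """
    if mother.sex != "female" or father.sex != "male":
        raise InvalidCrossError(
            f"cross requires a female mother and male father, got "
            f"{mother.sex} x {father.sex}"
        )
    from .mendel import expected_offspring

    expectation = expected_offspring(mother, father)
    classes = expectation.classes
    draws = rng.multinomial(n_eggs, [c.proportion for c in classes])
    class_counts: dict[str, int] = Counter()
    hatched = black = 0
    for cls, n in zip(classes, draws):
        class_counts[cls.label] += int(n)
        if cls.viable:
            hatched += int(n)
        else:
            black += int(n)
    brood = BroodRecord(
        mother=mother,
        father=father,
        n_eggs=n_eggs,
        class_counts=dict(class_counts),
        hatched=hatched,
        black_egg=black,
    )
    brood.validate()
    return brood


def simulate_expression_matrix(
    n_auto: int,
    n_z: int,
    classes: list[str] | None = None,
    rng: np.random.Generator | None = None,
    *,
    hom_factor: float = 1.87,
    z_a_ratio: float = 0.6,
    noise_sd: float = 0.25,
    baseline_log_mean: float = 3.0,
    baseline_log_sd: float = 1.2,
):
    """Generate a gene x sample abundance table with known dosage structure.

    Autosomal genes share one per-gene baseline across all zygosity classes.
    Z-linked genes are compensated to ``z_a_ratio`` of the autosomal level in
    hemizygous (hem) and heterozygous (het) samples; in homozygous (hom)
    samples compensation fails and Z expression is elevated by
    ``hom_factor`` (default 1.87) relative to hem. Noise is multiplicative
    lognormal with log-scale sd ``noise_sd``.

    Returns a :class:`zsd.dosage.ExpressionTable`.
    """
    from .dosage import ExpressionTable
    import pandas as pd

    if n_auto < 1 or n_z < 1:
        raise InvalidConfigError("n_auto and n_z must be positive")
    if classes is None:
        classes = ["hem"] * 3 + ["het"] * 3 + ["hom"] * 6
    for c in classes:
        if c not in {"hem", "het", "hom"}:
            raise InvalidConfigError(f"unknown zygosity class label {c!r}")
    if rng is None:
        rng = np.random.default_rng(0)

    genes = [f"gA{i:05d}" for i in range(n_auto)] + [f"gZ{i:05d}" for i in range(n_z)]
    gene_class = pd.Series(["A"] * n_auto + ["Z"] * n_z, index=genes, name="gene_class")
    samples = [f"s{i:02d}_{c}" for i, c in enumerate(classes)]
    sample_class = pd.Series(list(classes), index=samples, name="sample_class")

    baseline = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, size=n_auto + n_z))
    z_mask = np.array([False] * n_auto + [True] * n_z)
    factors = {"hem": 1.0, "het": 1.0, "hom": hom_factor}

    cols = []
    for c in classes:
        mean = baseline.copy()
        mean[z_mask] *= z_a_ratio * factors[c]
        if noise_sd > 0:
            mean = mean * np.exp(rng.normal(0.0, noise_sd, size=mean.shape))
        cols.append(mean)
    df = pd.DataFrame(np.column_stack(cols), index=genes, columns=samples)
    return ExpressionTable(values=df, gene_class=gene_class, sample_class=sample_class)
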