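"""Codon-aware sequence diversity on haplotype alignments.

Implements the Nei-Gojobori (1986) unweighted pathway method for
synonymous/nonsynonymous differences with pairwise deletion at codon
granularity, a triplet-indel measure for codon-aligned gaps, sliding-window
diversity profiles with bootstrap standard errors, codon-usage profiling of
hypervariable vs flanking regions, haplotype (gene) diversity, and AMOVA
Phi_ST with permutation testing.

Conventions: alignment coordinates are 0-based half-open in nucleotides;
indels are assumed to be triplet (codon) indels, so a maximal gap run of 3m
nucleotides counts as m triplet indels by default (an event-wise mode is
available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np

from ._codons import (
    CODON_TO_AA,
    pathway_differences,
    syn_site_fraction,
    translate,
)
from .errors import UndefinedStatisticError, ValidationError
from .simcore import HaplotypeRecord

__all__ = [
    "CodingAlignment",
    "validate_alignment",
    "align_simulated_haplotypes",
    "NeiGojoboriCounts",
    "nei_gojobori_pair",
    "triplet_indel_pair",
    "WindowDiversity",
    "sliding_window_diversity",
    "ExonDiversity",
    "exon_diversity",
    "CodonUsageTable",
    "codon_usage_profile",
    "hvr_length_distribution",
    "haplotype_diversity",
    "PhiStResult",
    "amova_phi_st",
]

_GAP = "-"


@dataclass(frozen=True)
class CodingAlignment:
    """A validated codon alignment (equal-length gapped rows).

    ``regions`` maps region names (e.g. "E8", "HVR", "E9") to 0-based
    half-open nucleotide intervals in alignment coordinates.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codon(self, row: int, col: int) -> str:
        return self.rows[row][col * 3 : col * 3 + 3]


def validate_alignment(
    records: Sequence[tuple[str, str]],
    regions: dict[str, tuple[int, int]] | None = None,
) -> CodingAlignment:
    """Validate raw (id, gapped sequence) pairs into a :class:`CodingAlignment`.

    Enforced invariants: >= 2 rows; all rows equal length; length divisible
    by 3; every gap run has length divisible by 3 and starts on a codon
    boundary; no internal stop codons (a stop as a row's final non-gap codon
    is allowed). Diagnostics name the offending row and column.
    """
    if len(records) < 2:
        raise ValidationError(f"alignment needs >= 2 sequences, got {len(records)}")
    ids = tuple(r[0] for r in records)
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate sequence ids: {dup}")
    rows = tuple(r[1].upper() for r in records)
    length = len(rows[0])
    for sid, row in zip(ids, rows):
        if len(row) != length:
            raise ValidationError(
                f"ragged alignment: row {sid!r} has length {len(row)}, expected {length}"
            )
    if length % 3:
        raise ValidationError(f"alignment length {length} is not a codon multiple")
    for sid, row in zip(ids, rows):
        pos = 0
        while pos < length:
            if row[pos] == _GAP:
                run_start = pos
                while pos < length and row[pos] == _GAP:
                    pos += 1
                run = pos - run_start
                if run % 3 or run_start % 3:
                    raise ValidationError(
                        f"row {sid!r}: gap run of {run} nt at column {run_start} "
                        f"is not a codon-aligned triplet gap"
                    )
            else:
                pos += 1
        # stop codon scan on occupied codons
        occupied = [
            (c, row[c * 3 : c * 3 + 3])
            for c in range(length // 3)
            if _GAP not in row[c * 3 : c * 3 + 3]
        ]
        for k, (c, codon) in enumerate(occupied):
            if codon not in CODON_TO_AA and set(codon) <= set("ACGT"):
                if k != len(occupied) - 1:
                    raise ValidationError(
                        f"row {sid!r}: internal stop codon {codon} at codon column {c}"
                    )
    if regions is not None:
        for name, (lo, hi) in regions.items():
            if not (0 <= lo <= hi <= length):
                raise ValidationError(f"region {name!r} span ({lo}, {hi}) outside alignment")
    return CodingAlignment(ids=ids, rows=rows, regions=dict(regions or {}))


def align_simulated_haplotypes(haps: Sequence[HaplotypeRecord]) -> CodingAlignment:
    """Codon alignment of simulator haplotypes sharing conserved flanks.

    Simulated haplotypes differ in length only through the HVR, so padding
    each HVR with gap codons to the longest HVR yields a valid codon
    alignment. Region spans (E8 flank, HVR, E9) are annotated in alignment
    nucleotide coordinates. Requires all haplotypes to share the same
    pre-HVR and post-HVR lengths.
    """
    if len(haps) < 2:
        raise ValidationError("alignment needs >= 2 haplotypes")
    lo0 = haps[0].hvr_span[0]
    tail0 = len(haps[0].nt_seq) // 3 - haps[0].hvr_span[1]
    for h in haps:
        if h.hvr_span[0] != lo0 or len(h.nt_seq) // 3 - h.hvr_span[1] != tail0:
            raise ValidationError(
                f"{h.allele_id}: flank lengths differ; haplotypes are not "
                f"alignable by HVR padding"
            )
    max_hvr = max(h.hvr_len for h in haps)
    rows = []
    for h in haps:
        lo, hi = h.hvr_span
        pad = "---" * (max_hvr - h.hvr_len)
        rows.append((h.allele_id, h.nt_seq[: hi * 3] + pad + h.nt_seq[hi * 3 :]))
    regions = {
        "E8": (0, lo0 * 3),
        "HVR": (lo0 * 3, (lo0 + max_hvr) * 3),
        "E9": ((lo0 + max_hvr) * 3, (lo0 + max_hvr + tail0) * 3),
    }
    return validate_alignment(rows, regions=regions)


class NeiGojoboriCounts(NamedTuple):
    syn_diffs: float
    nonsyn_diffs: float
    syn_sites: float
    nonsyn_sites: float

    @property
    def p_syn(self) -> float:
        if self.syn_sites == 0:
            raise UndefinedStatisticError("no synonymous sites compared")
        return self.syn_diffs / self.syn_sites

    @property
    def p_nonsyn(self) -> float:
        if self.nonsyn_sites == 0:
            raise UndefinedStatisticError("no nonsynonymous sites compared")
        return self.nonsyn_diffs / self.nonsyn_sites


def _comparable(codon: str) -> bool:
    return codon in CODON_TO_AA  # sense codon, no gap/ambiguity/stop


def nei_gojobori_pair(
    codons1: Sequence[str], codons2: Sequence[str]
) -> NeiGojoboriCounts:
    """Nei-Gojobori pathway counts for a pair of codon sequences.

    Codon pairs in which either member contains a gap, an ambiguity code or
    a stop codon are skipped entirely (pairwise deletion at codon
    granularity). Site counts are averaged over the two sequences; for
    codons differing at several positions, differences are averaged over
    all minimal substitution pathways avoiding stop codons.
    """
    if len(codons1) != len(codons2):
        raise ValidationError("codon sequences must have equal length")
    sd = nd = ss = ns = 0.0
    compared = 0
    for c1, c2 in zip(codons1, codons2):
        c1, c2 = c1.upper(), c2.upper()
        if not (_comparable(c1) and _comparable(c2)):
            continue
        compared += 1
        s1, s2 = syn_site_fraction(c1), syn_site_fraction(c2)
        ss += (s1 + s2) / 2.0
        ns += 3.0 - (s1 + s2) / 2.0
        d_syn, d_nonsyn = pathway_differences(c1, c2)
        sd += d_syn
        nd += d_nonsyn
    if compared == 0:
        raise UndefinedStatisticError("no comparable codon pairs (all gapped/ambiguous)")
    return NeiGojoboriCounts(sd, nd, ss, ns)


def triplet_indel_pair(
    row1: str, row2: str, window: tuple[int, int] | None = None, *, count_events: bool = False
) -> int:
    """Pairwise triplet-indel count between two aligned rows.

    A codon column gapped in exactly one of the two rows counts as one
    triplet indel (default). With ``count_events=True`` a maximal run of
    such columns counts once. Columns gapped in both rows are not pairwise
    differences. ``window`` is a 0-based half-open nucleotide interval on
    codon boundaries; the caller normalises by window codon count.
    """
    if len(row1) != len(row2):
        raise ValidationError("rows must have equal length")
    lo, hi = window if window is not None else (0, len(row1))
    if lo % 3 or hi % 3:
        raise ValidationError("window must fall on codon boundaries")
    count = 0
    prev_state = 0  # 0 = no single-gap, 1 = row1 gapped, 2 = row2 gapped
    for c in range(lo // 3, hi // 3):
        g1 = row1[c * 3 : c * 3 + 3] == "---"
        g2 = row2[c * 3 : c * 3 + 3] == "---"
        state = 1 if (g1 and not g2) else 2 if (g2 and not g1) else 0
        if state:
            if count_events:
                if state != prev_state:
                    count += 1
            else:
                count += 1
        prev_state = state
    return count


@dataclass(frozen=True)
class WindowDiversity:
    start: int  # alignment nt coords, 0-based half-open
    end: int
    pi_syn: float
    pi_nonsyn: float
    indel_per_triplet: float
    se_syn: float
    se_nonsyn: float


def _pair_codon_stats(aln: CodingAlignment):
    """Per-pair, per-codon-column Nei-Gojobori and indel primitives.

    Returns (pairs, comparable[p,c], syn_d, nonsyn_d, syn_s, nonsyn_s,
    single_gap[p,c]) with arrays over pair x codon column.
    """
    pairs = list(combinations(range(aln.n_seqs), 2))
    n_p, n_c = len(pairs), aln.n_codons
    comparable = np.zeros((n_p, n_c), dtype=bool)
    syn_d = np.zeros((n_p, n_c))
    nonsyn_d = np.zeros((n_p, n_c))
    syn_s = np.zeros((n_p, n_c))
    single_gap = np.zeros((n_p, n_c), dtype=bool)
    codons = [[aln.codon(r, c) for c in range(n_c)] for r in range(aln.n_seqs)]
    for p, (i, j) in enumerate(pairs):
        for c in range(n_c):
            c1, c2 = codons[i][c], codons[j][c]
            g1, g2 = c1 == "---", c2 == "---"
            if g1 != g2:
                single_gap[p, c] = True
            if _comparable(c1) and _comparable(c2):
                comparable[p, c] = True
                s1, s2 = syn_site_fraction(c1), syn_site_fraction(c2)
                syn_s[p, c] = (s1 + s2) / 2.0
                d_s, d_n = pathway_differences(c1, c2)
                syn_d[p, c] = d_s
                nonsyn_d[p, c] = d_n
    nonsyn_s = np.where(comparable, 3.0 - syn_s, 0.0)
    syn_s = np.where(comparable, syn_s, 0.0)
    return pairs, comparable, syn_d, nonsyn_d, syn_s, nonsyn_s, single_gap


def _mean_pairwise_props(cols, comparable, syn_d, nonsyn_d, syn_s, nonsyn_s):
    """Mean over pairs of per-pair p_syn and p_nonsyn on the given columns."""
    sd = syn_d[:, cols].sum(axis=1)
    nd = nonsyn_d[:, cols].sum(axis=1)
    ss = syn_s[:, cols].sum(axis=1)
    ns = nonsyn_s[:, cols].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ps = np.where(ss > 0, sd / np.where(ss > 0, ss, 1.0), np.nan)
        pn = np.where(ns > 0, nd / np.where(ns > 0, ns, 1.0), np.nan)
    mean_ps = float(np.nanmean(ps)) if not np.all(np.isnan(ps)) else 0.0
    mean_pn = float(np.nanmean(pn)) if not np.all(np.isnan(pn)) else 0.0
    return mean_ps, mean_pn


def sliding_window_diversity(
    aln: CodingAlignment,
    window_nt: int = 99,
    overlap_nt: int = 75,
    boot_reps: int = 100,
    rng: np.random.Generator | None = None,
) -> list[WindowDiversity]:
    """Sliding-window synonymous/nonsynonymous diversity and indel profile.

    All haplotype pairs are weighted equally. Windows step left to right
    from position 0 with step ``window_nt - overlap_nt`` (24 nt for the
    default 99/75); the final partial window is reported with its true
    length. Standard errors come from bootstrap resampling of codon columns
    within each window (``boot_reps`` replicates).
    """
    if window_nt % 3:
        raise ValidationError(f"window_nt={window_nt} is not a codon multiple")
    if overlap_nt >= window_nt:
        raise ValidationError("overlap must be smaller than the window")
    if aln.length < window_nt:
        raise ValidationError(
            f"alignment length {aln.length} nt is shorter than one {window_nt}-nt window"
        )
    if rng is None:
        rng = np.random.default_rng(0)
    step = window_nt - overlap_nt
    _, comparable, syn_d, nonsyn_d, syn_s, nonsyn_s, single_gap = _pair_codon_stats(aln)

    out: list[WindowDiversity] = []
    start = 0
    while start < aln.length:
        end = min(start + window_nt, aln.length)
        cols = np.arange(start // 3, (end + 2) // 3)
        n_codons = len(cols)
        ps, pn = _mean_pairwise_props(cols, comparable, syn_d, nonsyn_d, syn_s, nonsyn_s)
        indels = float(single_gap[:, cols].sum(axis=1).mean()) / n_codons
        boots_s = np.empty(boot_reps)
        boots_n = np.empty(boot_reps)
        for b in range(boot_reps):
            bcols = rng.choice(cols, size=n_codons, replace=True)
            boots_s[b], boots_n[b] = _mean_pairwise_props(
                bcols, comparable, syn_d, nonsyn_d, syn_s, nonsyn_s
            )
        out.append(
            WindowDiversity(
                start=start,
                end=end,
                pi_syn=ps,
                pi_nonsyn=pn,
                indel_per_triplet=indels,
                se_syn=float(boots_s.std(ddof=1)) if boot_reps > 1 else 0.0,
                se_nonsyn=float(boots_n.std(ddof=1)) if boot_reps > 1 else 0.0,
            )
        )
        if end == aln.length:
            break
        start += step
    return out


@dataclass(frozen=True)
class ExonDiversity:
    pi: float
    pi_syn: float
    pi_nonsyn: float
    se_pi: float
    se_syn: float
    se_nonsyn: float


def exon_diversity(
    aln: CodingAlignment,
    region: tuple[int, int] | None = None,
    *,
    method: str = "p",
    boot_reps: int = 100,
    rng: np.random.Generator | None = None,
) -> ExonDiversity:
    """Nucleotide diversity (pi) and Nei-Gojobori pi_s/pi_n for a region.

    pi is the mean pairwise nucleotide p-distance with site-level pairwise
    deletion (``method="jc"`` applies the Jukes-Cantor correction); pi_s
    and pi_n are Nei-Gojobori p-distances. Bootstrap (over codon columns)
    standard errors with ``boot_reps`` replicates.
    """
    if region is None:
        region = (0, aln.length)
    lo, hi = region
    if not (0 <= lo < hi <= aln.length):
        raise ValidationError(f"empty or out-of-range region ({lo}, {hi})")
    if lo % 3 or hi % 3:
        raise ValidationError("region must fall on codon boundaries")
    if rng is None:
        rng = np.random.default_rng(0)
    if method not in {"p", "jc"}:
        raise ValidationError(f"unknown method {method!r}")

    pairs, comparable, syn_d, nonsyn_d, syn_s, nonsyn_s, _ = _pair_codon_stats(aln)
    cols_all = np.arange(lo // 3, hi // 3)

    # nucleotide-level per-pair, per-codon diff/site counts for pi
    n_p = len(pairs)
    nt_diffs = np.zeros((n_p, aln.n_codons))
    nt_sites = np.zeros((n_p, aln.n_codons))
    for p, (i, j) in enumerate(pairs):
        ri, rj = aln.rows[i], aln.rows[j]
        for c in cols_all:
            for off in range(3):
                a, b = ri[3 * c + off], rj[3 * c + off]
                if a in "ACGT" and b in "ACGT":
                    nt_sites[p, c] += 1
                    if a != b:
                        nt_diffs[p, c] += 1

    def stats_on(cols):
        ps, pn = _mean_pairwise_props(cols, comparable, syn_d, nonsyn_d, syn_s, nonsyn_s)
        d = nt_diffs[:, cols].sum(axis=1)
        s = nt_sites[:, cols].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pd = np.where(s > 0, d / np.where(s > 0, s, 1.0), np.nan)
        if method == "jc":
            pd = np.where(pd < 0.75, -0.75 * np.log(1.0 - 4.0 / 3.0 * pd), np.nan)
        pi = float(np.nanmean(pd)) if not np.all(np.isnan(pd)) else 0.0
        return pi, ps, pn

    pi, ps, pn = stats_on(cols_all)
    boots = np.empty((boot_reps, 3))
    for b in range(boot_reps):
        bcols = rng.choice(cols_all, size=len(cols_all), replace=True)
        boots[b] = stats_on(bcols)
    se = boots.std(axis=0, ddof=1) if boot_reps > 1 else np.zeros(3)
    return ExonDiversity(
        pi=pi, pi_syn=ps, pi_nonsyn=pn,
        se_pi=float(se[0]), se_syn=float(se[1]), se_nonsyn=float(se[2]),
    )


@dataclass
class CodonUsageTable:
    """Per-haplotype, per-region proportions over the 61 sense codons."""

    proportions: dict[tuple[str, str], dict[str, float]]  # (allele_id, region) -> codon -> prop
    empty_regions: list[tuple[str, str]]
    hvr_ant_nat: bool  # True iff every HVR codon matches ANT or NAT


def codon_usage_profile(haps: Sequence[HaplotypeRecord]) -> CodonUsageTable:
    """Codon usage inside vs outside the HVR for each haplotype."""
    from .simcore import _is_ant_or_nat

    props: dict[tuple[str, str], dict[str, float]] = {}
    empty: list[tuple[str, str]] = []
    ant_nat = True
    for h in haps:
        lo, hi = h.hvr_span
        n_codons = len(h.nt_seq) // 3
        regions = {
            "HVR": [h.nt_seq[i * 3 : i * 3 + 3] for i in range(lo, hi)],
            "non-HVR": [
                h.nt_seq[i * 3 : i * 3 + 3]
                for i in range(n_codons)
                if not (lo <= i < hi)
            ],
        }
        for codon in regions["HVR"]:
            if not _is_ant_or_nat(codon):
                ant_nat = False
        for name, codons in regions.items():
            codons = [c for c in codons if c in CODON_TO_AA]
            if not codons:
                empty.append((h.allele_id, name))
                continue
            counts: dict[str, float] = {}
            for c in codons:
                counts[c] = counts.get(c, 0.0) + 1.0
            total = sum(counts.values())
            props[(h.allele_id, name)] = {c: v / total for c, v in counts.items()}
    return CodonUsageTable(proportions=props, empty_regions=empty, hvr_ant_nat=ant_nat)


def hvr_length_distribution(haps: Sequence[HaplotypeRecord]) -> dict[int, int]:
    """Histogram of HVR residue lengths keyed by length."""
    counts: dict[int, int] = {}
    for h in haps:
        counts[h.hvr_len] = counts.get(h.hvr_len, 0) + 1
    return dict(sorted(counts.items()))


def haplotype_diversity(counts) -> float:
    """Unbiased haplotype (gene) diversity H = n/(n-1) (1 - sum p_i^2)."""
    if hasattr(counts, "counts"):
        counts = counts.counts
    vals = np.asarray(list(counts.values()), dtype=float)
    n = vals.sum()
    if n < 2:
        raise UndefinedStatisticError("haplotype diversity requires n >= 2")
    p = vals / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


@dataclass(frozen=True)
class PhiStResult:
    pairwise: dict[tuple[str, str], float]
    pairwise_p: dict[tuple[str, str], float]
    average: float
    n_perm: int
    excluded: tuple[str, ...]


def _phi_from_squared(D2: np.ndarray, group_idx: list[np.ndarray]) -> float:
    """AMOVA Phi_ST from a matrix of squared distances and group row indices."""
    n = D2.shape[0]
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    sizes = []
    for idx in group_idx:
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        sizes.append(len(idx))
    g = len(group_idx)
    df_a, df_w = g - 1, n - g
    if df_w <= 0:
        return np.nan
    ms_a = (ss_total - ss_within) / df_a
    ms_w = ss_within / df_w
    n0 = (n - sum(s * s for s in sizes) / n) / df_a
    var_a = (ms_a - ms_w) / n0
    denom = var_a + ms_w
    if denom == 0:
        return 0.0
    return float(var_a / denom)


def amova_phi_st(
    distance_matrix: np.ndarray,
    population_labels: Sequence[str],
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> PhiStResult:
    """Pairwise AMOVA Phi_ST between populations with permutation p-values.

    Phi_ST is the among-population share of molecular variance computed from
    squared pairwise distances (Excoffier et al. 1992). Permutation p-values
    shuffle individual labels within each population pair; populations with
    fewer than 2 members are excluded with a warning.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValidationError("distance matrix must be symmetric")
    labels = np.asarray(population_labels)
    if labels.shape[0] != D.shape[0]:
        raise ValidationError("label count does not match matrix size")
    if rng is None:
        rng = np.random.default_rng(0)

    pops = sorted(set(labels.tolist()))
    sizes = {p: int((labels == p).sum()) for p in pops}
    excluded = tuple(p for p in pops if sizes[p] < 2)
    if excluded:
        warnings.warn(f"excluding singleton populations: {excluded}", stacklevel=2)
    kept = [p for p in pops if sizes[p] >= 2]
    if len(kept) < 2:
        raise ValidationError("need >= 2 populations with >= 2 members each")

    D2 = D**2
    pairwise: dict[tuple[str, str], float] = {}
    pairwise_p: dict[tuple[str, str], float] = {}
    for a, b in combinations(kept, 2):
        idx = np.where((labels == a) | (labels == b))[0]
        sub2 = D2[np.ix_(idx, idx)]
        sub_labels = labels[idx]
        obs = _phi_from_squared(
            sub2, [np.where(sub_labels == a)[0], np.where(sub_labels == b)[0]]
        )
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(sub_labels)
            phi = _phi_from_squared(
                sub2, [np.where(perm == a)[0], np.where(perm == b)[0]]
            )
            if phi >= obs:
                count += 1
        pairwise[(a, b)] = obs
        pairwise_p[(a, b)] = (count + 1) / (n_perm + 1)
    average = float(np.mean(list(pairwise.values())))
    return PhiStResult(
        pairwise=pairwise,
        pairwise_p=pairwise_p,
        average=average,
        n_perm=n_perm,
        excluded=excluded,
    )
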