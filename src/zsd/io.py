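"""Readers and writers for the package's file formats.

Formats are deliberately plain: FASTA for haplotypes and alignments (via
Biopython), tab-separated tables for genotypes, broods and expression
(via pandas), a BED-like three-column span file for region annotations,
and YAML for pipeline configuration. All coordinates in annotation files
are 0-based half-open.
"""

from __future__ import annotations

import sys
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diversity import CodingAlignment, validate_alignment
from .dosage import ExpressionTable
from .errors import ValidationError
from .richness import Observation
from .simcore import BroodRecord, HaplotypeRecord

__all__ = [
    "read_fasta_alignment",
    "write_fasta",
    "read_haplotype_fasta",
    "write_haplotypes",
    "read_region_file",
    "read_genotype_table",
    "write_genotype_table",
    "read_brood_table",
    "write_brood_table",
    "read_expression_table",
    "write_expression_table",
    "read_config",
    "log",
]

_FASTA_WIDTH = 80


def log(**fields) -> None:
    """Machine-parsable key=value logging to stderr."""
    print(" ".join(f"{k}={v}" for k, v in fields.items()), file=sys.stderr)


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(path: str | Path, records: Sequence[tuple[str, str]]) -> None:
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=_FASTA_WIDTH)
        writer.write_file(seqs)


def read_fasta_alignment(
    path: str | Path, regions: dict[str, tuple[int, int]] | None = None
) -> CodingAlignment:
    """Read an aligned FASTA into a validated :class:`CodingAlignment`.

    Duplicate ids, ragged rows, non-triplet gaps and internal stops are all
    rejected with named errors.
    """
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValidationError(f"{path}: empty or not a FASTA file")
    return validate_alignment(records, regions=regions)


def write_haplotypes(path: str | Path, haps: Sequence[HaplotypeRecord]) -> None:
    """Write haplotypes as FASTA; HVR span is carried in the description."""
    seqs = [
        SeqRecord(
            Seq(h.nt_seq),
            id=h.allele_id,
            description=f"hvr={h.hvr_span[0]}-{h.hvr_span[1]}",
        )
        for h in haps
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=_FASTA_WIDTH)
        writer.write_file(seqs)


def read_haplotype_fasta(path: str | Path) -> list[HaplotypeRecord]:
    """Read haplotypes written by :func:`write_haplotypes` (hvr= in header)."""
    out = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        span = None
        for token in rec.description.split():
            if token.startswith("hvr="):
                lo, hi = token[4:].split("-")
                span = (int(lo), int(hi))
        if span is None:
            raise ValidationError(f"{path}: record {rec.id!r} lacks an hvr= span")
        out.append(HaplotypeRecord(allele_id=rec.id, nt_seq=str(rec.seq), hvr_span=span))
    if not out:
        raise ValidationError(f"{path}: empty or not a FASTA file")
    return out


def read_region_file(path: str | Path) -> dict[str, tuple[int, int]]:
    """BED-like 3-column file: name <tab> start <tab> end (0-based half-open)."""
    regions: dict[str, tuple[int, int]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValidationError(f"{path}:{ln}: expected 3 tab-separated columns")
        try:
            regions[parts[0]] = (int(parts[1]), int(parts[2]))
        except ValueError as exc:
            raise ValidationError(f"{path}:{ln}: non-integer coordinate") from exc
    return regions


# ---------------------------------------------------------------------------
# TSV tables

_GENOTYPE_COLS = ["individual", "population", "g1_flag", "allele1", "allele2"]


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def read_genotype_table(path: str | Path) -> list[Observation]:
    """Genotype TSV -> allele observations (one row per individual).

    Columns: individual, population, g1_flag (0/1), allele1, allele2
    (allele2 empty for hemizygous females). Each carried allele yields one
    observation.
    """
    df = _read_tsv(path, _GENOTYPE_COLS)
    out: list[Observation] = []
    for idx, row in df.iterrows():
        flag = str(row["g1_flag"]).strip().lower()
        if flag not in {"0", "1", "true", "false"}:
            raise ValidationError(f"{path}: row {idx + 2}: bad g1_flag {row['g1_flag']!r}")
        g1 = flag in {"1", "true"}
        alleles = [
            a for a in (row["allele1"], row.get("allele2"))
            if isinstance(a, str) and a.strip()
        ]
        if not 1 <= len(alleles) <= 2:
            raise ValidationError(f"{path}: row {idx + 2}: expected 1-2 alleles")
        for a in alleles:
            out.append(
                Observation(
                    individual=str(row["individual"]),
                    population=str(row["population"]),
                    g1_flag=g1,
                    allele_id=a.strip(),
                )
            )
    return out


def write_genotype_table(path: str | Path, observations: Sequence[Observation]) -> None:
    """Write observations back as a genotype TSV (one row per individual)."""
    by_ind: dict[str, list[Observation]] = {}
    order: list[str] = []
    for o in observations:
        if o.individual not in by_ind:
            order.append(o.individual)
        by_ind.setdefault(o.individual, []).append(o)
    rows = []
    for ind in order:
        obs = by_ind[ind]
        alleles = [o.allele_id for o in obs]
        rows.append(
            {
                "individual": ind,
                "population": obs[0].population,
                "g1_flag": int(obs[0].g1_flag),
                "allele1": alleles[0],
                "allele2": alleles[1] if len(alleles) > 1 else "",
            }
        )
    pd.DataFrame(rows, columns=_GENOTYPE_COLS).to_csv(path, sep="\t", index=False)


_BROOD_COLS = [
    "mother_karyotype", "mother_allele", "father_allele1", "father_allele2",
    "n_eggs", "hatched", "black_egg", "white_egg", "collapsed",
]


def write_brood_table(path: str | Path, broods: Sequence[BroodRecord]) -> None:
    rows = []
    for b in broods:
        rows.append(
            {
                "mother_karyotype": b.mother.karyotype,
                "mother_allele": b.mother.alleles[0],
                "father_allele1": b.father.alleles[0],
                "father_allele2": b.father.alleles[1],
                "n_eggs": b.n_eggs,
                "hatched": b.hatched,
                "black_egg": b.black_egg,
                "white_egg": b.white_egg,
                "collapsed": b.collapsed,
            }
        )
    pd.DataFrame(rows, columns=_BROOD_COLS).to_csv(path, sep="\t", index=False)


def read_brood_table(path: str | Path) -> pd.DataFrame:
    """Brood TSV -> typed DataFrame (counts validated nonnegative)."""
    df = _read_tsv(path, _BROOD_COLS)
    ints = ["n_eggs", "hatched", "black_egg", "white_egg", "collapsed"]
    for c in ints:
        try:
            df[c] = df[c].astype(int)
        except ValueError as exc:
            bad = df[~df[c].str.fullmatch(r"-?\d+")].index
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise ValidationError(f"{path}: row {row}: non-integer {c}") from exc
    neg = df.index[(df[ints] < 0).any(axis=1)]
    if len(neg):
        raise ValidationError(f"{path}: row {int(neg[0]) + 2}: negative count")
    bad = df.index[df[ints[1:]].sum(axis=1) != df["n_eggs"]]
    if len(bad):
        raise ValidationError(
            f"{path}: row {int(bad[0]) + 2}: outcome counts do not sum to n_eggs"
        )
    return df


def write_expression_table(
    prefix: str | Path, table: ExpressionTable
) -> tuple[Path, Path, Path]:
    """Write matrix + two class sidecars: <prefix>.tsv, .genes.tsv, .samples.tsv."""
    prefix = Path(prefix)
    matrix = prefix.with_suffix(".tsv")
    genes = prefix.with_suffix(".genes.tsv")
    samples = prefix.with_suffix(".samples.tsv")
    table.values.to_csv(matrix, sep="\t", index_label="gene")
    table.gene_class.rename("gene_class").to_csv(genes, sep="\t", index_label="gene")
    table.sample_class.rename("sample_class").to_csv(samples, sep="\t", index_label="sample")
    return matrix, genes, samples


def read_expression_table(
    matrix: str | Path, genes: str | Path, samples: str | Path
) -> ExpressionTable:
    """Read a gene x sample TSV plus gene/sample class sidecars."""
    values = pd.read_csv(matrix, sep="\t", index_col="gene")
    if values.isna().any().any():
        bad = values.index[values.isna().any(axis=1)][0]
        raise ValidationError(f"{matrix}: missing abundance for gene {bad!r}")
    if (values.values < 0).any():
        bad = values.index[(values < 0).any(axis=1)][0]
        raise ValidationError(f"{matrix}: negative abundance for gene {bad!r}")
    gene_class = pd.read_csv(genes, sep="\t", index_col="gene")["gene_class"]
    sample_class = pd.read_csv(samples, sep="\t", index_col="sample")["sample_class"]
    return ExpressionTable(values=values, gene_class=gene_class, sample_class=sample_class)


def read_config(path: str | Path) -> dict:
    """Read a YAML pipeline configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: configuration must be a mapping")
    return cfg
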