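"""Domain containers and readers/writers for the pipeline's external formats.

Formats handled here: aligned FASTA (via Bio.SeqIO), a TSV genotype dialect
carrying per-call read depth and read-support (``allele:depth:support``),
read-only genepop, labelled TSV distance matrices, isolate metadata TSV and
Newick export of dendrograms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = set("ACGTN-")

#: sentinel for an unknown read depth (e.g. genepop input carries none)
DEPTH_UNKNOWN = -1
#: sentinel allele code for a missing genotype call
MISSING = -1


class RaggedAlignmentError(ValueError):
    """Records of a supposedly aligned FASTA differ in length."""


@dataclass
class Alignment:
    """Equal-length nucleotide sequences with optional coding-frame offset.

    ``frame`` marks the 0-based offset of the first complete codon; ``None``
    means the alignment is not annotated as coding.
    """

    ids: list[str]
    seqs: list[str]
    frame: Optional[int] = None
    locus_name: str = ""

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs length mismatch")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise RaggedAlignmentError(
                f"ragged alignment: record lengths {sorted(lengths)}"
            )
        for rid, s in zip(self.ids, self.seqs):
            bad = set(s) - ALPHABET
            if bad:
                raise ValueError(
                    f"illegal characters {sorted(bad)} in record {rid!r}"
                )
        if self.frame is not None:
            if self.frame not in (0, 1, 2):
                raise ValueError("frame must be 0, 1 or 2")
            if self.seqs and (self.length - self.frame) < 3:
                raise ValueError("alignment too short for one codon at given frame")

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, ids: Sequence[str]) -> "Alignment":
        idx = {i: k for k, i in enumerate(self.ids)}
        missing = [i for i in ids if i not in idx]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        return Alignment(
            ids=list(ids),
            seqs=[self.seqs[idx[i]] for i in ids],
            frame=self.frame,
            locus_name=self.locus_name,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.seqs == other.seqs
            and self.frame == other.frame
            and self.locus_name == other.locus_name
        )


def _normalise_seq(raw: str, rid: str) -> str:
    s = str(raw).upper().replace("U", "T")
    bad = set(s) - ALPHABET
    if bad:
        raise ValueError(f"illegal characters {sorted(bad)} in record {rid!r}")
    return s


def read_alignment(path, frame: Optional[int] = None, locus_name: str = "") -> Alignment:
    """Read an aligned FASTA file. Lowercase is uppercased and U mapped to T."""
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        ids.append(rec.id)
        seqs.append(_normalise_seq(str(rec.seq), rec.id))
    if not ids:
        raise ValueError(f"no FASTA records in {path}")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise RaggedAlignmentError(
            f"ragged alignment in {path}: lengths {sorted(lengths)}"
        )
    if not locus_name:
        locus_name = Path(str(path)).stem
    return Alignment(ids=ids, seqs=seqs, frame=frame, locus_name=locus_name)


def write_alignment(aln: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# SNP matrices


@dataclass
class SnpMatrix:
    """Isolate x locus biallelic genotype grid with call metadata.

    ``alleles`` holds 0/1 calls with :data:`MISSING` (-1) for no-calls.
    ``depth`` holds read depth per call (:data:`DEPTH_UNKNOWN` when the input
    format carries none) and ``support`` the fraction of reads backing the
    call (NaN when unknown). ``coords`` optionally maps each locus to a
    (contig, start, end) interval, 0-based half-open.
    """

    isolate_ids: list[str]
    locus_ids: list[str]
    alleles: np.ndarray  # (n_isolates, n_loci) int8
    depth: np.ndarray  # (n_isolates, n_loci) int32
    support: np.ndarray  # (n_isolates, n_loci) float64
    coords: Optional[list[Optional[tuple[str, int, int]]]] = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        self.support = np.asarray(self.support, dtype=np.float64)
        shape = (len(self.isolate_ids), len(self.locus_ids))
        for name, arr in (
            ("alleles", self.alleles),
            ("depth", self.depth),
            ("support", self.support),
        ):
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != {shape}")
        if len(set(self.isolate_ids)) != len(self.isolate_ids):
            raise ValueError("duplicate isolate ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus ids")
        if self.coords is not None:
            if len(self.coords) != len(self.locus_ids):
                raise ValueError("coords length != number of loci")
            for c in self.coords:
                if c is not None and not (c[1] < c[2]):
                    raise ValueError(f"invalid interval {c}: start must be < end")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.isolate_ids), len(self.locus_ids))

    def subset_isolates(self, ids: Sequence[str]) -> "SnpMatrix":
        idx = [self.isolate_ids.index(i) for i in ids]
        return SnpMatrix(
            isolate_ids=list(ids),
            locus_ids=list(self.locus_ids),
            alleles=self.alleles[idx],
            depth=self.depth[idx],
            support=self.support[idx],
            coords=None if self.coords is None else list(self.coords),
        )

    def subset_loci(self, keep: np.ndarray) -> "SnpMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return SnpMatrix(
            isolate_ids=list(self.isolate_ids),
            locus_ids=[self.locus_ids[k] for k in keep],
            alleles=self.alleles[:, keep],
            depth=self.depth[:, keep],
            support=self.support[:, keep],
            coords=None
            if self.coords is None
            else [self.coords[k] for k in keep],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpMatrix):
            return NotImplemented
        return (
            self.isolate_ids == other.isolate_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.depth, other.depth)
            and np.array_equal(self.support, other.support, equal_nan=True)
            and self.coords == other.coords
        )


def _parse_locus_header(tok: str) -> tuple[str, Optional[tuple[str, int, int]]]:
    """Locus headers may embed coordinates as ``name@contig:start-end``."""
    if "@" in tok:
        name, loc = tok.split("@", 1)
        contig, span = loc.rsplit(":", 1)
        start_s, end_s = span.split("-", 1)
        return name, (contig, int(start_s), int(end_s))
    return tok, None


def read_snp_matrix(path, dialect: str = "tsv") -> SnpMatrix:
    """Read a genotype matrix.

    ``tsv`` dialect: first header cell is arbitrary, remaining header cells
    are locus ids (optionally ``name@contig:start-end``); one row per isolate
    with cells ``allele:depth:support`` or ``.`` for missing.

    ``genepop`` dialect: alleles only; depth/support come back unknown so the
    depth/support filters downstream become no-ops (they warn).
    """
    if dialect == "tsv":
        return _read_snp_tsv(path)
    if dialect == "genepop":
        return _read_genepop(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_snp_tsv(path) -> SnpMatrix:
    lines = Path(str(path)).read_text().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ValueError(f"empty SNP matrix file {path}")
    header = lines[0].split("\t")
    locus_ids: list[str] = []
    coords: list[Optional[tuple[str, int, int]]] = []
    for tok in header[1:]:
        name, coord = _parse_locus_header(tok)
        locus_ids.append(name)
        coords.append(coord)
    n_loci = len(locus_ids)
    isolate_ids: list[str] = []
    alleles, depth, support = [], [], []
    for row_no, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != n_loci + 1:
            raise ValueError(
                f"row {row_no}: expected {n_loci + 1} columns, got {len(cells)}"
            )
        isolate_ids.append(cells[0])
        arow, drow, srow = [], [], []
        for cell in cells[1:]:
            if cell == ".":
                arow.append(MISSING)
                drow.append(DEPTH_UNKNOWN)
                srow.append(np.nan)
            else:
                parts = cell.split(":")
                if len(parts) != 3:
                    raise ValueError(
                        f"row {row_no}: malformed cell {cell!r} "
                        "(want allele:depth:support or '.')"
                    )
                arow.append(int(parts[0]))
                drow.append(int(parts[1]))
                srow.append(float(parts[2]))
        alleles.append(arow)
        depth.append(drow)
        support.append(srow)
    return SnpMatrix(
        isolate_ids=isolate_ids,
        locus_ids=locus_ids,
        alleles=np.array(alleles, dtype=np.int8),
        depth=np.array(depth, dtype=np.int32),
        support=np.array(support, dtype=np.float64),
        coords=coords if any(c is not None for c in coords) else None,
    )


def write_snp_matrix(m: SnpMatrix, path) -> None:
    with open(str(path), "w") as fh:
        header = ["isolate"]
        for k, name in enumerate(m.locus_ids):
            if m.coords is not None and m.coords[k] is not None:
                contig, start, end = m.coords[k]
                header.append(f"{name}@{contig}:{start}-{end}")
            else:
                header.append(name)
        fh.write("\t".join(header) + "\n")
        for i, iso in enumerate(m.isolate_ids):
            cells = [iso]
            for k in range(len(m.locus_ids)):
                a = int(m.alleles[i, k])
                if a == MISSING:
                    cells.append(".")
                else:
                    s = m.support[i, k]
                    s_str = "nan" if np.isnan(s) else format(s, "g")
                    cells.append(f"{a}:{int(m.depth[i, k])}:{s_str}")
            fh.write("\t".join(cells) + "\n")


def _read_genepop(path) -> SnpMatrix:
    """Minimal genepop reader: title line, locus names, POP blocks.

    Allele codes per locus are mapped to 0/1 by sorted code order; "00"/"000"
    encodes missing. Depth and support are unknown in this format.
    """
    raw = [ln.rstrip("\n") for ln in Path(str(path)).read_text().splitlines()]
    raw = [ln for ln in raw if ln.strip()]
    if len(raw) < 3:
        raise ValueError("genepop file too short")
    body = raw[1:]
    locus_ids: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        chunk = body[i]
        locus_ids.extend(tok.strip() for tok in chunk.split(",") if tok.strip())
        i += 1
    if i == len(body):
        raise ValueError("no POP line in genepop file")
    isolate_ids: list[str] = []
    codes: list[list[str]] = []
    for ln in body[i:]:
        if ln.strip().upper() == "POP":
            continue
        if "," not in ln:
            raise ValueError(f"malformed genepop sample line: {ln!r}")
        name, geno = ln.split(",", 1)
        toks = geno.split()
        if len(toks) != len(locus_ids):
            raise ValueError(
                f"sample {name.strip()!r}: {len(toks)} genotypes for "
                f"{len(locus_ids)} loci"
            )
        isolate_ids.append(name.strip())
        codes.append(toks)
    n, p = len(isolate_ids), len(locus_ids)
    alleles = np.full((n, p), MISSING, dtype=np.int8)
    for k in range(p):
        col = [codes[i][k] for i in range(n)]
        # haploid: one code per cell; diploid codes would be longer and are
        # not supported here
        seen = sorted({c for c in col if int(c) != 0})
        if len(seen) > 2:
            raise ValueError(
                f"locus {locus_ids[k]!r} has {len(seen)} alleles; "
                "only biallelic loci are supported"
            )
        mapping = {c: j for j, c in enumerate(seen)}
        for i in range(n):
            if int(col[i]) != 0:
                alleles[i, k] = mapping[col[i]]
    logger.warning(
        "genepop input carries no depth/support metadata; depth/support "
        "filters will be skipped"
    )
    return SnpMatrix(
        isolate_ids=isolate_ids,
        locus_ids=locus_ids,
        alleles=alleles,
        depth=np.full((n, p), DEPTH_UNKNOWN, dtype=np.int32),
        support=np.full((n, p), np.nan),
        coords=None,
    )


# ---------------------------------------------------------------------------
# Distance matrices


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n},{n})")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.allclose(self.values, self.values.T, rtol=0, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("diagonal is not zero")
        if np.any(self.values < -1e-12):
            raise ValueError("negative distances")
        # enforce exact symmetry / zero diagonal after tolerance check
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy ``squareform`` order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def restrict(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DistanceMatrix):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(
            self.values, other.values
        )


def write_distance_matrix(d: DistanceMatrix, path) -> None:
    with open(str(path), "w") as fh:
        fh.write("\t".join([""] + d.labels) + "\n")
        for i, lab in enumerate(d.labels):
            row = "\t".join(format(v, ".10g") for v in d.values[i])
            fh.write(f"{lab}\t{row}\n")


def read_distance_matrix(path) -> DistanceMatrix:
    lines = [ln for ln in Path(str(path)).read_text().splitlines() if ln.strip("\t")]
    header = lines[0].split("\t")
    labels = header[1:]
    rows = []
    row_labels = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        row_labels.append(cells[0])
        rows.append([float(v) for v in cells[1:]])
    if row_labels != labels:
        raise ValueError("row labels do not match column labels")
    values = np.array(rows)
    if not np.allclose(values, values.T, rtol=0, atol=1e-9):
        raise ValueError("asymmetric distance matrix on read")
    return DistanceMatrix(labels, values)


# ---------------------------------------------------------------------------
# Metadata


REQUIRED_METADATA_COLS = ["isolate_id", "species", "origin"]


def read_metadata(path) -> pd.DataFrame:
    """Isolate metadata TSV: isolate_id, species, origin, optional mat_type."""
    df = pd.read_csv(str(path), sep="\t", dtype=str)
    missing = [c for c in REQUIRED_METADATA_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if df["isolate_id"].duplicated().any():
        dupes = df.loc[df["isolate_id"].duplicated(), "isolate_id"].tolist()
        raise ValueError(f"duplicate isolate ids in metadata: {dupes}")
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(str(path), sep="\t", index=False)


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read a 3+-column BED file of regions to exclude (0-based half-open)."""
    regions = []
    for ln in Path(str(path)).read_text().splitlines():
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        parts = ln.split("\t")
        if len(parts) < 3:
            raise ValueError(f"BED line with fewer than 3 columns: {ln!r}")
        regions.append((parts[0], int(parts[1]), int(parts[2])))
    return regions


# ---------------------------------------------------------------------------
# Newick export


def write_newick(dendrogram, path) -> None:
    """Write a dendrogram (see :mod:`clonescan.congruence`) as Newick."""
    with open(str(path), "w") as fh:
        fh.write(dendrogram.to_newick() + "\n")
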