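"""Readers and writers for the pipeline's plain-text formats.

Counts and metadata are tab-separated; the pathway collection is standard
GMT (name TAB description TAB gene...); the DGR locus travels as FASTA (TR)
plus BED (VR intervals, 0-based half-open) with an optional two-column
TR -> VR alignment map; pileups are TSV with columns
pos, ref, depth, nA, nC, nG, nT.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dgr import DgrLocus, PileupTable, VrRegion
from .enrichment import GeneSetCollection
from .errors import ParseError
from .preprocess import ExpressionMatrix, META_COLUMNS, ZMatrix


# -- expression matrices ----------------------------------------------------

def write_counts_tsv(X: ExpressionMatrix | ZMatrix, counts_path, meta_path=None) -> None:
    df = X.values.copy()
    df.index.name = "gene_id"
    df.to_csv(counts_path, sep="\t")
    if meta_path is not None:
        X.meta.to_csv(meta_path, sep="\t")


def _read_values(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pandas raises various parse errors
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    for gene, row in df.iterrows():
        bad = row[pd.to_numeric(row, errors="coerce").isna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric value {bad.iloc[0]!r} for gene {gene!r}")
    return df.astype(float)


def read_meta_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"{path}: metadata missing columns {missing}")
    return meta


def read_counts_tsv(counts_path, meta_path) -> ExpressionMatrix:
    values = _read_values(counts_path)
    meta = read_meta_tsv(meta_path)
    try:
        return ExpressionMatrix(values, meta.loc[list(values.columns)])
    except KeyError as exc:
        raise ParseError(f"{meta_path}: metadata missing samples: {exc}") from exc


def read_zmatrix_tsv(z_path, meta_path) -> ZMatrix:
    values = _read_values(z_path)
    meta = read_meta_tsv(meta_path)
    return ZMatrix(values, meta.loc[list(values.columns)])


# -- GMT --------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has < 3 fields")
            name, desc, *genes = fields
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen = dict.fromkeys(g for g in genes if g)
            if len(seen) < len([g for g in genes if g]):
                warnings.warn(f"{path}:{lineno}: duplicate genes in set {name!r} "
                              "deduplicated", stacklevel=2)
            sets[name] = list(seen)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection.sets[name]]) + "\n")


# -- pileup -----------------------------------------------------------------

PILEUP_COLUMNS = ["pos", "ref", "depth", "nA", "nC", "nG", "nT"]


def read_pileup_tsv(path) -> PileupTable:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: pileup missing columns {missing}")
    try:
        return PileupTable(df[PILEUP_COLUMNS])
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_pileup_tsv(pileup: PileupTable, path) -> None:
    pileup.table[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


# -- DGR locus: FASTA + BED + alignment map ---------------------------------

def write_locus(locus: DgrLocus, fasta_path, bed_path, map_dir=None) -> None:
    record = SeqRecord(Seq(locus.tr_sequence), id="TR", description="template repeat")
    SeqIO.write([record], fasta_path, "fasta")
    with open(bed_path, "w") as fh:
        for vr in locus.vr_regions:
            fh.write(f"dgr_locus\t{vr.start}\t{vr.end}\t{vr.name}\t0\t{vr.strand}\n")
    if map_dir is not None:
        for name, pairs in locus.alignment_maps.items():
            with open(Path(map_dir) / f"{name}.map.tsv", "w") as fh:
                fh.write("tr_index\tvr_pos\n")
                for ti, vp in pairs:
                    fh.write(f"{ti}\t{vp}\n")


def read_locus(fasta_path, bed_path, map_paths: dict[str, str] | None = None) -> DgrLocus:
    records = list(SeqIO.parse(fasta_path, "fasta"))
    if not records:
        raise ParseError(f"{fasta_path}: no sequences")
    tr = str(records[0].seq).upper()
    regions = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ParseError(f"{bed_path}:{lineno}: BED line has < 4 fields")
            start, end = int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) > 5 else "+"
            regions.append(VrRegion(fields[3], start, end, strand))
    maps = {}
    for name, path in (map_paths or {}).items():
        df = pd.read_csv(path, sep="\t")
        maps[name] = list(zip(df.iloc[:, 0].astype(int), df.iloc[:, 1].astype(int)))
    return DgrLocus(tr_sequence=tr, vr_regions=regions, alignment_maps=maps)


# -- simple gene lists ------------------------------------------------------

def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
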