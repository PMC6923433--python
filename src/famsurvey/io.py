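"""Readers and writers: FASTA, GFF3, Newick, TSV, and packaged reference tables."""
from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import gffutils
import skbio

from .models import GeneLocus, GeneModel, ProteinRecord, chromosome_from_locus_id


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` preserving order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty FASTA file")
    first = next(i for i, ln in enumerate(text.splitlines(), 1) if ln.strip())
    if not text.splitlines()[first - 1].startswith(">"):
        raise ParseError(f"{path}: line {first}: expected '>' header")
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    return records


def write_fasta(records, path, width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_fasta_proteins(path) -> list[ProteinRecord]:
    return [ProteinRecord(name, seq) for name, seq in read_fasta(path)]


# ---------------------------------------------------------------------------
# GFF3

def _seqid_to_chromosome(seqid: str) -> int:
    m = re.fullmatch(r"(?:[Cc]hr)?0*(\d+)", seqid)
    if not m:
        raise ParseError(f"unknown seqid {seqid!r}: cannot derive chromosome number")
    return int(m.group(1))


@dataclass
class GenomeAnnotation:
    """All gene models plus the genome-wide gene ordering per chromosome."""

    models: list[GeneModel]
    loci: dict[str, GeneLocus]                 # locus_id -> GeneLocus (with ordinal)
    gene_order: dict[int, list[str]]           # chromosome -> locus ids by start

    def models_for(self, locus_id: str) -> list[GeneModel]:
        return [m for m in self.models if m.locus.locus_id == locus_id]


def read_gff3(path) -> GenomeAnnotation:
    """Parse a GFF3 file into gene models and per-chromosome gene ordinals.

    Requires gene / mRNA / exon / CDS features with Parent links; UTR
    features (five_prime_UTR / three_prime_UTR) are optional.  Coordinates
    stay 1-based inclusive.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    gene_raw: dict[str, gffutils.Feature] = {g.id: g for g in db.features_of_type("gene")}

    # genome-wide ordinals: rank among all genes per chromosome, by start
    by_chrom: dict[int, list[gffutils.Feature]] = {}
    for g in gene_raw.values():
        by_chrom.setdefault(_seqid_to_chromosome(g.seqid), []).append(g)
    loci: dict[str, GeneLocus] = {}
    gene_order: dict[int, list[str]] = {}
    for chrom, genes in sorted(by_chrom.items()):
        genes.sort(key=lambda g: (g.start, g.id))
        gene_order[chrom] = [g.id for g in genes]
        for rank, g in enumerate(genes, 1):
            parsed = chromosome_from_locus_id(g.id)
            loci[g.id] = GeneLocus(
                locus_id=g.id,
                chromosome=parsed if parsed is not None else chrom,
                start=g.start, end=g.end, strand=g.strand, ordinal=rank,
            )

    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        if not parents or parents[0] not in gene_raw:
            raise ParseError(f"mRNA {mrna.id}: missing or unknown Parent gene")
        locus = loci[parents[0]]
        kids: dict[str, list[tuple[int, int]]] = {
            "exon": [], "CDS": [], "five_prime_UTR": [], "three_prime_UTR": []
        }
        for child in db.children(mrna, level=1):
            if child.featuretype in kids:
                kids[child.featuretype].append((child.start, child.end))
        if not kids["exon"] and kids["CDS"]:
            kids["exon"] = list(kids["CDS"])  # minimal annotations omit exons
        models.append(GeneModel(
            locus=locus, mrna_id=mrna.id,
            exons=kids["exon"], cds=kids["CDS"],
            utr5=kids["five_prime_UTR"], utr3=kids["three_prime_UTR"],
        ))
    return GenomeAnnotation(models=models, loci=loci, gene_order=gene_order)


# ---------------------------------------------------------------------------
# Newick

def read_newick(path) -> skbio.TreeNode:
    try:
        return skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise ParseError(f"{path}: invalid newick ({exc})") from exc


def write_newick(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# TSV + packaged tables

def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _packaged(name: str) -> pd.DataFrame:
    with resources.files("famsurvey.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


def load_family_roster() -> pd.DataFrame:
    """The published 20-gene rice desaturase roster (names, loci, protein stats)."""
    df = _packaged("table1_loci.tsv")
    for col, typ in (("introns", int), ("size_aa", int), ("mw_da", float), ("pi", float)):
        df[col] = df[col].astype(typ)
    return df


def load_hbox_table() -> pd.DataFrame:
    """Packaged histidine-box patterns per subfamily (degenerate grammar strings)."""
    df = _packaged("hbox_patterns.tsv")
    df["box_index"] = df["box_index"].astype(int)
    return df


def load_cis_elements() -> pd.DataFrame:
    """Default cis-regulatory element table (PlantCARE-style consensi; replaceable)."""
    return _packaged("cis_elements.tsv")
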