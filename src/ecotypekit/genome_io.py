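"""Genome data model and I/O.

Internal coordinates are 0-based half-open throughout; GFF3 and the
GenBank-style feature table (both 1-based inclusive) are converted at the
boundary. Ambiguous nucleotides are excluded from both numerator and
denominator of GC fractions.
"""

from __future__ import annotations

import dataclasses
import urllib.parse
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "other")

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class GenomeIOError(ValueError):
    """Malformed genome input (coordinates, duplicate ids, bad dialect)."""


@dataclasses.dataclass
class GeneFeature:
    locus_tag: str
    contig_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'
    ftype: str  # CDS / tRNA / rRNA / other
    product: str = ""
    protein: str | None = None
    rank: int = -1  # gene-order index along the contig, set by read_genome

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"feature {self.locus_tag}: invalid span {self.start}..{self.end}"
            )
        if self.strand not in "+-":
            raise GenomeIOError(f"feature {self.locus_tag}: bad strand {self.strand!r}")
        if self.ftype not in FEATURE_TYPES:
            self.ftype = "other"
        if self.protein is not None and self.ftype != "CDS":
            raise GenomeIOError(
                f"feature {self.locus_tag}: protein on non-CDS feature"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def gc_fraction(seq: str) -> float:
    """GC over unambiguous bases only; 0.0 for a sequence with none."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    total = gc + at
    return gc / total if total else 0.0


@dataclasses.dataclass
class GenomeRecord:
    genome_id: str
    contigs: list[tuple[str, str]]
    features: list[GeneFeature]

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.contigs]
        if len(set(ids)) != len(ids):
            raise GenomeIOError(f"{self.genome_id}: duplicate contig ids")
        lens = {cid: len(seq) for cid, seq in self.contigs}
        tags = set()
        for f in self.features:
            if f.locus_tag in tags:
                raise GenomeIOError(f"{self.genome_id}: duplicate locus_tag {f.locus_tag}")
            tags.add(f.locus_tag)
            if f.contig_id not in lens:
                raise GenomeIOError(
                    f"{self.genome_id}: feature {f.locus_tag} references unknown "
                    f"contig {f.contig_id}"
                )
            if f.end > lens[f.contig_id]:
                raise GenomeIOError(
                    f"{self.genome_id}: feature {f.locus_tag} extends beyond "
                    f"contig {f.contig_id} ({f.end} > {lens[f.contig_id]})"
                )

    @property
    def mean_gc(self) -> float:
        gc = at = 0
        for _, seq in self.contigs:
            s = seq.upper()
            gc += s.count("G") + s.count("C")
            at += s.count("A") + s.count("T")
        return gc / (gc + at) if gc + at else 0.0

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    def contig_seq(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)

    def features_by_type(self, ftype: str) -> list[GeneFeature]:
        return [f for f in self.features if f.ftype == ftype]

    def feature(self, locus_tag: str) -> GeneFeature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(locus_tag)

    def stats(self) -> dict:
        """Table-3-style per-genome statistics. rRNA operons are counted as
        the number of 16S rRNA features (falling back to total rRNA count / 3
        when products carry no 16S label)."""
        rrnas = self.features_by_type("rRNA")
        n16s = sum(1 for f in rrnas if "16s" in f.product.lower())
        return {
            "genome_id": self.genome_id,
            "total_nucleotides": self.total_length,
            "gc_percent": round(100 * self.mean_gc, 2),
            "rrna_operons": n16s if n16s else len(rrnas) // 3,
            "trna": len(self.features_by_type("tRNA")),
            "predicted_proteins": len(self.features_by_type("CDS")),
        }


@dataclasses.dataclass
class Proteome:
    genome_id: str
    entries: list[tuple[str, str]]  # (locus_tag, protein sequence)

    def __post_init__(self) -> None:
        tags = [t for t, _ in self.entries]
        if len(set(tags)) != len(tags):
            raise GenomeIOError(f"{self.genome_id}: duplicate locus_tags in proteome")
        for tag, seq in self.entries:
            if not seq:
                raise GenomeIOError(f"{self.genome_id}: empty protein for {tag}")
            bad = set(seq.upper()) - AA_ALPHABET
            if bad:
                raise GenomeIOError(
                    f"{self.genome_id}: invalid residues {sorted(bad)} in {tag}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def as_dict(self) -> dict[str, str]:
        return dict(self.entries)


class EmptyProteomeError(GenomeIOError):
    pass


def translate_cds(nt_seq: str, strand: str) -> str:
    """Bacterial-code (table 11) translation of a CDS span; terminal stop
    trimmed, internal stops kept as '*' so malformed inputs stay visible."""
    seq = Seq(nt_seq)
    if strand == "-":
        seq = seq.reverse_complement()
    prot = str(seq.translate(table=11))
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


# ---------------------------------------------------------------------------
# readers


def _parse_gff3_attrs(field: str) -> dict[str, str]:
    attrs = {}
    for item in field.split(";"):
        item = item.strip()
        if not item or "=" not in item:
            continue
        k, v = item.split("=", 1)
        attrs[k] = urllib.parse.unquote(v)
    return attrs


def _read_features_gff3(path: Path) -> list[GeneFeature]:
    feats = []
    n_anon = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise GenomeIOError(f"{path}: malformed GFF3 line: {line!r}")
            contig, _src, ftype, start, end, _score, strand, _phase, attr_f = cols[:9]
            if ftype not in ("CDS", "tRNA", "rRNA"):
                if ftype in ("gene", "region", "exon", "mRNA"):
                    continue
                ftype = "other"
            attrs = _parse_gff3_attrs(attr_f)
            tag = attrs.get("locus_tag") or attrs.get("ID")
            if tag is None:
                n_anon += 1
                tag = f"feature_{n_anon:05d}"
            feats.append(
                GeneFeature(
                    locus_tag=tag,
                    contig_id=contig,
                    start=int(start) - 1,  # GFF3 is 1-based inclusive
                    end=int(end),
                    strand=strand if strand in "+-" else "+",
                    ftype=ftype,
                    product=attrs.get("product", ""),
                    protein=attrs.get("translation") if ftype == "CDS" else None,
                )
            )
    return feats


TABLE_COLUMNS = ["locus_tag", "contig_id", "start", "end", "strand", "ftype", "product", "protein"]


def _read_features_table(path: Path) -> list[GeneFeature]:
    """GenBank-style feature TSV: 1-based inclusive coordinates, columns as
    in TABLE_COLUMNS; header line required."""
    feats = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(TABLE_COLUMNS) - 2] != TABLE_COLUMNS[:-2]:
            raise GenomeIOError(
                f"{path}: expected feature-table header {TABLE_COLUMNS}, got {header}"
            )
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            cols += [""] * (len(TABLE_COLUMNS) - len(cols))
            tag, contig, start, end, strand, ftype, product, protein = cols[:8]
            feats.append(
                GeneFeature(
                    locus_tag=tag,
                    contig_id=contig,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    ftype=ftype,
                    product=product,
                    protein=protein or None if ftype == "CDS" else None,
                )
            )
    return feats


def read_genome(
    fasta_path: str | Path,
    features_path: str | Path,
    dialect: str = "gff3",
    genome_id: str | None = None,
) -> GenomeRecord:
    """Load a genome from FASTA + feature file (``gff3`` or ``genbank_table``).

    Feature ranks are assigned by coordinate sort per contig; CDS lacking a
    translation are translated from the spanned nucleotides (table 11).
    """
    fasta_path = Path(fasta_path)
    features_path = Path(features_path)
    contigs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(fasta_path), "fasta")]
    if not contigs:
        raise GenomeIOError(f"{fasta_path}: no sequences")
    if dialect == "gff3":
        feats = _read_features_gff3(features_path)
    elif dialect == "genbank_table":
        feats = _read_features_table(features_path)
    else:
        raise GenomeIOError(f"unknown dialect {dialect!r}; use 'gff3' or 'genbank_table'")
    gid = genome_id or fasta_path.stem
    genome = GenomeRecord(gid, contigs, feats)
    assign_ranks(genome)
    fill_translations(genome)
    return genome


def assign_ranks(genome: GenomeRecord) -> None:
    """Sort features by (contig order, start) and assign per-contig ranks."""
    order = {cid: i for i, (cid, _) in enumerate(genome.contigs)}
    genome.features.sort(key=lambda f: (order[f.contig_id], f.start, f.end))
    rank = 0
    last_contig = None
    for f in genome.features:
        if f.contig_id != last_contig:
            rank = 0
            last_contig = f.contig_id
        f.rank = rank
        rank += 1


def fill_translations(genome: GenomeRecord) -> None:
    for f in genome.features:
        if f.ftype == "CDS" and f.protein is None:
            nt = genome.contig_seq(f.contig_id)[f.start:f.end]
            f.protein = translate_cds(nt, f.strand)


def extract_proteome(genome: GenomeRecord) -> Proteome:
    """One entry per CDS, genome order preserved."""
    entries = []
    for f in genome.features:
        if f.ftype != "CDS":
            continue
        prot = f.protein
        if prot is None:
            nt = genome.contig_seq(f.contig_id)[f.start:f.end]
            prot = translate_cds(nt, f.strand)
        entries.append((f.locus_tag, prot))
    if not entries:
        raise EmptyProteomeError(f"{genome.genome_id}: genome has no CDS features")
    return Proteome(genome.genome_id, entries)


# ---------------------------------------------------------------------------
# writers


def write_genome_fasta(genome: GenomeRecord, path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=cid, description="") for cid, seq in genome.contigs]
    SeqIO.write(recs, str(path), "fasta")


def write_proteome_fasta(proteome: Proteome, path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=tag, description="") for tag, seq in proteome.entries]
    SeqIO.write(recs, str(path), "fasta")


def read_proteome_fasta(path: str | Path, genome_id: str | None = None) -> Proteome:
    entries = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    return Proteome(genome_id or Path(path).stem, entries)


def _gff3_escape(value: str) -> str:
    return urllib.parse.quote(value, safe=" .:^*$@!+_?|'()/-")


def write_features_gff3(genome: GenomeRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, seq in genome.contigs:
            fh.write(f"##sequence-region {cid} 1 {len(seq)}\n")
        for f in genome.features:
            attrs = [f"ID={f.locus_tag}", f"locus_tag={f.locus_tag}"]
            if f.product:
                attrs.append(f"product={_gff3_escape(f.product)}")
            if f.protein is not None:
                attrs.append(f"translation={f.protein}")
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        "ecotypekit",
                        f.ftype if f.ftype != "other" else "misc_feature",
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        "0" if f.ftype == "CDS" else ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def write_features_table(genome: GenomeRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for f in genome.features:
            fh.write(
                "\t".join(
                    [
                        f.locus_tag,
                        f.contig_id,
                        str(f.start + 1),
                        str(f.end),
                        f.strand,
                        f.ftype,
                        f.product,
                        f.protein or "",
                    ]
                )
                + "\n"
            )


ISLAND_COLUMNS = [
    "contig",
    "start",
    "end",
    "genome",
    "n_genes",
    "mean_gc",
    "gc_z",
    "trna_flank",
    "has_recombinase",
    "anchor_id",
]


def write_islands_tsv(islands: Sequence, path: str | Path) -> None:
    """BED-like island table (0-based half-open spans); header always written."""
    with open(path, "w") as fh:
        fh.write("\t".join(ISLAND_COLUMNS) + "\n")
        for isl in islands:
            fh.write(
                "\t".join(
                    [
                        isl.contig_id,
                        str(isl.start),
                        str(isl.end),
                        isl.genome_id,
                        str(isl.n_genes),
                        f"{isl.mean_gc:.4f}",
                        f"{isl.gc_z:.3f}",
                        isl.trna_flank,
                        str(int(isl.has_recombinase)),
                        isl.anchor_id,
                    ]
                )
                + "\n"
            )


def write_matrix_tsv(matrix, path: str | Path) -> None:
    """Square labelled matrix (pandas DataFrame) as TSV."""
    matrix.to_csv(path, sep="\t", index_label="")


def read_matrix_tsv(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", index_col=0)


def write_phylip(alignment, path: str | Path, partition_path: str | Path | None = None) -> None:
    """Relaxed PHYLIP (names <= 50 chars, single block) plus optional
    RAxML-style partition file ('DATA, <group> = start-end', 1-based)."""
    rows = alignment.rows
    ncols = alignment.ncols
    with open(path, "w") as fh:
        fh.write(f"{len(rows)} {ncols}\n")
        for name in sorted(rows):
            if len(name) > 50:
                raise GenomeIOError(f"taxon name too long for relaxed PHYLIP: {name}")
            fh.write(f"{name:<51s}{rows[name]}\n")
    if partition_path is not None:
        with open(partition_path, "w") as fh:
            for group_id, start, end in alignment.partitions:
                fh.write(f"DATA, {group_id} = {start + 1}-{end}\n")


def write_newick(tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_newick(path_or_string: str | Path):
    from .phylogenomics import PhyloTree

    s = str(path_or_string)
    if not s.lstrip().startswith("(") and Path(s).exists():
        s = Path(s).read_text()
    return PhyloTree.from_newick(s)


_WRITERS = {
    "aai_matrix": write_matrix_tsv,
    "matrix": write_matrix_tsv,
    "islands": write_islands_tsv,
    "tree": write_newick,
    "alignment": write_phylip,
}


def write_report(obj, path: str | Path, format: str) -> None:
    """Dispatching writer for pipeline artifacts.

    Formats: ``matrix``/``aai_matrix`` (TSV), ``islands`` (BED-like TSV),
    ``tree`` (Newick), ``alignment`` (relaxed PHYLIP; partition side-file is
    written next to it with suffix ``.partitions``).
    """
    writer = _WRITERS.get(format)
    if writer is None:
        raise GenomeIOError(
            f"unknown report format {format!r}; supported: {sorted(_WRITERS)}"
        )
    if format == "alignment":
        writer(obj, path, str(path) + ".partitions")
    else:
        writer(obj, path)
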