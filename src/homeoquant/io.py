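"""Readers and writers for FASTA, GFF3, FASTQ, SAM and the package's TSV tables.

All coordinate conversions between external formats (GFF3/SAM, 1-based) and
the internal 0-based half-open convention happen here and nowhere else.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import SubgenomeAlignment, TranscriptModel

log = logging.getLogger(__name__)

_CIGAR_NUM2OP = {0: "M", 1: "I", 2: "D", 3: "N", 4: "S", 7: "M", 8: "M"}
_CIGAR_OP2NUM = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4}


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Sequences are upper-cased; non-ACGT characters are preserved as-is.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}:{lineno}: expected FASTA header line, got "
                    f"{stripped[:30]!r}"
                )
            if len(stripped) == 1:
                raise ValueError(f"{path}:{lineno}: empty FASTA header")
            break
        else:
            log.warning("FASTA file %s is empty", path)
            return {}
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    with open(path, "w") as out:
        for name, seq in records.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[tuple[str, str, bytes]], path) -> None:
    """Write ``(read_id, sequence, phred_quals)`` triples as FASTQ."""
    with open(path, "w") as out:
        for read_id, seq, quals in reads:
            qstr = "".join(chr(q + 33) for q in quals)
            out.write(f"@{read_id}\n{seq}\n+\n{qstr}\n")


def read_fastq(path) -> list[tuple[str, str, bytes]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = bytes(rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq).upper(), quals))
    return out


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path, subgenome: str) -> list[TranscriptModel]:
    """Parse gene/mRNA/exon features into :class:`TranscriptModel` objects.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Transcripts are grouped under their parent genes; an exon whose Parent is
    not an annotated mRNA raises an error naming the offending feature.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    mrna_gene: dict[str, str] = {}
    mrna_meta: dict[str, tuple[str, str]] = {}  # id -> (contig, strand)
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [mrna.id])
        mrna_gene[mrna.id] = parents[0]
        mrna_meta[mrna.id] = (mrna.seqid, mrna.strand)
    exons_by_mrna: dict[str, list[tuple[int, int]]] = {m: [] for m in mrna_gene}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents or parents[0] not in exons_by_mrna:
            exon_id = exon.id or exon.attributes.get("ID", ["<unnamed>"])[0]
            raise ValueError(
                f"exon {exon_id} has no parent mRNA among annotated transcripts"
            )
        exons_by_mrna[parents[0]].append((exon.start - 1, exon.end))
    models = []
    for mrna_id, exons in exons_by_mrna.items():
        contig, strand = mrna_meta[mrna_id]
        models.append(
            TranscriptModel(
                gene_id=mrna_gene[mrna_id],
                transcript_id=mrna_id,
                subgenome=subgenome,
                contig=contig,
                strand=strand,
                exons=tuple(sorted(exons)),
            )
        )
    return models


def write_gff3(models: Sequence[TranscriptModel], path) -> None:
    """Write transcript models as gene/mRNA/exon GFF3 (1-based inclusive)."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for gene_id, txs in by_gene.items():
            start = min(t.exons[0][0] for t in txs)
            end = max(t.exons[-1][1] for t in txs)
            t0 = txs[0]
            out.write(
                f"{t0.contig}\thomeoquant\tgene\t{start + 1}\t{end}\t.\t"
                f"{t0.strand}\t.\tID={gene_id}\n"
            )
            for t in txs:
                out.write(
                    f"{t.contig}\thomeoquant\tmRNA\t{t.exons[0][0] + 1}\t"
                    f"{t.exons[-1][1]}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={gene_id}\n"
                )
                for i, (s, e) in enumerate(t.exons, 1):
                    out.write(
                        f"{t.contig}\thomeoquant\texon\t{s + 1}\t{e}\t.\t"
                        f"{t.strand}\t.\tID={t.transcript_id}.exon{i};"
                        f"Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def _mismatches_from_md(md: str, cigar) -> int:
    """NM-style edit count derived from an MD tag plus CIGAR indel lengths."""
    subs = len(re.findall(r"(?<!\^)[A-Z]", re.sub(r"\^[A-Z]+", "^", md)))
    dels = sum(len(run) for run in re.findall(r"\^([A-Z]+)", md))
    ins = sum(n for op, n in cigar if op == "I")
    return subs + dels + ins


def read_sam(path, subgenome: str, mapq_min: int | None = None):
    """Read SAM/BAM alignments for one subgenome.

    Returns ``(alignments, stats)`` where stats counts unmapped and
    MAPQ-filtered records.  Mismatch counts come from the NM tag, else are
    derived from MD; records with neither raise an error.
    """
    alignments: list[SubgenomeAlignment] = []
    stats = {"unmapped": 0, "mapq_filtered": 0, "parsed": 0}
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                stats["unmapped"] += 1
                continue
            if mapq_min is not None and rec.mapping_quality < mapq_min:
                stats["mapq_filtered"] += 1
                continue
            cigar = tuple(
                (_CIGAR_NUM2OP[op], n)
                for op, n in rec.cigartuples
                if op in _CIGAR_NUM2OP
            )
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            elif rec.has_tag("MD"):
                nm = _mismatches_from_md(str(rec.get_tag("MD")), cigar)
            else:
                raise ValueError(
                    f"alignment {rec.query_name} lacks both NM and MD tags; "
                    "recompute tags (e.g. samtools calmd) before classification"
                )
            mate = 0
            if rec.is_paired:
                mate = 1 if rec.is_read1 else 2
            quals = rec.query_qualities
            alignments.append(
                SubgenomeAlignment(
                    read_id=rec.query_name,
                    mate=mate,
                    subgenome=subgenome,
                    contig=rec.reference_name,
                    pos=rec.reference_start,
                    cigar=cigar,
                    mismatches=nm,
                    mapq=rec.mapping_quality,
                    seq=(rec.query_sequence or "").encode(),
                    base_quals=bytes(quals) if quals is not None else b"",
                    is_secondary=rec.is_secondary,
                    is_reverse=rec.is_reverse,
                )
            )
            stats["parsed"] += 1
    return alignments, stats


def write_sam(
    alignments: Iterable[SubgenomeAlignment],
    path,
    reference_lengths: dict[str, int],
) -> None:
    """Write alignments as plain-text SAM with NM tags."""
    refs = sorted(reference_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": reference_lengths[name]} for name in refs],
    }
    ref_index = {name: i for i, name in enumerate(refs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.read_id
            rec.reference_id = ref_index[aln.contig]
            rec.reference_start = aln.pos
            rec.mapping_quality = aln.mapq
            rec.cigartuples = [(_CIGAR_OP2NUM[op], n) for op, n in aln.cigar]
            flag = 0
            if aln.mate:
                flag |= 0x1 | (0x40 if aln.mate == 1 else 0x80)
            if aln.is_reverse:
                flag |= 0x10
            if aln.is_secondary:
                flag |= 0x100
            rec.flag = flag
            rec.query_sequence = aln.seq.decode() if aln.seq else None
            if aln.base_quals:
                rec.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in aln.base_quals)
                )
            rec.set_tag("NM", aln.mismatches)
            out.write(rec)


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_count_table(counts: pd.DataFrame, path) -> None:
    """Write a homeolog count table (columns ``sample:subgenome``)."""
    flat = counts.copy()
    flat.columns = [f"{s}:{g}" for s, g in counts.columns]
    flat.to_csv(path, sep="\t", index_label="homeolog_id")


def read_count_table(path) -> pd.DataFrame:
    flat = pd.read_csv(path, sep="\t", index_col="homeolog_id")
    cols = [tuple(c.split(":", 1)) for c in flat.columns]
    flat.columns = pd.MultiIndex.from_tuples(cols, names=["sample", "subgenome"])
    if (flat.values < 0).any():
        raise ValueError("count table contains negative values")
    return flat


def write_classifications(classifications, subgenomes, path) -> None:
    """Write per-read classifications as TSV."""
    rows = []
    for rc in classifications.values():
        row = {
            "read_id": rc.read_id,
            "label": rc.label,
            "n_informative_sites": rc.n_informative_sites,
        }
        for s in subgenomes:
            row[f"posterior:{s}"] = rc.posteriors.get(s, float("nan"))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_classifications(path):
    from .model import ReadClassification

    df = pd.read_csv(path, sep="\t")
    post_cols = [c for c in df.columns if c.startswith("posterior:")]
    out = {}
    for d in df.to_dict("records"):
        posteriors = {
            c.split(":", 1)[1]: float(d[c]) for c in post_cols if pd.notna(d[c])
        }
        out[d["read_id"]] = ReadClassification(
            read_id=d["read_id"],
            posteriors=posteriors,
            label=d["label"],
            n_informative_sites=int(d["n_informative_sites"]),
        )
    return out
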