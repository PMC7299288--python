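"""Synthetic allopolyploid data with known read origins.

The generator emulates the ground-truth designs used to benchmark subgenome
read classification: an ancestral transcript set is duplicated into two
(allotetraploid, labels H/L) or three (allohexaploid, labels A/B/D)
subgenome copies, each receiving independent substitutions at a per-copy
rate ``snp_divergence`` (so the pairwise homeolog divergence is roughly
``2 d (1 - d)``; the default 0.0125 per copy targets ~2.5% pairwise,
matching the 2-3% typically separating homeologs in recently formed
allopolyploids).  Reads of known subgenome origin are then simulated with a
uniform Phred error model, and alignments against every subgenome are
produced by coordinate lift-over through the known ancestral maps — no
external aligner is involved, and reads from regions absent in the other
homeolog (annotation asymmetry) get no cross-subgenome record.

All randomness flows from a single integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import DiscriminatingVariant, HomeologCatalog, HomeologGroup
from .model import SubgenomeAlignment, TranscriptModel, TruthTable

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TETRAPLOID_SUBGENOMES = ("H", "L")
HEXAPLOID_SUBGENOMES = ("A", "B", "D")


@dataclass(slots=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults match the benchmark design: 200 genes of ~1.5 kb, two
    subgenomes at 0.0125 substitutions per copy (~2.5% pairwise homeolog
    divergence), no indels, 100 bp paired reads at Phred 30, 100 000
    fragments per sample.
    """

    n_genes: int = 200
    gene_length_range: tuple[int, int] = (1000, 2000)
    ploidy: int = 2
    snp_divergence: float = 0.0125
    indel_rate: float = 0.0
    annotation_asymmetry: float = 0.0
    extra_exon_length: tuple[int, int] = (150, 300)
    focal_fraction: float = 0.5
    expression_dispersion: float = 1.0
    sample_divergence: float = 0.0
    read_length: int = 100
    fragment_length: int = 250
    fragment_sd: int = 30
    fragments_per_sample: int = 100_000
    base_quality: int = 30
    seed: int = 0

    def __post_init__(self):
        for rate in (
            self.snp_divergence,
            self.indel_rate,
            self.annotation_asymmetry,
            self.sample_divergence,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if not 0.0 <= self.focal_fraction <= 1.0:
            raise ValueError("focal_fraction outside [0, 1]")
        if self.ploidy not in (2, 3):
            raise ValueError("ploidy must be 2 or 3")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")

    @property
    def subgenomes(self) -> tuple[str, ...]:
        return (
            TETRAPLOID_SUBGENOMES if self.ploidy == 2 else HEXAPLOID_SUBGENOMES
        )

    @property
    def error_rate(self) -> float:
        return 10.0 ** (-self.base_quality / 10.0)


@dataclass(slots=True)
class SimGene:
    gene_id: str
    anc_len: int
    seqs: dict[str, np.ndarray]  # subgenome -> base codes (0..3)
    anc_maps: dict[str, np.ndarray]  # anc position -> sub position (-1: deleted)
    sub_maps: dict[str, np.ndarray]  # sub position -> anc position (-1: inserted)
    extra: dict[str, Optional[tuple[int, int]]]  # unalignable terminal region

    def transcript_id(self, sub: str) -> str:
        return f"{self.gene_id}_{sub}"


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _mutate_copy(anc: np.ndarray, d: float, indel_rate: float, rng):
    """One subgenome copy: substitutions plus optional short indels."""
    seq = anc.copy()
    sub_mask = rng.random(len(anc)) < d
    shifts = rng.integers(1, 4, size=int(sub_mask.sum()))
    seq[sub_mask] = (seq[sub_mask] + shifts) % 4
    if indel_rate <= 0:
        span = np.arange(len(anc), dtype=np.int64)
        return seq, span, span.copy()
    out, anc_map, sub_map = [], np.full(len(anc), -1, np.int64), []
    i = 0
    while i < len(anc):
        if rng.random() < indel_rate:
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # deletion of [i, i+length)
                i += length
                continue
            for _ in range(length):  # insertion before position i
                out.append(int(rng.integers(0, 4)))
                sub_map.append(-1)
        anc_map[i] = len(out)
        out.append(int(seq[i]))
        sub_map.append(i)
        i += 1
    return (
        np.array(out, dtype=np.uint8),
        anc_map,
        np.array(sub_map, dtype=np.int64),
    )


@dataclass(slots=True)
class SimulatedGenome:
    config: SimConfig
    genes: list[SimGene]

    @property
    def subgenomes(self) -> tuple[str, ...]:
        return self.config.subgenomes

    def sequences(self) -> dict[str, dict[str, str]]:
        """Per subgenome: transcript_id -> sequence string."""
        return {
            s: {g.transcript_id(s): _decode(g.seqs[s]) for g in self.genes}
            for s in self.subgenomes
        }

    def transcript_models(self) -> dict[str, list[TranscriptModel]]:
        """Transcript-space gene models (contig = transcript)."""
        out = {}
        for s in self.subgenomes:
            models = []
            for g in self.genes:
                tid = g.transcript_id(s)
                models.append(
                    TranscriptModel(
                        gene_id=g.gene_id,
                        transcript_id=tid,
                        subgenome=s,
                        contig=tid,
                        strand="+",
                        exons=((0, len(g.seqs[s])),),
                    )
                )
            out[s] = models
        return out

    def planted_variants(self) -> dict[str, list[DiscriminatingVariant]]:
        """Per gene: the SNP variants implied by the planted substitutions."""
        subs = self.subgenomes
        out = {}
        for g in self.genes:
            variants = []
            for p in range(g.anc_len):
                positions, alleles = {}, {}
                for s in subs:
                    sp = int(g.anc_maps[s][p])
                    if sp >= 0:
                        positions[s] = sp
                        alleles[s] = chr(_BASES[g.seqs[s][sp]])
                if len(positions) >= 2 and len(set(alleles.values())) >= 2:
                    variants.append(
                        DiscriminatingVariant(
                            kind="SNP", positions=positions, alleles=alleles
                        )
                    )
            out[g.gene_id] = variants
        return out

    def truth_catalog(self) -> HomeologCatalog:
        """The catalog implied by construction (bypasses RBH alignment)."""
        planted = self.planted_variants()
        groups = []
        for g in self.genes:
            aligned_intervals = {}
            fractions = {}
            for s in self.subgenomes:
                mapped = g.anc_maps[s]
                present = mapped[mapped >= 0]
                end = int(present.max()) + 1 if present.size else 0
                aligned_intervals[s] = ((0, end),) if end else ()
                fractions[s] = end / len(g.seqs[s]) if len(g.seqs[s]) else 0.0
            groups.append(
                HomeologGroup(
                    group_id=g.gene_id,
                    ploidy=self.config.ploidy,
                    members={s: g.transcript_id(s) for s in self.subgenomes},
                    aligned_fraction=fractions,
                    variants=planted[g.gene_id],
                    aligned_intervals=aligned_intervals,
                )
            )
        return HomeologCatalog(self.subgenomes, groups)


def simulate_subgenomes(config: SimConfig) -> SimulatedGenome:
    """Generate the subgenome copies, annotations and planted variants."""
    rng = np.random.default_rng([config.seed, 0])
    genes = []
    lo, hi = config.gene_length_range
    for i in range(config.n_genes):
        anc_len = int(rng.integers(lo, hi + 1))
        anc = rng.integers(0, 4, size=anc_len).astype(np.uint8)
        seqs, anc_maps, sub_maps, extra = {}, {}, {}, {}
        asym_sub = None
        if config.annotation_asymmetry > 0 and rng.random() < config.annotation_asymmetry:
            asym_sub = config.subgenomes[
                int(rng.integers(0, config.ploidy))
            ]
        for s in config.subgenomes:
            seq, amap, smap = _mutate_copy(
                anc, config.snp_divergence, config.indel_rate, rng
            )
            extra[s] = None
            if s == asym_sub:
                elo, ehi = config.extra_exon_length
                extra_len = int(rng.integers(elo, ehi + 1))
                extra_seq = rng.integers(0, 4, size=extra_len).astype(np.uint8)
                start = len(seq)
                seq = np.concatenate([seq, extra_seq])
                smap = np.concatenate(
                    [smap, np.full(extra_len, -1, np.int64)]
                )
                extra[s] = (start, start + extra_len)
            seqs[s], anc_maps[s], sub_maps[s] = seq, amap, smap
        genes.append(
            SimGene(
                gene_id=f"g{i + 1:05d}",
                anc_len=anc_len,
                seqs=seqs,
                anc_maps=anc_maps,
                sub_maps=sub_maps,
                extra=extra,
            )
        )
    return SimulatedGenome(config=config, genes=genes)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class ReadSet:
    sample: str
    read_length: int
    gene_idx: np.ndarray
    sub_idx: np.ndarray
    start: np.ndarray  # fragment start in source transcript coordinates
    frag_len: np.ndarray
    mate1: np.ndarray  # (n, read_length) base codes
    mate2: np.ndarray  # right end of the fragment, reference orientation
    base_quality: int

    def __len__(self):
        return len(self.gene_idx)

    def read_id(self, i: int) -> str:
        return f"{self.sample}:{i:08d}"

    def truth(self, sim: SimulatedGenome) -> TruthTable:
        subs = sim.subgenomes
        return {
            self.read_id(i): subs[self.sub_idx[i]] for i in range(len(self))
        }


def simulate_reads(
    sim: SimulatedGenome,
    n_fragments: int | None = None,
    sample: str = "s1",
    focal_fraction: float | None = None,
    seed_stream: int = 1,
) -> ReadSet:
    """Draw paired-end fragments of known subgenome origin.

    Fragment counts per gene follow a log-normal expression model; the focal
    (first) subgenome contributes a fraction ``focal_fraction`` of each
    gene's fragments, the remainder split equally among the others.
    Sequencing errors are injected per base at the Phred-implied rate.
    """
    import zlib

    config = sim.config
    rng = np.random.default_rng(
        [config.seed, seed_stream, zlib.crc32(sample.encode())]
    )
    n = n_fragments if n_fragments is not None else config.fragments_per_sample
    pi = focal_fraction if focal_fraction is not None else config.focal_fraction
    rl = config.read_length

    usable = [
        i
        for i, g in enumerate(sim.genes)
        if all(len(g.seqs[s]) >= rl for s in sim.subgenomes)
    ]
    if len(usable) < len(sim.genes):
        import logging

        logging.getLogger(__name__).warning(
            "%d genes shorter than the read length were skipped",
            len(sim.genes) - len(usable),
        )
    weights = rng.lognormal(0.0, config.expression_dispersion, size=len(usable))
    weights /= weights.sum()
    gene_idx = np.array(usable)[rng.choice(len(usable), size=n, p=weights)]

    u = rng.random(n)
    if config.ploidy == 2:
        sub_idx = (u >= pi).astype(np.int8)
    else:
        rest = (1.0 - pi) / 2.0
        sub_idx = np.select([u < pi, u < pi + rest], [0, 1], default=2).astype(
            np.int8
        )

    # per-sample source templates (optionally diverged from the reference)
    templates = {}
    for gi in usable:
        g = sim.genes[gi]
        for si, s in enumerate(sim.subgenomes):
            tmpl = g.seqs[s]
            if config.sample_divergence > 0:
                tmpl = tmpl.copy()
                mask = rng.random(len(tmpl)) < config.sample_divergence
                shift = rng.integers(1, 4, size=int(mask.sum()))
                tmpl[mask] = (tmpl[mask] + shift) % 4
            templates[(gi, si)] = tmpl

    start = np.zeros(n, dtype=np.int64)
    frag_len = np.zeros(n, dtype=np.int64)
    mate1 = np.zeros((n, rl), dtype=np.uint8)
    mate2 = np.zeros((n, rl), dtype=np.uint8)
    offsets = np.arange(rl)
    for key in sorted({(int(g), int(s)) for g, s in zip(gene_idx, sub_idx)}):
        gi, si = key
        rows = np.where((gene_idx == gi) & (sub_idx == si))[0]
        tmpl = templates[key]
        L = len(tmpl)
        fl = np.clip(
            np.round(
                rng.normal(config.fragment_length, config.fragment_sd, len(rows))
            ).astype(np.int64),
            rl,
            L,
        )
        st = rng.integers(0, L - fl + 1)
        start[rows] = st
        frag_len[rows] = fl
        mate1[rows] = tmpl[st[:, None] + offsets]
        mate2[rows] = tmpl[(st + fl - rl)[:, None] + offsets]

    e = config.error_rate
    for mates in (mate1, mate2):
        mask = rng.random(mates.shape) < e
        shift = rng.integers(1, 4, size=mates.shape).astype(np.uint8)
        mates[mask] = (mates[mask] + shift[mask]) % 4

    return ReadSet(
        sample=sample,
        read_length=rl,
        gene_idx=gene_idx.astype(np.int32),
        sub_idx=sub_idx,
        start=start,
        frag_len=frag_len,
        mate1=mate1,
        mate2=mate2,
        base_quality=config.base_quality,
    )


# ---------------------------------------------------------------------------
# Alignment projection
# ---------------------------------------------------------------------------

def _lift_cigar(g: SimGene, src: str, dst: str, start: int, end: int):
    """Lift a source-transcript interval to another subgenome copy.

    Returns ``(dst_start, cigar, n_indel_bases)`` or ``None`` when no part of
    the interval is alignable.  Walks the ancestral coordinate maps, so
    insertions/deletions between the copies become I/D CIGAR ops.
    """
    s2a = g.sub_maps[src]
    a2d = g.anc_maps[dst]
    dst_pos = [
        -1 if s2a[p] < 0 else int(a2d[s2a[p]]) for p in range(start, end)
    ]
    if all(p < 0 for p in dst_pos):
        return None
    first = next(p for p in dst_pos if p >= 0)
    ops: list[list] = []
    prev = None
    n_indel = 0
    for p in dst_pos:
        if p < 0:  # base absent in dst: insertion relative to it
            op = "I"
        elif prev is not None and prev >= 0 and p > prev + 1:
            ops.append(["D", p - prev - 1])
            n_indel += p - prev - 1
            op = "M"
        elif prev is not None and prev >= 0 and p <= prev and p != prev + 1:
            return None  # non-colinear lift; give up on this read
        else:
            op = "M"
        if op == "I":
            n_indel += 1
        if ops and ops[-1][0] == op:
            ops[-1][1] += 1
        else:
            ops.append([op, 1])
        if p >= 0:
            prev = p
    # leading/trailing insertions become soft clips so pos stays within dst
    if ops[0][0] == "I":
        ops[0][0] = "S"
        n_indel -= ops[0][1]
    if ops[-1][0] == "I":
        ops[-1][0] = "S"
        n_indel -= ops[-1][1]
    return first, tuple((op, length) for op, length in ops), n_indel


def project_alignments(
    readset: ReadSet, sim: SimulatedGenome
) -> dict[str, list[SubgenomeAlignment]]:
    """Emit per-subgenome alignments for every read by coordinate lift-over.

    Each mate gets an exact alignment to its source transcript and, where
    the homeologous copy covers the region, a lifted alignment against every
    other subgenome with the divergence-induced mismatches materialised in
    the NM count.  Mates falling entirely in regions absent from the other
    copy (annotation asymmetry) get no cross-subgenome record.
    """
    config = sim.config
    subs = sim.subgenomes
    rl = readset.read_length
    quals = bytes([readset.base_quality]) * rl
    simple_cigar = (("M", rl),)
    out: dict[str, list[SubgenomeAlignment]] = {s: [] for s in subs}
    no_indels = config.indel_rate == 0

    by_group: dict[tuple[int, int], np.ndarray] = {}
    for i in range(len(readset)):
        by_group.setdefault(
            (int(readset.gene_idx[i]), int(readset.sub_idx[i])), []
        ).append(i)

    offsets = np.arange(rl)
    for (gi, si), rows in sorted(by_group.items()):
        rows = np.asarray(rows)
        g = sim.genes[gi]
        src = subs[si]
        starts1 = readset.start[rows]
        starts2 = readset.start[rows] + readset.frag_len[rows] - rl
        m1 = readset.mate1[rows]
        m2 = readset.mate2[rows]
        for dst in subs:
            ref = sim.genes[gi].seqs[dst]
            if dst == src:
                nm1 = (m1 != ref[starts1[:, None] + offsets]).sum(axis=1)
                nm2 = (m2 != ref[starts2[:, None] + offsets]).sum(axis=1)
                for k, i in enumerate(rows):
                    rid = readset.read_id(int(i))
                    for mate, st, codes, nm in (
                        (1, starts1[k], m1[k], nm1[k]),
                        (2, starts2[k], m2[k], nm2[k]),
                    ):
                        out[dst].append(
                            SubgenomeAlignment(
                                read_id=rid,
                                mate=mate,
                                subgenome=dst,
                                contig=g.transcript_id(src),
                                pos=int(st),
                                cigar=simple_cigar,
                                mismatches=int(nm),
                                mapq=60,
                                seq=_BASES[codes].tobytes(),
                                base_quals=quals,
                                is_reverse=(mate == 2),
                            )
                        )
                continue
            # cross-subgenome lift-over
            if no_indels:
                limit = g.anc_len  # source positions beyond this are "extra"
                dst_len = g.anc_len if g.extra[dst] is None else g.extra[dst][0]
                ok1 = starts1 + rl <= min(limit, dst_len)
                ok2 = starts2 + rl <= min(limit, dst_len)
                nm1 = np.full(len(rows), -1)
                nm2 = np.full(len(rows), -1)
                if ok1.any():
                    idx = np.where(ok1)[0]
                    nm1[idx] = (
                        m1[idx] != ref[starts1[idx][:, None] + offsets]
                    ).sum(axis=1)
                if ok2.any():
                    idx = np.where(ok2)[0]
                    nm2[idx] = (
                        m2[idx] != ref[starts2[idx][:, None] + offsets]
                    ).sum(axis=1)
                for k, i in enumerate(rows):
                    rid = readset.read_id(int(i))
                    for mate, st, codes, nm, ok in (
                        (1, starts1[k], m1[k], nm1[k], ok1[k]),
                        (2, starts2[k], m2[k], nm2[k], ok2[k]),
                    ):
                        if not ok:
                            continue
                        out[dst].append(
                            SubgenomeAlignment(
                                read_id=rid,
                                mate=mate,
                                subgenome=dst,
                                contig=g.transcript_id(dst),
                                pos=int(st),
                                cigar=simple_cigar,
                                mismatches=int(nm),
                                mapq=60,
                                seq=_BASES[codes].tobytes(),
                                base_quals=quals,
                                is_reverse=(mate == 2),
                            )
                        )
            else:
                for k, i in enumerate(rows):
                    rid = readset.read_id(int(i))
                    for mate, st, codes in (
                        (1, int(starts1[k]), m1[k]),
                        (2, int(starts2[k]), m2[k]),
                    ):
                        lifted = _lift_cigar(g, src, dst, st, st + rl)
                        if lifted is None:
                            continue
                        dpos, cigar, n_indel = lifted
                        nm = n_indel
                        # count substitutions along M ops
                        qi, rp = 0, dpos
                        for op, length in cigar:
                            if op == "M":
                                nm += int(
                                    (codes[qi : qi + length] != ref[rp : rp + length]).sum()
                                )
                                qi += length
                                rp += length
                            elif op in ("I", "S"):
                                qi += length
                            else:
                                rp += length
                        out[dst].append(
                            SubgenomeAlignment(
                                read_id=rid,
                                mate=mate,
                                subgenome=dst,
                                contig=g.transcript_id(dst),
                                pos=dpos,
                                cigar=cigar,
                                mismatches=nm,
                                mapq=60,
                                seq=_BASES[codes].tobytes(),
                                base_quals=quals,
                                is_reverse=(mate == 2),
                            )
                        )
    return out


def fastq_records(readset: ReadSet, mate: int):
    """Yield ``(read_id, sequence, quals)`` for FASTQ output (mate 2 is
    reverse-complemented back to sequencing orientation)."""
    quals = bytes([readset.base_quality]) * readset.read_length
    comp = np.array([3, 2, 1, 0], dtype=np.uint8)
    mat = readset.mate1 if mate == 1 else readset.mate2
    for i in range(len(readset)):
        codes = mat[i]
        if mate == 2:
            codes = comp[codes[::-1]]
        yield f"{readset.read_id(i)}/{mate}", _decode(codes), quals


# ---------------------------------------------------------------------------
# k-mer uniqueness simulation
# ---------------------------------------------------------------------------

def _pack_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Exact 2-bit packing of all k-mers (k <= 31) into uint64 codes."""
    if k > 31:
        raise ValueError("k must be <= 31 for exact packing")
    if len(codes) < k:
        raise ValueError("sequence shorter than k")
    windows = np.lib.stride_tricks.sliding_window_view(
        codes.astype(np.uint64), k
    )
    weights = (np.uint64(4) ** np.arange(k, dtype=np.uint64))[::-1]
    return windows @ weights


def discriminating_kmer_counts(seq_a, seq_b, k: int) -> tuple[int, int]:
    """Distinct k-mers unique to each of two sequences (exact enumeration)."""

    def codes(seq):
        if isinstance(seq, np.ndarray):
            return seq
        lookup = np.zeros(256, dtype=np.uint8)
        lookup[np.frombuffer(b"ACGT", np.uint8)] = [0, 1, 2, 3]
        return lookup[np.frombuffer(seq.encode(), np.uint8)]

    ka = np.unique(_pack_kmers(codes(seq_a), k))
    kb = np.unique(_pack_kmers(codes(seq_b), k))
    return (
        int(len(np.setdiff1d(ka, kb, assume_unique=True))),
        int(len(np.setdiff1d(kb, ka, assume_unique=True))),
    )


def kmer_uniqueness_sim(
    gene_set_size: int = 100,
    trials: int = 1000,
    k: int = 31,
    divergence_grid=(0.005, 0.01, 0.015, 0.02, 0.025, 0.03),
    gene_length_range: tuple[int, int] = (1000, 2000),
    seed: int = 0,
    gene_pool: list[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Fraction of copy-discriminating k-mers versus homeolog divergence.

    Each trial samples ``gene_set_size`` genes, duplicates each and assigns
    SNPs to the copy at per-base rate d, then counts the k-mers unique to
    one copy as a fraction of each copy's distinct k-mers.  Reported per
    divergence level as mean and sd over trials.
    """
    rng = np.random.default_rng([seed, 7])
    if gene_pool is None:
        lo, hi = gene_length_range
        gene_pool = [
            rng.integers(0, 4, size=int(rng.integers(lo, hi + 1))).astype(
                np.uint8
            )
            for _ in range(max(gene_set_size * 2, 200))
        ]
    if any(len(g) < k for g in gene_pool):
        raise ValueError("k exceeds the shortest gene length")
    rows = []
    for trial in range(trials):
        chosen = rng.choice(len(gene_pool), size=gene_set_size, replace=False)
        per_d = {d: [] for d in divergence_grid}
        for gi in chosen:
            gene = gene_pool[gi]
            n_kmers = len(gene) - k + 1
            for d in divergence_grid:
                copy = gene.copy()
                mask = rng.random(len(copy)) < d
                shift = rng.integers(1, 4, size=int(mask.sum()))
                copy[mask] = (copy[mask] + shift) % 4
                ua, ub = discriminating_kmer_counts(gene, copy, k)
                per_d[d].append((ua + ub) / (2.0 * n_kmers))
        for d in divergence_grid:
            rows.append(
                {
                    "trial": trial,
                    "divergence": d,
                    "unique_fraction": float(np.mean(per_d[d])),
                }
            )
    df = pd.DataFrame(rows)
    return (
        df.groupby("divergence")["unique_fraction"]
        .agg(["mean", "std"])
        .reset_index()
    )


# ---------------------------------------------------------------------------
# Count-level simulation for ratio/DEH testing
# ---------------------------------------------------------------------------

def simulate_homeolog_counts(
    n_genes: int = 500,
    n_reps: int = 3,
    mean_depth: float = 200.0,
    pi_condition1: float = 0.5,
    pi_condition2: float = 0.5,
    de_fold: float = 1.0,
    shifted_fraction: float = 0.0,
    subgenomes=TETRAPLOID_SUBGENOMES,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Two-condition homeolog count tables with planted ratio shifts.

    A fraction ``shifted_fraction`` of genes changes its focal proportion
    from ``pi_condition1`` to ``pi_condition2`` in condition 2 and its total
    expression by ``de_fold``; the rest stay at ``pi_condition1`` with
    unchanged expression.  Returns (counts_c1, counts_c2, shifted_flags).
    """
    rng = np.random.default_rng([seed, 11])
    focal, other = subgenomes[0], subgenomes[1]
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    mu = mean_depth * rng.lognormal(0.0, 0.5, size=n_genes)
    shifted = rng.random(n_genes) < shifted_fraction

    def condition(pis, folds, prefix):
        cols = {}
        for rep in range(1, n_reps + 1):
            totals = rng.poisson(mu * folds)
            f = rng.binomial(totals, pis)
            cols[(f"{prefix}{rep}", focal)] = f
            cols[(f"{prefix}{rep}", other)] = totals - f
        df = pd.DataFrame(cols, index=gene_ids).astype(float)
        df.columns = pd.MultiIndex.from_tuples(
            df.columns, names=["sample", "subgenome"]
        )
        return df

    pis1 = np.full(n_genes, pi_condition1)
    pis2 = np.where(shifted, pi_condition2, pi_condition1)
    folds2 = np.where(shifted, de_fold, 1.0)
    c1 = condition(pis1, np.ones(n_genes), "c1r")
    c2 = condition(pis2, folds2, "c2r")
    return c1, c2, pd.Series(shifted, index=gene_ids)
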