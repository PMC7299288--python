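"""Homeolog identification by reciprocal best hit and variant enumeration.

Homeolog pairs (allotetraploid) or triples (allohexaploid) are identified by
reciprocal best hit (RBH) between the transcript sets of each subgenome,
requiring the hit E-value to beat a cutoff (default 1e-10) and at least a
minimum number of aligned bases (default 200) in *both* transcripts.  Within
each group the aligned columns are scanned for subgenome-discriminating
variants (SNPs and indels), the resource consumed by the likelihood-based
read classifier.

Pairwise transcript alignment uses an affine-gap global alignment with free
end gaps (Biopython's ``PairwiseAligner``).  E-values are approximated from
the raw score in the Karlin-Altschul form ``E = K * m * n * exp(-lambda * S)``
with fixed ungapped +1/-1 constants (lambda=1.33, K=0.621); only the relative
ordering of hits and the absolute cutoff matter for RBH.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from Bio import Align

log = logging.getLogger(__name__)

KARLIN_LAMBDA = 1.33
KARLIN_K = 0.621

GAP = "-"


@dataclass(frozen=True, slots=True)
class PairwiseHit:
    """One directional transcript-vs-transcript hit.

    ``blocks`` is a colinear list of gapless aligned segments
    ``((q_start, q_end), (t_start, t_end))`` in 0-based half-open
    coordinates of the query and target transcripts.
    """

    query_id: str
    target_id: str
    score: float
    evalue: float
    aligned_query_bases: int
    aligned_target_bases: int
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]

    def flipped(self) -> "PairwiseHit":
        """The same hit with query and target roles exchanged."""
        return PairwiseHit(
            query_id=self.target_id,
            target_id=self.query_id,
            score=self.score,
            evalue=self.evalue,
            aligned_query_bases=self.aligned_target_bases,
            aligned_target_bases=self.aligned_query_bases,
            blocks=tuple((t, q) for q, t in self.blocks),
        )


@dataclass(slots=True)
class DiscriminatingVariant:
    """A sequence difference between homeologs.

    ``positions`` gives the transcript-coordinate offset of the variant in
    each subgenome that carries it; ``alleles`` the base(s) there, with
    ``"-"`` denoting a gap (the subgenome lacks the segment).
    """

    kind: str  # SNP, insertion or deletion
    positions: dict[str, int]
    alleles: dict[str, str]

    def __post_init__(self):
        if self.kind not in ("SNP", "insertion", "deletion"):
            raise ValueError(f"bad variant kind {self.kind!r}")
        if len(set(self.alleles.values())) < 2:
            raise ValueError(
                f"variant alleles do not discriminate: {self.alleles}"
            )


@dataclass(slots=True)
class HomeologGroup:
    group_id: str
    ploidy: int
    members: dict[str, str]  # subgenome -> transcript_id
    aligned_fraction: dict[str, float] = field(default_factory=dict)
    variants: list[DiscriminatingVariant] = field(default_factory=list)
    # per member: intervals of the transcript covered by pairwise alignment
    aligned_intervals: dict[str, tuple[tuple[int, int], ...]] = field(
        default_factory=dict
    )

    def __post_init__(self):
        if len(self.members) != self.ploidy:
            raise ValueError(
                f"group {self.group_id}: {len(self.members)} members for "
                f"ploidy {self.ploidy}"
            )


class HomeologCatalog:
    """A set of homeolog groups with a transcript-level index."""

    def __init__(self, subgenomes, groups):
        from .model import validate_subgenomes

        self.subgenomes = validate_subgenomes(subgenomes)
        self.groups: list[HomeologGroup] = list(groups)
        self.by_transcript: dict[str, HomeologGroup] = {}
        for g in self.groups:
            for tid in g.members.values():
                if tid in self.by_transcript:
                    raise ValueError(
                        f"transcript {tid} appears in more than one group"
                    )
                self.by_transcript[tid] = g

    def __len__(self):
        return len(self.groups)


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

def _make_aligner(gap_open, gap_extend, match, mismatch) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    # free end gaps: local-like ends with global colinearity
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def karlin_evalue(score: float, m: int, n: int) -> float:
    log_e = math.log(KARLIN_K * m * n) - KARLIN_LAMBDA * score
    return math.exp(log_e) if log_e > -700 else 0.0


def align_transcript_pair(
    seq_a: str,
    seq_b: str,
    *,
    query_id: str = "a",
    target_id: str = "b",
    gap_open: float = 2.0,
    gap_extend: float = 1.0,
    match: float = 1.0,
    mismatch: float = -1.0,
) -> PairwiseHit:
    """Align two transcripts (affine gaps, free end gaps) into a hit."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align zero-length sequences")
    aligner = _make_aligner(gap_open, gap_extend, match, mismatch)
    aln = aligner.align(seq_a, seq_b)[0]
    a_blocks, b_blocks = aln.aligned
    blocks = tuple(
        ((int(a0), int(a1)), (int(b0), int(b1)))
        for (a0, a1), (b0, b1) in zip(a_blocks, b_blocks)
    )
    aligned = sum(a1 - a0 for (a0, a1), _ in blocks)
    return PairwiseHit(
        query_id=query_id,
        target_id=target_id,
        score=float(aln.score),
        evalue=karlin_evalue(float(aln.score), len(seq_a), len(seq_b)),
        aligned_query_bases=aligned,
        aligned_target_bases=aligned,
        blocks=blocks,
    )


# ---------------------------------------------------------------------------
# Reciprocal best hit
# ---------------------------------------------------------------------------

def _best_hits(hits) -> dict[str, PairwiseHit]:
    """Best hit per query; ties broken by lexicographic target id."""
    best: dict[str, PairwiseHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.evalue, -h.score, h.target_id) < (
            cur.evalue,
            -cur.score,
            cur.target_id,
        ):
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    hits_ab,
    hits_ba,
    evalue_max: float = 1e-10,
    min_aligned_bases: int = 200,
) -> list[tuple[str, str]]:
    """RBH pairs (a, b) passing the E-value and aligned-base filters.

    A hit enters best-hit selection only if its E-value is below
    ``evalue_max`` and both transcripts have at least ``min_aligned_bases``
    aligned bases.
    """

    def passes(h: PairwiseHit) -> bool:
        return (
            h.evalue < evalue_max
            and h.aligned_query_bases >= min_aligned_bases
            and h.aligned_target_bases >= min_aligned_bases
        )

    best_ab = _best_hits(h for h in hits_ab if passes(h))
    best_ba = _best_hits(h for h in hits_ba if passes(h))
    pairs = []
    for a, hit in sorted(best_ab.items()):
        back = best_ba.get(hit.target_id)
        if back is not None and back.target_id == a:
            pairs.append((a, hit.target_id))
    return pairs


class TripleResult(NamedTuple):
    triples: list[tuple[str, str, str]]
    two_copy: dict[tuple[str, str], list[tuple[str, str]]]


def triple_homeologs(pairs_ab, pairs_ad, pairs_bd) -> TripleResult:
    """Assemble three-copy homeologs from the three pairwise RBH lists.

    An AB pair (a, b) becomes a triple (a, b, d) iff a's AD partner and b's
    BD partner are the same transcript d.  Pairs not closing a consistent
    triangle are reported as two-copy homeologs.
    """
    ad = dict(pairs_ad)
    bd = dict(pairs_bd)
    triples = []
    leftover_ab = []
    used_ad, used_bd = set(), set()
    for a, b in pairs_ab:
        d1, d2 = ad.get(a), bd.get(b)
        if d1 is not None and d1 == d2:
            triples.append((a, b, d1))
            used_ad.add((a, d1))
            used_bd.add((b, d1))
        else:
            leftover_ab.append((a, b))
    two_copy = {
        ("A", "B"): leftover_ab,
        ("A", "D"): [p for p in pairs_ad if p not in used_ad],
        ("B", "D"): [p for p in pairs_bd if p not in used_bd],
    }
    return TripleResult(triples, two_copy)


# ---------------------------------------------------------------------------
# Variant enumeration
# ---------------------------------------------------------------------------

class CoordMap:
    """Coordinate lifting between two transcripts through alignment blocks."""

    def __init__(self, blocks):
        self._a_starts = np.array([a0 for (a0, _), _ in blocks], dtype=np.int64)
        self._a_ends = np.array([a1 for (_, a1), _ in blocks], dtype=np.int64)
        self._b_starts = np.array([b0 for _, (b0, _) in blocks], dtype=np.int64)

    def a_to_b(self, pos: int) -> Optional[int]:
        i = int(np.searchsorted(self._a_starts, pos, side="right")) - 1
        if i >= 0 and pos < self._a_ends[i]:
            return int(self._b_starts[i] + (pos - self._a_starts[i]))
        return None


def _merge_intervals(intervals):
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return tuple(merged)


def _pair_variants(seq_a, seq_b, blocks, label_a, label_b):
    """Mismatch and gap columns inside/between aligned blocks as variants.

    Adjacent gap columns are merged into single indel events.
    """
    variants = []
    for i, ((a0, a1), (b0, b1)) in enumerate(blocks):
        for off in range(a1 - a0):
            base_a, base_b = seq_a[a0 + off], seq_b[b0 + off]
            if base_a != base_b:
                variants.append(
                    DiscriminatingVariant(
                        kind="SNP",
                        positions={label_a: a0 + off, label_b: b0 + off},
                        alleles={label_a: base_a, label_b: base_b},
                    )
                )
        if i + 1 < len(blocks):
            (na0, _), (nb0, _) = blocks[i + 1]
            if na0 > a1:  # segment present in a, absent in b
                variants.append(
                    DiscriminatingVariant(
                        kind="deletion",
                        positions={label_a: a1, label_b: b1},
                        alleles={label_a: seq_a[a1:na0], label_b: GAP},
                    )
                )
            if nb0 > b1:  # segment present in b, absent in a
                variants.append(
                    DiscriminatingVariant(
                        kind="insertion",
                        positions={label_a: a1, label_b: b1},
                        alleles={label_a: GAP, label_b: seq_b[b1:nb0]},
                    )
                )
    return variants


def enumerate_variants(
    group: HomeologGroup,
    seqs: dict[str, str],
    hits: dict[tuple[str, str], PairwiseHit],
) -> HomeologGroup:
    """Fill in a group's variants, aligned fractions and aligned intervals.

    ``seqs`` maps subgenome label -> member transcript sequence; ``hits``
    maps subgenome label pairs -> the pairwise hit between the members
    (blocks in member transcript coordinates, first label = query).

    For ploidy 3, SNP columns from the three pairwise comparisons are merged
    into triple-allele variants in the frame of the first subgenome; columns
    not alignable across all members are kept as pairwise variants.
    """
    subs = [s for s in group.members if s in seqs]
    if not hits or all(not h.blocks for h in hits.values()):
        log.warning("group %s has no alignment blocks", group.group_id)
        group.variants = []
        group.aligned_fraction = {s: 0.0 for s in subs}
        group.aligned_intervals = {s: () for s in subs}
        return group

    member_intervals: dict[str, list] = {s: [] for s in subs}
    for (sa, sb), hit in hits.items():
        for (a0, a1), (b0, b1) in hit.blocks:
            member_intervals[sa].append((a0, a1))
            member_intervals[sb].append((b0, b1))
    group.aligned_intervals = {
        s: _merge_intervals(iv) for s, iv in member_intervals.items()
    }
    group.aligned_fraction = {
        s: sum(e - b for b, e in group.aligned_intervals[s]) / len(seqs[s])
        for s in subs
    }

    if group.ploidy == 2:
        (sa, sb), hit = next(iter(hits.items()))
        group.variants = _pair_variants(seqs[sa], seqs[sb], hit.blocks, sa, sb)
        return group

    # ploidy 3: merge SNP columns into the frame of the first subgenome
    s0, s1, s2 = subs
    maps = {}
    for (sa, sb), hit in hits.items():
        maps[(sa, sb)] = CoordMap(hit.blocks)
        maps[(sb, sa)] = CoordMap(tuple((t, q) for q, t in hit.blocks))

    def lift(pos, src, dst):
        if src == dst:
            return pos
        m = maps.get((src, dst))
        if m is not None:
            return m.a_to_b(pos)
        # compose through the frame subgenome
        mid = maps.get((src, s0))
        if mid is None:
            return None
        p0 = mid.a_to_b(pos)
        return None if p0 is None else maps[(s0, dst)].a_to_b(p0)

    snp_sites: dict[tuple[str, int], None] = {}
    indels = []
    for (sa, sb), hit in hits.items():
        for v in _pair_variants(seqs[sa], seqs[sb], hit.blocks, sa, sb):
            if v.kind == "SNP":
                p0 = lift(v.positions[sa], sa, s0)
                if p0 is not None:
                    snp_sites[(s0, p0)] = None
                else:
                    indels.append(v)  # unalignable in frame: keep pairwise
            else:
                indels.append(v)

    variants = []
    for (_, p0) in sorted(snp_sites):
        positions, alleles = {}, {}
        for s in subs:
            p = lift(p0, s0, s)
            if p is not None:
                positions[s] = p
                alleles[s] = seqs[s][p]
        if len(set(alleles.values())) >= 2:
            variants.append(
                DiscriminatingVariant(
                    kind="SNP", positions=positions, alleles=alleles
                )
            )
    group.variants = variants + indels
    return group


# ---------------------------------------------------------------------------
# Catalog construction
# ---------------------------------------------------------------------------

def _candidate_pairs(seqs_a, seqs_b, k=15, min_shared=10):
    """Transcript pairs sharing at least ``min_shared`` k-mers.

    Seeding step to avoid all-vs-all alignment; analogous to the seed phase
    of a local aligner.
    """
    index: dict[str, set] = {}
    for tid, seq in seqs_b.items():
        for i in range(0, len(seq) - k + 1, 4):
            index.setdefault(seq[i : i + k], set()).add(tid)
    pairs = {}
    for tid_a, seq in seqs_a.items():
        shared: dict[str, int] = {}
        for i in range(len(seq) - k + 1):
            for tid_b in index.get(seq[i : i + k], ()):
                shared[tid_b] = shared.get(tid_b, 0) + 1
        for tid_b, n in shared.items():
            if n >= min_shared:
                pairs[(tid_a, tid_b)] = n
    return sorted(pairs)


def longest_transcript_per_gene(models, seqs):
    """Pick each gene's longest transcript as its RBH representative."""
    best = {}
    for m in models:
        L = len(seqs[m.transcript_id])
        cur = best.get(m.gene_id)
        if cur is None or L > len(seqs[cur]):
            best[m.gene_id] = m.transcript_id
    return {tid: seqs[tid] for tid in best.values()}


def build_catalog(
    seqs_by_subgenome: dict[str, dict[str, str]],
    evalue_max: float = 1e-10,
    min_aligned_bases: int = 200,
    **align_kwargs,
) -> HomeologCatalog:
    """Identify homeolog groups across 2 or 3 subgenomes and their variants."""
    from .model import validate_subgenomes

    subs = validate_subgenomes(seqs_by_subgenome)
    ploidy = len(subs)
    if ploidy not in (2, 3):
        raise ValueError("catalogs support 2 or 3 subgenomes")

    hits_cache: dict[tuple[str, str], PairwiseHit] = {}
    rbh: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for i in range(ploidy):
        for j in range(i + 1, ploidy):
            sa, sb = subs[i], subs[j]
            fwd = []
            for ta, tb in _candidate_pairs(
                seqs_by_subgenome[sa], seqs_by_subgenome[sb]
            ):
                hit = align_transcript_pair(
                    seqs_by_subgenome[sa][ta],
                    seqs_by_subgenome[sb][tb],
                    query_id=ta,
                    target_id=tb,
                    **align_kwargs,
                )
                hits_cache[(ta, tb)] = hit
                fwd.append(hit)
            rbh[(sa, sb)] = reciprocal_best_hits(
                fwd,
                [h.flipped() for h in fwd],
                evalue_max=evalue_max,
                min_aligned_bases=min_aligned_bases,
            )

    groups = []
    if ploidy == 2:
        sa, sb = subs
        for n, (ta, tb) in enumerate(rbh[(sa, sb)], 1):
            g = HomeologGroup(
                group_id=f"hg{n:05d}", ploidy=2, members={sa: ta, sb: tb}
            )
            enumerate_variants(
                g,
                {sa: seqs_by_subgenome[sa][ta], sb: seqs_by_subgenome[sb][tb]},
                {(sa, sb): hits_cache[(ta, tb)]},
            )
            groups.append(g)
    else:
        sa, sb, sc = subs
        result = triple_homeologs(
            rbh[(sa, sb)], rbh[(sa, sc)], rbh[(sb, sc)]
        )
        for n, (ta, tb, tc) in enumerate(result.triples, 1):
            g = HomeologGroup(
                group_id=f"hg{n:05d}",
                ploidy=3,
                members={sa: ta, sb: tb, sc: tc},
            )
            enumerate_variants(
                g,
                {
                    sa: seqs_by_subgenome[sa][ta],
                    sb: seqs_by_subgenome[sb][tb],
                    sc: seqs_by_subgenome[sc][tc],
                },
                {
                    (sa, sb): hits_cache[(ta, tb)],
                    (sa, sc): hits_cache[(ta, tc)],
                    (sb, sc): hits_cache[(tb, tc)],
                },
            )
            groups.append(g)
    return HomeologCatalog(subs, groups)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _intervals_str(iv):
    return ";".join(f"{s}-{e}" for s, e in iv)


def _intervals_parse(text):
    if not isinstance(text, str) or not text:
        return ()
    return tuple(
        (int(s), int(e)) for s, e in (part.split("-") for part in text.split(";"))
    )


def write_catalog(catalog: HomeologCatalog, groups_path, variants_path) -> None:
    subs = catalog.subgenomes
    grows, vrows = [], []
    for g in catalog.groups:
        row = {"group_id": g.group_id, "ploidy": g.ploidy}
        for s in subs:
            row[f"member:{s}"] = g.members.get(s, "")
            row[f"aligned_fraction:{s}"] = g.aligned_fraction.get(s, float("nan"))
            row[f"aligned_intervals:{s}"] = _intervals_str(
                g.aligned_intervals.get(s, ())
            )
        grows.append(row)
        for v in g.variants:
            vrow = {"group_id": g.group_id, "kind": v.kind}
            for s in subs:
                vrow[f"pos:{s}"] = v.positions.get(s, "")
                vrow[f"allele:{s}"] = v.alleles.get(s, "")
            vrows.append(vrow)
    pd.DataFrame(grows).to_csv(groups_path, sep="\t", index=False)
    pd.DataFrame(
        vrows, columns=["group_id", "kind"]
        + [f"{f}:{s}" for s in subs for f in ("pos", "allele")],
    ).to_csv(variants_path, sep="\t", index=False)


def read_catalog(groups_path, variants_path, subgenomes) -> HomeologCatalog:
    from .model import validate_subgenomes

    subs = validate_subgenomes(subgenomes)
    gdf = pd.read_csv(groups_path, sep="\t")
    vdf = pd.read_csv(variants_path, sep="\t", keep_default_na=False)
    variants_by_group: dict[str, list[DiscriminatingVariant]] = {}
    for d in vdf.to_dict("records"):
        positions, alleles = {}, {}
        for s in subs:
            if d.get(f"pos:{s}", "") != "":
                positions[s] = int(d[f"pos:{s}"])
                alleles[s] = str(d[f"allele:{s}"])
        variants_by_group.setdefault(d["group_id"], []).append(
            DiscriminatingVariant(kind=d["kind"], positions=positions, alleles=alleles)
        )
    groups = []
    for d in gdf.to_dict("records"):
        members = {
            s: d[f"member:{s}"]
            for s in subs
            if isinstance(d.get(f"member:{s}"), str) and d[f"member:{s}"]
        }
        g = HomeologGroup(
            group_id=d["group_id"],
            ploidy=int(d["ploidy"]),
            members=members,
            aligned_fraction={
                s: float(d[f"aligned_fraction:{s}"]) for s in members
            },
            variants=variants_by_group.get(d["group_id"], []),
            aligned_intervals={
                s: _intervals_parse(d.get(f"aligned_intervals:{s}", ""))
                for s in members
            },
        )
        groups.append(g)
    return HomeologCatalog(subs, groups)
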