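"""Subgenome read classification.

Two classifiers are provided:

* **Likelihood-based** (posterior-threshold): for each fragment, the
  per-base Phred error model is evaluated at the subgenome-discriminating
  variant positions the read covers, giving a log-likelihood per subgenome
  hypothesis.  With hypotheses ``G_ref`` and alternatives sharing one
  denominator, the posterior is

      P[r in G_ref] = P[r|G_ref] / sum_G P[r|G]

  and a fragment is assigned to the winning subgenome only if its posterior
  is at least ``p_min`` (default 0.95) and the marginal probability (the
  winning posterior over the sum of all reference-hypothesis posteriors) is
  at least ``marginal_min`` (default 0.51); otherwise it is UNKNOWN.
  Fragments covering no discriminating site (or with exactly tied
  likelihoods) are COMMON.

* **Mismatch-count**: a fragment is assigned to the subgenome where it
  aligns with strictly fewest mismatches, up to a cap (default 10) beyond
  which an alignment counts as unmappable.  Fragments must be mappable to
  every subgenome to be considered; ties are COMMON.

Hexaploid (three-subgenome) classification is bottom-up from the three
pairwise comparisons, either by consensus of the pairwise labels or by the
highest three-hypothesis posterior.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .catalog import GAP, HomeologCatalog
from .model import COMMON, UNKNOWN, ReadClassification, SubgenomeAlignment

# log-likelihood contributions per Phred score; error prob clamped to 0.75
# so that q=0 bases stay uninformative rather than degenerate
_MAX_Q = 94
_ERR = np.minimum(10.0 ** (-np.arange(_MAX_Q + 1) / 10.0), 0.75)
_LOG_MATCH = np.log1p(-_ERR)
_LOG_MISMATCH = np.log(_ERR / 3.0)


@dataclass(slots=True)
class GenotypeHypothesis:
    """Expected alleles of one subgenome at the read's informative offsets."""

    subgenome: str
    expected: tuple[tuple[int, str], ...]  # (read offset, allele or "-")


def read_likelihood(
    read_bases: bytes, base_quals: bytes, hypothesis: GenotypeHypothesis
) -> Optional[float]:
    """Log-likelihood of the read under one genotype hypothesis.

    log P[r|G] = sum over informative positions of log(1 - e_i) when the read
    base matches the hypothesis allele and log(e_i / 3) otherwise, with
    e_i = 10^(-q_i/10).  A gap allele ("-", homeolog lacks the segment) is a
    mismatch against any base.  Returns ``None`` ("no information") when no
    informative position is covered; this is distinct from a log-likelihood
    of zero.
    """
    if not hypothesis.expected:
        return None
    total = 0.0
    for off, allele in hypothesis.expected:
        q = min(base_quals[off], _MAX_Q) if base_quals else 40
        if allele != GAP and read_bases[off] == ord(allele[0]):
            total += _LOG_MATCH[q]
        else:
            total += _LOG_MISMATCH[q]
    return total


def classify_posteriors(
    loglik_by_subgenome: dict[str, Optional[float]],
    p_min: float = 0.95,
    marginal_min: float = 0.51,
    read_id: str = "",
    n_informative_sites: int = 0,
) -> ReadClassification:
    """Turn per-subgenome log-likelihoods into a labelled classification.

    All hypotheses share one denominator, so for ploidy 2 this is the
    two-term posterior and for ploidy 3 the three-term posterior.  ``None``
    entries mean "no information" for that hypothesis.
    """
    if len(loglik_by_subgenome) < 2:
        raise ValueError("classification needs at least two hypotheses")
    evaluable = {s: v for s, v in loglik_by_subgenome.items() if v is not None}
    if not evaluable:
        return ReadClassification(read_id, {}, COMMON, n_informative_sites)

    subs = list(evaluable)
    lls = np.array([evaluable[s] for s in subs], dtype=float)
    probs = np.exp(lls - lls.max())
    probs /= probs.sum()
    posteriors = dict(zip(subs, probs.tolist()))

    if len(evaluable) == 1:
        # no alternative hypothesis to compare against
        return ReadClassification(read_id, posteriors, UNKNOWN, n_informative_sites)
    if np.all(lls == lls[0]):  # exactly tied: equally supported everywhere
        return ReadClassification(read_id, posteriors, COMMON, n_informative_sites)

    order = np.argsort(-probs)
    winner = subs[order[0]]
    p_win = probs[order[0]]
    marginal = p_win / probs.sum()  # reference-hypothesis posteriors sum to 1
    label = winner if (p_win >= p_min and marginal >= marginal_min) else UNKNOWN
    return ReadClassification(read_id, posteriors, label, n_informative_sites)


def classify_mismatch(
    mismatches_by_subgenome: dict[str, Optional[int]],
    max_mismatches: int = 10,
    read_id: str = "",
) -> ReadClassification:
    """Mismatch-count classification over all declared subgenomes.

    ``None`` means no alignment to that subgenome; counts above
    ``max_mismatches`` are treated as unmappable.  Fragments not mappable to
    every subgenome are UNKNOWN; strictly fewest mismatches wins and ties
    are COMMON.
    """
    if not any(v is not None for v in mismatches_by_subgenome.values()):
        raise ValueError("read is not mappable to any subgenome")
    mappable = {
        s: m
        for s, m in mismatches_by_subgenome.items()
        if m is not None and m <= max_mismatches
    }
    if len(mappable) < len(mismatches_by_subgenome):
        return ReadClassification(read_id, {}, UNKNOWN)
    best = min(mappable.values())
    winners = [s for s, m in mappable.items() if m == best]
    label = winners[0] if len(winners) == 1 else COMMON
    return ReadClassification(read_id, {}, label)


# ---------------------------------------------------------------------------
# Hexaploid bottom-up combination
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class PairwiseOutcome:
    """One pairwise comparison's result for a fragment."""

    label: str  # a subgenome label, COMMON or UNKNOWN
    logliks: dict[str, Optional[float]] = field(default_factory=dict)


def hexaploid_bottom_up(
    pairwise: dict[tuple[str, str], PairwiseOutcome],
    subgenomes: tuple[str, str, str],
    mode: str = "consensus",
    p_min: float = 0.95,
    marginal_min: float = 0.51,
    read_id: str = "",
    n_informative_sites: int = 0,
) -> ReadClassification:
    """Combine the three pairwise comparisons into one classification.

    *consensus*: a fragment is labelled X iff both pairwise comparisons
    involving X voted X (e.g. A requires an A vote in both AB and AD); all
    three COMMON gives COMMON; anything else is UNKNOWN.

    *max_posterior*: the three per-subgenome log-likelihoods are summed
    bottom-up over the pairwise comparisons (ll_A = ll_A|AB + ll_A|AD, ...)
    and thresholded through the shared three-term posterior.
    """
    if mode == "consensus":
        votes = {pair: out.label for pair, out in pairwise.items()}
        winners = []
        for s in subgenomes:
            involving = [p for p in votes if s in p]
            if len(involving) == 2 and all(votes[p] == s for p in involving):
                winners.append(s)
        if len(winners) == 1:
            label = winners[0]
        elif len(votes) == 3 and all(v == COMMON for v in votes.values()):
            label = COMMON
        else:
            label = UNKNOWN
        return ReadClassification(read_id, {}, label, n_informative_sites)

    if mode == "max_posterior":
        combined: dict[str, Optional[float]] = {}
        for s in subgenomes:
            parts = [
                out.logliks.get(s)
                for pair, out in pairwise.items()
                if s in pair and out.logliks.get(s) is not None
            ]
            combined[s] = sum(parts) if parts else None
        return classify_posteriors(
            combined, p_min, marginal_min, read_id, n_informative_sites
        )

    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Whole-sample driver
# ---------------------------------------------------------------------------

class _TranscriptSites:
    """Per-transcript discriminating-site arrays for fast lookup.

    Positions are in the coordinates of the frame transcript; alleles are
    byte codes per subgenome (0 where the subgenome lacks an allele).
    """

    __slots__ = ("positions", "alleles", "intervals")

    def __init__(self, positions, alleles, intervals):
        self.positions = positions  # sorted int64 array
        self.alleles = alleles  # {subgenome: uint8 array}
        self.intervals = intervals


def _index_catalog(catalog: HomeologCatalog) -> dict[str, _TranscriptSites]:
    index = {}
    for g in catalog.groups:
        for frame_sub, tid in g.members.items():
            usable = [
                v
                for v in g.variants
                if frame_sub in v.positions
                and len(v.positions) == g.ploidy  # complete across members
            ]
            usable.sort(key=lambda v: v.positions[frame_sub])
            positions = np.array(
                [v.positions[frame_sub] for v in usable], dtype=np.int64
            )
            alleles = {
                s: np.array(
                    [ord(v.alleles[s][0]) if v.alleles[s] else 0 for v in usable],
                    dtype=np.uint8,
                )
                for s in g.members
            }
            index[tid] = _TranscriptSites(
                positions, alleles, g.aligned_intervals.get(frame_sub, ())
            )
    return index


def _overlaps(intervals, start, end) -> bool:
    return any(s < end and start < e for s, e in intervals)


def _group_fragments(alignments_by_subgenome):
    frags: dict[str, dict[str, list[SubgenomeAlignment]]] = {}
    for sub, alns in alignments_by_subgenome.items():
        for aln in alns:
            if aln.is_secondary:
                continue
            frags.setdefault(aln.read_id, {}).setdefault(sub, []).append(aln)
    return frags


def _fragment_logliks(mates, sites_index, subgenomes):
    """Per-subgenome log-likelihoods for one fragment in one frame.

    Returns (logliks, n_sites, in_aligned_region, per_site) where per_site
    lists (site_array_index, transcript_id, contribution per subgenome) for
    pairwise restriction in the hexaploid path.
    """
    logliks: dict[str, Optional[float]] = {s: None for s in subgenomes}
    n_sites = 0
    touched_aligned = False
    per_site = []
    for aln in mates:
        sites = sites_index.get(aln.contig)
        if sites is None:
            return None, 0, False, []  # non-homeolog transcript
        start, end = aln.pos, aln.reference_end
        if _overlaps(sites.intervals, start, end):
            touched_aligned = True
        lo = int(np.searchsorted(sites.positions, start, side="left"))
        hi = int(np.searchsorted(sites.positions, end, side="left"))
        for i in range(lo, hi):
            ref_pos = int(sites.positions[i])
            off = aln.read_offset_at(ref_pos)
            if off is None or not aln.seq:
                continue
            q = min(aln.base_quals[off], _MAX_Q) if aln.base_quals else 40
            base = aln.seq[off]
            contrib = {}
            for s in subgenomes:
                code = sites.alleles[s][i]
                if code == 0:
                    continue
                if code == base:
                    val = float(_LOG_MATCH[q])
                else:
                    val = float(_LOG_MISMATCH[q])
                contrib[s] = val
                logliks[s] = val if logliks[s] is None else logliks[s] + val
            if contrib:
                n_sites += 1
                per_site.append((aln.contig, i, contrib))
    return logliks, n_sites, touched_aligned, per_site


def classify_sample(
    alignments_by_subgenome: dict[str, Iterable[SubgenomeAlignment]],
    catalog: HomeologCatalog,
    method: str = "likelihood",
    hexaploid_mode: str = "max_posterior",
    p_min: float = 0.95,
    marginal_min: float = 0.51,
    max_mismatches: int = 10,
) -> tuple[dict[str, ReadClassification], dict]:
    """Classify every fragment of a sample.

    Mates of a fragment are combined before classification (summed
    log-likelihoods / summed mismatch counts).  Fragments aligned only to
    transcripts absent from the catalog are UNKNOWN and tallied as
    non-homeolog; fragments whose alignments fall entirely outside the
    pairwise-aligned region of their homeolog group are UNKNOWN.
    """
    subs = catalog.subgenomes
    frags = _group_fragments(alignments_by_subgenome)
    out: dict[str, ReadClassification] = {}
    summary = {
        "n_fragments": len(frags),
        "n_non_homeolog": 0,
        "labels": {s: 0 for s in subs} | {COMMON: 0, UNKNOWN: 0},
    }

    if method == "mismatch":
        for read_id in frags:
            by_sub = frags[read_id]
            universal = set()
            for mates in by_sub.values():
                universal |= {a.mate for a in mates}
            mm: dict[str, Optional[int]] = {}
            for s in subs:
                mates = by_sub.get(s, [])
                if {a.mate for a in mates} != universal:
                    mm[s] = None  # a mate failed to map to this subgenome
                elif any(a.mismatches > max_mismatches for a in mates):
                    mm[s] = max_mismatches + 1  # capped: unmappable
                else:
                    mm[s] = sum(a.mismatches for a in mates)
            rc = classify_mismatch(mm, max_mismatches, read_id=read_id)
            out[read_id] = rc
            summary["labels"][rc.label] += 1
        _finalize_summary(summary)
        return out, summary

    if method != "likelihood":
        raise ValueError(f"unknown method {method!r}")

    sites_index = _index_catalog(catalog)
    pair_masks = _pairwise_site_masks(catalog) if len(subs) == 3 else None

    for read_id in frags:
        by_sub = frags[read_id]
        # frame: fewest total mismatches, ties broken by declared order
        frame = min(
            by_sub,
            key=lambda s: (sum(a.mismatches for a in by_sub[s]), subs.index(s)),
        )
        logliks, n_sites, in_aligned, per_site = _fragment_logliks(
            by_sub[frame], sites_index, subs
        )
        if logliks is None:
            rc = ReadClassification(read_id, {}, UNKNOWN, 0)
            summary["n_non_homeolog"] += 1
        elif not in_aligned:
            # read entirely in exon regions not pairwise aligned
            rc = ReadClassification(read_id, {}, UNKNOWN, 0)
        elif len(subs) == 2:
            rc = classify_posteriors(
                logliks, p_min, marginal_min, read_id, n_sites
            )
        else:
            rc = _classify_hexaploid(
                per_site,
                pair_masks,
                subs,
                hexaploid_mode,
                p_min,
                marginal_min,
                read_id,
                n_sites,
            )
        out[read_id] = rc
        summary["labels"][rc.label] += 1
    _finalize_summary(summary)
    return out, summary


def _pairwise_site_masks(catalog):
    """Per transcript, per subgenome pair: mask of sites where the pair differs."""
    masks = {}
    for g in catalog.groups:
        subs = list(g.members)
        for frame_sub, tid in g.members.items():
            usable = [
                v
                for v in g.variants
                if frame_sub in v.positions and len(v.positions) == g.ploidy
            ]
            usable.sort(key=lambda v: v.positions[frame_sub])
            tm = {}
            for sa, sb in itertools.combinations(subs, 2):
                tm[(sa, sb)] = np.array(
                    [v.alleles[sa] != v.alleles[sb] for v in usable], dtype=bool
                )
            masks[tid] = tm
    return masks


def _classify_hexaploid(
    per_site, pair_masks, subs, mode, p_min, marginal_min, read_id, n_sites
):
    pairwise: dict[tuple[str, str], PairwiseOutcome] = {}
    for sa, sb in itertools.combinations(subs, 2):
        lls: dict[str, Optional[float]] = {sa: None, sb: None}
        for tid, i, contrib in per_site:
            mask = pair_masks[tid][(sa, sb)]
            if i < len(mask) and mask[i]:
                for s in (sa, sb):
                    if s in contrib:
                        lls[s] = (
                            contrib[s]
                            if lls[s] is None
                            else lls[s] + contrib[s]
                        )
        outcome = PairwiseOutcome(label=COMMON, logliks=lls)
        if any(v is not None for v in lls.values()):
            outcome.label = classify_posteriors(
                lls, p_min, marginal_min, read_id
            ).label
        pairwise[(sa, sb)] = outcome
    return hexaploid_bottom_up(
        pairwise,
        tuple(subs),
        mode=mode,
        p_min=p_min,
        marginal_min=marginal_min,
        read_id=read_id,
        n_informative_sites=n_sites,
    )


def _finalize_summary(summary):
    labels = summary["labels"]
    n = summary["n_fragments"]
    classified = sum(
        c for lab, c in labels.items() if lab not in (COMMON, UNKNOWN)
    )
    summary["n_classified"] = classified
    summary["classified_pct"] = 100.0 * classified / n if n else 0.0
    summary["common_pct"] = 100.0 * labels[COMMON] / n if n else 0.0
    summary["unknown_pct"] = 100.0 * labels[UNKNOWN] / n if n else 0.0
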