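"""Integration-product fidelity metrics.

Four read-level measures of how clean the integration chemistry is:

* ``quantify_indels`` — indel frequency among unintegrated amplicon reads
  within a 40-bp window centered at the predicted insertion site;
* ``tsd_substitution_rate`` — fraction of junction reads carrying at least
  one substitution within the target-site duplication (TSD), a footprint of
  gap repair after the staggered TnsB transesterifications;
* ``integration_fraction`` — read-count proxy for integration efficiency;
* ``classify_long_read`` — simple insertion vs cointegrate, the latter
  recognized by retained donor backbone or an extra transposon-end copy.
"""

from __future__ import annotations

import edlib
import numpy as np
from Bio import Align

from .errors import EmptyInputError, InvalidArgumentError
from .seq import revcomp
from .simulate import (
    DEFAULT_OFFSET_BP,
    DEFAULT_TSD_LEN,
    oriented_sequence,
    oriented_three_prime,
)
from .types import (
    DonorConfig,
    GenomeRef,
    IndelCall,
    JunctionCall,
    LongReadClass,
    TargetSite,
)

# Free-parameter alignment scoring for amplicon/read global alignment;
# ties resolve to the aligner's first reported (leftmost-gap) alignment.
MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_OPEN = -4
GAP_EXTEND = -1


def _amplicon_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    # The read is a sub-slice of the amplicon: the amplicon overhangs
    # (deletions relative to the target) are free at both ends, while
    # read end gaps stay penalized.
    aligner.open_left_deletion_score = 0
    aligner.extend_left_deletion_score = 0
    aligner.open_right_deletion_score = 0
    aligner.extend_right_deletion_score = 0
    return aligner


def read_gaps(read: str, amplicon_seq: str) -> list[tuple[str, int, int]]:
    """Gaps in the read/amplicon alignment as (kind, amplicon_column, length).

    ``deletion`` gaps span amplicon columns [column, column+length);
    ``insertion`` gaps attach all inserted read bases to the single
    amplicon column before which they sit.
    """
    aligner = _amplicon_aligner()
    alignment = next(iter(aligner.align(amplicon_seq, read)))
    blocks_t, blocks_q = alignment.aligned
    gaps = []
    for i in range(1, len(blocks_t)):
        t_gap = blocks_t[i][0] - blocks_t[i - 1][1]
        q_gap = blocks_q[i][0] - blocks_q[i - 1][1]
        if t_gap > 0:
            gaps.append(("deletion", int(blocks_t[i - 1][1]), int(t_gap)))
        if q_gap > 0:
            gaps.append(("insertion", int(blocks_t[i - 1][1]), int(q_gap)))
    return gaps


def quantify_indels(
    unintegrated_reads,
    amplicon: GenomeRef,
    site: TargetSite,
    window: int = 40,
    predicted_offset: int = DEFAULT_OFFSET_BP,
    center: int | None = None,
) -> tuple[float, list[IndelCall]]:
    """Indel frequency among unintegrated reads near the insertion site.

    Each read is globally aligned to the (oriented) amplicon; a read is
    indel-positive when any alignment gap overlaps the half-open window
    ``[center − window/2, center + window/2)``. The center defaults to the
    target 3' end plus ``predicted_offset`` (ideally the modal junction
    distance measured on the same sample); pass ``center`` to override.
    Returns ``(frequency, calls)`` with one call per gap.
    """
    if window < 2 or window % 2 != 0:
        raise InvalidArgumentError("window must be even and >= 2")
    if window > len(amplicon):
        raise InvalidArgumentError("window larger than the amplicon")
    reads = list(unintegrated_reads)
    if not reads:
        raise EmptyInputError("no unintegrated reads")
    oseq = oriented_sequence(amplicon, site)
    if center is None:
        center = oriented_three_prime(site, len(amplicon)) + predicted_offset
    half = window // 2
    lo, hi = center - half, center + half

    # Unintegrated reads span the insertion site by contract, so alignment
    # is restricted to the window neighbourhood (read length + slack on
    # each side) — identical placements, much less DP.
    max_read = max(len(t[1]) for t in reads)
    region_lo = max(0, lo - max_read - 60)
    region_hi = min(len(oseq), hi + max_read + 60)
    region = oseq[region_lo:region_hi]

    calls: list[IndelCall] = []
    positives = 0
    for tup in reads:
        rid, seq = tup[0], tup[1]
        read_hit = False
        for kind, rcol, length in read_gaps(seq, region):
            col = rcol + region_lo
            span = range(col, col + length) if kind == "deletion" else [col]
            in_window = any(lo <= c < hi for c in span)
            read_hit = read_hit or in_window
            calls.append(IndelCall(read_id=rid, kind=kind, length=length,
                                   center_offset=col - center,
                                   in_window=in_window))
        positives += read_hit
    return positives / len(reads), calls


def tsd_substitution_rate(
    calls: list[JunctionCall],
    ref: GenomeRef,
    site: TargetSite,
    tsd_len: int = DEFAULT_TSD_LEN,
) -> dict:
    """Fraction of evaluable junction reads with >= 1 TSD substitution.

    Only downstream-side junction reads carry the repaired (gap-filled)
    TSD copy at the start of their genomic flank; their TSD bases are
    compared against the reference bases at the called junction. Reads
    whose flank truncates the TSD are excluded and counted. Raw sequencing
    errors are not deconvolved from true substitutions.
    """
    oseq = oriented_sequence(ref, site)
    evaluated = substituted = excluded = 0
    for call in calls:
        if call.side != "downstream":
            continue
        if len(call.flank_seq) < tsd_len:
            excluded += 1
            continue
        read_tsd = call.flank_seq[:tsd_len]
        ref_tsd = oseq[call.junction_pos:call.junction_pos + tsd_len]
        if len(ref_tsd) < tsd_len:
            excluded += 1
            continue
        evaluated += 1
        if read_tsd != ref_tsd:
            substituted += 1
    rate = substituted / evaluated if evaluated else float("nan")
    return {"rate": rate, "evaluated": evaluated,
            "substituted": substituted, "excluded": excluded}


def integration_fraction(read_class_counts: dict) -> dict:
    """Read-level integration fraction from the conservation partition.

    junction-called / (junction-called + unintegrated-candidate); the
    excluded categories are reported alongside, never folded in.
    """
    called = read_class_counts.get("junction-called", 0)
    unint = read_class_counts.get("unintegrated-candidate", 0)
    if called + unint == 0:
        raise EmptyInputError("no classifiable reads")
    excluded = {k: v for k, v in read_class_counts.items()
                if k not in ("junction-called", "unintegrated-candidate") and v}
    return {"fraction": called / (called + unint),
            "n_integrated": called, "n_unintegrated": unint,
            "excluded": excluded}


def _find_hits(anchor: str, seq: str, max_edit: int) -> list[tuple[int, int, int]]:
    """All non-overlapping placements of ``anchor`` in ``seq`` with edit
    distance <= max_edit, found by iteratively masking best hits."""
    hits: list[tuple[int, int, int]] = []
    work = seq
    while True:
        res = edlib.align(anchor, work, mode="HW", task="locations", k=max_edit)
        if res["editDistance"] == -1:
            break
        d = res["editDistance"]
        locs = sorted((s, e) for s, e in res["locations"])
        kept = []
        for s, e in locs:
            if kept and s <= kept[-1][1]:
                continue
            kept.append((s, e))
        for s, e in kept:
            hits.append((s, e + 1, d))
            work = work[:s] + "#" * (e + 1 - s) + work[e + 1:]
    return sorted(hits)


def classify_long_read(
    read_tuple,
    donor: DonorConfig,
    anchor_len: int = 20,
    max_edit: int = 2,
    backbone_anchor_len: int = 30,
) -> LongReadClass:
    """Classify a long read as simple insertion, cointegrate, or unclassified.

    Simple: exactly one right-end and one left-end copy, no donor backbone.
    Cointegrate: backbone detected, or an extra copy of a transposon end.
    Detection counts bounded-edit placements of the end-terminal anchors
    and a backbone-internal anchor, on the forward read first and on its
    reverse complement if the forward strand shows no evidence.
    """
    rid, seq = read_tuple[0], read_tuple[1]
    if not donor.backbone and backbone_anchor_len:
        backbone_anchor = ""
    else:
        mid = max(0, len(donor.backbone) // 2 - backbone_anchor_len // 2)
        backbone_anchor = donor.backbone[mid:mid + backbone_anchor_len]

    def survey(s: str) -> dict:
        out = {
            "RE": len(_find_hits(donor.right_end[:anchor_len], s, max_edit)),
            "LE": len(_find_hits(donor.left_end[-anchor_len:], s, max_edit)),
            "cargo": len(_find_hits(
                donor.cargo[len(donor.cargo) // 2:
                            len(donor.cargo) // 2 + anchor_len], s, max_edit))
            if len(donor.cargo) >= anchor_len else 0,
            "backbone": len(_find_hits(backbone_anchor, s, max_edit))
            if backbone_anchor else 0,
        }
        return out

    counts = survey(seq)
    if sum(counts.values()) == 0:
        counts = survey(revcomp(seq))
    evidence = tuple(sorted(k for k, v in counts.items() if v))
    if counts["backbone"] > 0:
        return LongReadClass(rid, "cointegrate", evidence + ("extra-end",)
                             if counts["RE"] > 1 or counts["LE"] > 1
                             else evidence)
    if counts["RE"] > 1 or counts["LE"] > 1:
        return LongReadClass(rid, "cointegrate", evidence + ("extra-end",))
    if counts["RE"] == 1 and counts["LE"] == 1:
        return LongReadClass(rid, "simple", evidence)
    return LongReadClass(rid, "unclassified", evidence)


def simple_fraction(classes: list[LongReadClass]) -> dict:
    """Fraction of classified long reads labeled simple insertions."""
    n_simple = sum(c.label == "simple" for c in classes)
    n_coint = sum(c.label == "cointegrate" for c in classes)
    n_uncls = sum(c.label == "unclassified" for c in classes)
    classified = n_simple + n_coint
    if classified == 0:
        raise EmptyInputError("no classified long reads")
    return {"fraction": n_simple / classified, "n_simple": n_simple,
            "n_cointegrate": n_coint, "n_unclassified": n_uncls}
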