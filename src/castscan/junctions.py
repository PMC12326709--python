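"""Transposon-end/genome junction calling on amplicon reads.

A junction read contains a contiguous genomic flank joined to transposon
sequence. The caller (1) locates a transposon-end anchor in the read among
the four junction-adjacent candidates — right-end prefix (forward),
left-end suffix reverse-complemented (upstream-side T-LR), left-end suffix
(downstream-side T-RL) and right-end prefix reverse-complemented — using
bounded edit distance; (2) maps the genomic flank to the reference (exact
match first, then edit-bounded infix alignment); and (3) reports the
junction coordinate as the first base of the target-site duplication (TSD),
its signed distance to the target 3' end, and the orientation call.

All coordinates here live in the oriented frame (reference read along the
target strand), which makes distance and orientation invariant under
reverse-complementing the reference and flipping the site strand.
"""

from __future__ import annotations

from collections import Counter

import edlib
import numpy as np
import pandas as pd

from .errors import (
    AmbiguousMatchError,
    EmptyInputError,
    InconsistentJunctionsError,
    InvalidArgumentError,
    MultimapError,
    TooShortError,
    UnmappedFlankError,
)
from .seq import find_all_exact, revcomp
from .simulate import DEFAULT_TSD_LEN, oriented_sequence, oriented_three_prime
from .types import (
    ORIENT_TLR,
    ORIENT_TRL,
    DonorConfig,
    EndMatch,
    GenomeRef,
    JunctionCall,
    TargetSite,
)

DEFAULT_ANCHOR_LEN = 20
DEFAULT_MAX_EDIT = 2


def junction_anchors(donor: DonorConfig, anchor_len: int) -> list[tuple]:
    """The four junction-adjacent anchors as (seq, end, orient, side)."""
    if anchor_len > min(len(donor.right_end), len(donor.left_end)):
        raise InvalidArgumentError("anchor_len exceeds a transposon end length")
    re_, le = donor.right_end, donor.left_end
    return [
        (re_[:anchor_len], "right", "forward", "upstream"),     # T-RL upstream
        (revcomp(le[-anchor_len:]), "left", "revcomp", "upstream"),   # T-LR upstream
        (le[-anchor_len:], "left", "forward", "downstream"),    # T-RL downstream
        (revcomp(re_[:anchor_len]), "right", "revcomp", "downstream"),  # T-LR downstream
    ]


def _best_locations(result: dict) -> list[tuple[int, int]]:
    """Edlib HW locations deduplicated to non-overlapping placements."""
    locs = sorted((s, e) for s, e in result["locations"])
    kept: list[tuple[int, int]] = []
    for s, e in locs:
        if kept and s <= kept[-1][1]:
            continue
        kept.append((s, e))
    return kept


def locate_transposon_end(
    read: str,
    donor: DonorConfig,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    max_edit: int = DEFAULT_MAX_EDIT,
    read_id: str = "",
) -> EndMatch | None:
    """Best transposon-end anchor match in a read, or None.

    Searches all four junction-adjacent anchors with edit distance bounded
    by ``max_edit``. A tie at the best edit distance between the two end
    identities raises :class:`AmbiguousMatchError`; ties within one anchor
    resolve to the leftmost placement.
    """
    if max_edit < 0:
        raise InvalidArgumentError("max_edit must be >= 0")
    best: list[tuple] = []
    best_dist = max_edit + 1
    for anchor, end, orient, side in junction_anchors(donor, anchor_len):
        res = edlib.align(anchor, read, mode="HW", task="locations", k=max_edit)
        if res["editDistance"] == -1:
            continue
        d = res["editDistance"]
        if d < best_dist:
            best_dist, best = d, []
        if d == best_dist:
            s, e = _best_locations(res)[0]
            best.append((end, orient, side, s, e + 1))
    if not best:
        return None
    if len({end for end, *_ in best}) > 1:
        raise AmbiguousMatchError(
            f"read {read_id or '<anon>'}: right and left ends tie at edit "
            f"distance {best_dist}"
        )
    end, orient, side, s, e = best[0]
    return EndMatch(read_id=read_id, end=end, end_orient=orient,
                    read_offset=s, read_end=e, edit_distance=best_dist,
                    side=side)


def map_sequence(
    query: str,
    target: str,
    max_edit: int = DEFAULT_MAX_EDIT,
) -> tuple[int, int]:
    """Unique best placement of ``query`` within ``target`` (forward only).

    Returns ``(start, edit_distance)``. Exact occurrences are sought first;
    failing that, an edit-bounded infix alignment over the whole target.
    Raises :class:`MultimapError` on multiple equally good placements and
    :class:`UnmappedFlankError` when nothing is within the bound.
    """
    exact = find_all_exact(query, target)
    if len(exact) == 1:
        return exact[0], 0
    if len(exact) > 1:
        raise MultimapError(f"{len(exact)} exact placements")
    res = edlib.align(query, target, mode="HW", task="locations", k=max_edit)
    if res["editDistance"] == -1:
        raise UnmappedFlankError("no placement within the edit bound")
    locs = _best_locations(res)
    if len(locs) > 1:
        raise MultimapError(f"{len(locs)} placements at edit distance "
                            f"{res['editDistance']}")
    s, e = locs[0]
    return s, res["editDistance"]


def call_junction(
    read: str,
    match: EndMatch,
    ref: GenomeRef,
    site: TargetSite,
    min_flank: int = 20,
    tsd_len: int = DEFAULT_TSD_LEN,
    max_edit: int = DEFAULT_MAX_EDIT,
) -> JunctionCall:
    """Resolve an end-matched read into a junction call.

    Upstream-side reads place the flank before the anchor; its last mapped
    base is the last base of the upstream TSD copy, so the first TSD base
    sits ``tsd_len − 1`` before it. Downstream-side reads place the flank
    after the anchor and it starts directly on the first base of the
    downstream TSD copy.
    """
    L = len(ref)
    oref = oriented_sequence(ref, site)
    o3 = oriented_three_prime(site, L)
    if match.side == "upstream":
        flank = read[:match.read_offset]
    else:
        flank = read[match.read_end:]
    if len(flank) < min_flank:
        raise TooShortError(
            f"flank {len(flank)} bp < min_flank {min_flank}"
        )
    pos, _ = map_sequence(flank, oref, max_edit=max_edit)
    if match.side == "upstream":
        boundary = pos + len(flank) - 1          # last genomic base before tx
        junction_pos = boundary - tsd_len + 1
    else:
        boundary = pos                           # first genomic base after tx
        junction_pos = boundary
    if (match.side, match.end) in (("upstream", "right"), ("downstream", "left")):
        orientation = ORIENT_TRL
    else:
        orientation = ORIENT_TLR
    return JunctionCall(
        read_id=match.read_id, ref_name=ref.name,
        junction_pos=junction_pos, end=match.end,
        end_orient=match.end_orient, side=match.side,
        boundary_pos=boundary, distance_bp=junction_pos - o3,
        orientation_call=orientation, flank_seq=flank,
    )


def partition_reads(
    reads,
    donor: DonorConfig,
    ref: GenomeRef,
    site: TargetSite,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    max_edit: int = DEFAULT_MAX_EDIT,
    min_flank: int = 20,
    tsd_len: int = DEFAULT_TSD_LEN,
) -> tuple[list[JunctionCall], list, dict]:
    """Assign every read exactly one outcome.

    Returns ``(calls, unintegrated, counts)`` where ``counts`` maps each
    category — junction-called, unintegrated-candidate, ambiguous,
    multimap, too-short, unmatched — to its read count; the categories sum
    to the input size (the conservation invariant). ``unintegrated`` holds
    the (id, seq) pairs with no transposon anchor.
    """
    calls: list[JunctionCall] = []
    unintegrated: list[tuple[str, str]] = []
    counts = Counter({k: 0 for k in (
        "junction-called", "unintegrated-candidate", "ambiguous",
        "multimap", "too-short", "unmatched")})
    for tup in reads:
        rid, seq = tup[0], tup[1]
        try:
            match = locate_transposon_end(seq, donor, anchor_len, max_edit,
                                          read_id=rid)
        except AmbiguousMatchError:
            counts["ambiguous"] += 1
            continue
        if match is None:
            counts["unintegrated-candidate"] += 1
            unintegrated.append((rid, seq))
            continue
        try:
            calls.append(call_junction(seq, match, ref, site,
                                       min_flank=min_flank, tsd_len=tsd_len,
                                       max_edit=max_edit))
            counts["junction-called"] += 1
        except MultimapError:
            counts["multimap"] += 1
        except TooShortError:
            counts["too-short"] += 1
        except UnmappedFlankError:
            counts["unmatched"] += 1
    return calls, unintegrated, dict(counts)


def distance_profile(calls: list[JunctionCall]) -> tuple[pd.DataFrame, int]:
    """Integer-binned histogram of junction distances and the modal distance.

    Ties at the maximal count break toward the smaller distance.
    """
    if not calls:
        raise EmptyInputError("no junction calls")
    distances = pd.Series([c.distance_bp for c in calls], name="count")
    hist = distances.value_counts().sort_index()
    table = hist.rename_axis("distance_bp").reset_index()
    mode = int(table.loc[table["count"] == table["count"].max(),
                         "distance_bp"].min())
    return table, mode


def classify_orientation_bulk(calls: list[JunctionCall]) -> dict:
    """Orientation fractions over classified reads.

    Fractions of T-RL and T-LR sum to 1 over reads with a definite call;
    the ambiguous count is reported separately, not folded in.
    """
    if not calls:
        raise EmptyInputError("no junction calls")
    n_trl = sum(c.orientation_call == ORIENT_TRL for c in calls)
    n_tlr = sum(c.orientation_call == ORIENT_TLR for c in calls)
    n_amb = len(calls) - n_trl - n_tlr
    classified = n_trl + n_tlr
    if classified == 0:
        raise EmptyInputError("no orientation-classified calls")
    return {
        ORIENT_TRL: n_trl / classified,
        ORIENT_TLR: n_tlr / classified,
        "ambiguous": n_amb,
        "n_classified": classified,
    }


def _mode_int(values) -> int:
    counts = Counter(values)
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)


def infer_tsd(
    upstream_calls: list[JunctionCall],
    downstream_calls: list[JunctionCall],
    pairing: str = "population",
    pair_window: int = 25,
) -> tuple[int, tuple[int, int]]:
    """Infer the TSD length from paired junction boundaries.

    With ``p_L`` the last genomic base before the transposon (upstream side)
    and ``p_R`` the first genomic base after it (downstream side),
    ``tsd_len = p_L − p_R + 1``. ``population`` mode takes the modal
    boundary on each side; ``per-event`` groups boundaries into loci within
    ``pair_window`` and takes the modal per-locus length. Returns the
    length and the consensus TSD interval ``[p_R, p_L + 1)``.

    An inferred length below −1 (more than a blunt joint apart) raises
    :class:`InconsistentJunctionsError`.
    """
    if not upstream_calls or not downstream_calls:
        raise EmptyInputError("need at least one call on each side")
    p_l = [c.boundary_pos for c in upstream_calls]
    p_r = [c.boundary_pos for c in downstream_calls]
    if pairing == "population":
        mode_l, mode_r = _mode_int(p_l), _mode_int(p_r)
        tsd_len = mode_l - mode_r + 1
        interval = (mode_r, mode_l + 1)
    elif pairing == "per-event":
        # group boundaries from both sides into loci (gap > pair_window
        # starts a new locus), then take modal boundaries per locus
        tagged = sorted([(p, "L") for p in p_l] + [(p, "R") for p in p_r])
        loci: list[list] = [[]]
        for p, tag in tagged:
            if loci[-1] and p - loci[-1][-1][0] > pair_window:
                loci.append([])
            loci[-1].append((p, tag))
        lengths = []
        for locus in loci:
            ls = [p for p, t in locus if t == "L"]
            rs = [p for p, t in locus if t == "R"]
            if ls and rs:
                lengths.append(_mode_int(ls) - _mode_int(rs) + 1)
        if not lengths:
            raise EmptyInputError("no locus with junctions on both sides")
        tsd_len = _mode_int(lengths)
        interval = (0, 0)
    else:
        raise InvalidArgumentError(f"unknown pairing mode {pairing!r}")
    if tsd_len < -1:
        raise InconsistentJunctionsError(
            f"inferred TSD length {tsd_len} < -1"
        )
    return tsd_len, interval
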