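"""UDiTaS-style genome-wide integration-site discovery.

Unidirectional UMI-tagged reads (UMI + transposon-end anchor + genomic
flank) are processed in four steps: UMI extraction and anchor trimming,
flank mapping, site clustering with per-site UMI deduplication, and
on/off-target labeling with a target-homology scan. Deduplicated UMI
counts approximate independent integration events; an off-target site
supported by a single UMI represents a single integration event.
"""

from __future__ import annotations

from collections import Counter

import edlib
import numpy as np
from Bio import Align

from .errors import EmptyInputError, InvalidArgumentError
from .seq import find_all_exact, revcomp
from .simulate import DEFAULT_OFFSET_BP, expected_insertion_position
from .types import GenomeRef, SiteCluster, TargetSite, UmiRead


def extract_umi(
    read_tuple,
    umi_len: int = 12,
    anchor: str = "",
    max_edit: int = 2,
) -> UmiRead | None:
    """Split a read into UMI, transposon-end anchor, and genomic flank.

    The first ``umi_len`` bases are the UMI; the anchor must follow
    immediately, matched as a prefix alignment within ``max_edit`` edits.
    Returns None (rejected) when the read is too short or the anchor is
    not found.
    """
    if umi_len < 6:
        raise InvalidArgumentError("umi_len must be >= 6")
    if not anchor:
        raise InvalidArgumentError("anchor sequence required")
    rid, seq = read_tuple[0], read_tuple[1]
    if len(seq) <= umi_len + len(anchor):
        return None
    umi = seq[:umi_len]
    rest = seq[umi_len:]
    res = edlib.align(anchor, rest, mode="SHW", task="locations", k=max_edit)
    if res["editDistance"] == -1:
        return None
    end = min(e for _, e in res["locations"])
    return UmiRead(read_id=rid, umi=umi, flank=rest[end + 1:])


def map_flank(
    flank: str,
    ref: GenomeRef,
    seed_len: int = 15,
    max_edit: int = 2,
) -> tuple[int, str] | str:
    """Place a unidirectional flank on the reference.

    Returns ``(position, strand)`` where position is the plus-strand
    coordinate of the *first flank base* (the insertion-adjacent base), or
    the string ``"unmapped"`` / ``"multimapped"``. Exact search on both
    strands first; then edit-bounded infix alignment over the whole
    reference.
    """
    if len(flank) < seed_len:
        return "unmapped"
    seq = ref.sequence
    fwd = find_all_exact(flank, seq)
    rev = find_all_exact(revcomp(flank), seq)
    n_exact = len(fwd) + len(rev)
    if n_exact == 1:
        if fwd:
            return fwd[0], "+"
        return rev[0] + len(flank) - 1, "-"
    if n_exact > 1:
        return "multimapped"

    candidates = []
    best = max_edit + 1
    for strand, query in (("+", flank), ("-", revcomp(flank))):
        res = edlib.align(query, seq, mode="HW", task="locations", k=max_edit)
        if res["editDistance"] == -1:
            continue
        d = res["editDistance"]
        locs = sorted((s, e) for s, e in res["locations"])
        kept = []
        for s, e in locs:
            if kept and s <= kept[-1][1]:
                continue
            kept.append((s, e))
        if d < best:
            best, candidates = d, []
        if d == best:
            candidates.extend((strand, s, e) for s, e in kept)
    if not candidates:
        return "unmapped"
    if len(candidates) > 1:
        return "multimapped"
    strand, s, e = candidates[0]
    return (s, "+") if strand == "+" else (e, "-")


def collapse_umis(umis: list[str], max_hamming: int = 1) -> int:
    """Deduplicated UMI count under single-linkage Hamming clustering.

    UMIs within ``max_hamming`` substitutions are linked; the count is the
    number of connected components. Empty input collapses to 0.
    """
    if not umis:
        return 0
    if len({len(u) for u in umis}) > 1:
        raise InvalidArgumentError("UMIs must share one length")
    uniq = sorted(set(umis))
    n = len(uniq)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    arr = np.frombuffer("".join(uniq).encode(), dtype="S1").reshape(n, -1)
    for i in range(n):
        dist = (arr[i + 1:] != arr[i]).sum(axis=1)
        for j in np.nonzero(dist <= max_hamming)[0]:
            ri, rj = find(i), find(int(i + 1 + j))
            if ri != rj:
                parent[rj] = ri
    return len({find(i) for i in range(n)})


def process_uditas_reads(
    reads,
    ref: GenomeRef,
    anchor: str,
    umi_len: int = 12,
    max_edit: int = 2,
    seed_len: int = 15,
) -> tuple[list, dict]:
    """Extract, map, and account for every UDiTaS read.

    Returns ``(mapped, counts)``: mapped entries are (UmiRead, position,
    strand); counts partition the input into rejected / unmapped /
    multimapped / mapped, summing to the input size.
    """
    mapped = []
    counts = Counter({"rejected": 0, "unmapped": 0, "multimapped": 0,
                      "mapped": 0})
    for tup in reads:
        ur = extract_umi(tup, umi_len=umi_len, anchor=anchor,
                         max_edit=max_edit)
        if ur is None:
            counts["rejected"] += 1
            continue
        placed = map_flank(ur.flank, ref, seed_len=seed_len, max_edit=max_edit)
        if placed == "unmapped":
            counts["unmapped"] += 1
        elif placed == "multimapped":
            counts["multimapped"] += 1
        else:
            counts["mapped"] += 1
            mapped.append((ur, placed[0], placed[1]))
    return mapped, dict(counts)


def cluster_sites(
    mapped_reads,
    ref_name: str = "ref",
    merge_window: int = 5,
    max_hamming: int = 1,
) -> list[SiteCluster]:
    """Merge mapped positions into integration-site clusters.

    Same-strand positions within ``merge_window`` of their neighbor chain
    into one cluster (single linkage along the coordinate). The
    representative position is the modal member position (smaller wins
    ties); UMIs are deduplicated per cluster. Clusters sort by coordinate.
    """
    by_strand: dict[str, list] = {}
    for ur, pos, strand in mapped_reads:
        by_strand.setdefault(strand, []).append((pos, ur))
    clusters: list[SiteCluster] = []
    for strand, members in by_strand.items():
        members.sort(key=lambda m: m[0])
        group: list = []
        for pos, ur in members + [(None, None)]:
            if group and (pos is None or pos - group[-1][0] > merge_window):
                positions = [p for p, _ in group]
                umis = [u.umi for _, u in group]
                cnt = Counter(positions)
                top = max(cnt.values())
                rep = min(p for p, c in cnt.items() if c == top)
                clusters.append(SiteCluster(
                    ref_name=ref_name, position=rep, strand=strand,
                    read_count=len(group),
                    umi_count_raw=len(set(umis)),
                    umi_count_dedup=collapse_umis(umis, max_hamming),
                    members=tuple(positions),
                ))
                group = []
            if pos is not None:
                group.append((pos, ur))
    clusters.sort(key=lambda c: (c.position, c.strand))
    return clusters


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def label_and_scan(
    clusters: list[SiteCluster],
    site: TargetSite,
    ref: GenomeRef,
    on_target_tol: int = 100,
    offset_bp: int = DEFAULT_OFFSET_BP,
    flank_radius: int = 50,
    n_shuffle: int = 1000,
    percentile: float = 99.0,
    seed: int = 0,
) -> list[SiteCluster]:
    """Label clusters on/off-target and scan their flanks for target homology.

    A cluster is on-target when its position lies within ``on_target_tol``
    of the expected on-target insertion position (target 3' end +
    ``offset_bp``). The homology score is the best local alignment of the
    target sequence (either strand) against ±``flank_radius`` bp of
    reference flank; the per-cluster threshold is the given percentile of
    scores against ``n_shuffle`` shuffles of that flank (seeded), so
    "homologous" means exceeding what base composition alone explains.
    """
    expected = expected_insertion_position(site, len(ref), offset_bp)
    target_seq = ref.sequence[site.start:site.end]
    target_rc = revcomp(target_seq)
    aligner = _local_aligner()
    rng = np.random.default_rng(seed)
    out = []
    for cl in clusters:
        lo = max(0, cl.position - flank_radius)
        hi = min(len(ref), cl.position + flank_radius)
        flank = ref.sequence[lo:hi]
        score = max(aligner.score(flank, target_seq),
                    aligner.score(flank, target_rc))
        letters = np.frombuffer(flank.encode(), dtype="S1")
        null = np.empty(n_shuffle)
        for i in range(n_shuffle):
            shuf = rng.permutation(letters).tobytes().decode()
            null[i] = max(aligner.score(shuf, target_seq),
                          aligner.score(shuf, target_rc))
        threshold = float(np.percentile(null, percentile))
        out.append(SiteCluster(
            ref_name=cl.ref_name, position=cl.position, strand=cl.strand,
            read_count=cl.read_count, umi_count_raw=cl.umi_count_raw,
            umi_count_dedup=cl.umi_count_dedup, members=cl.members,
            on_target=abs(cl.position - expected) <= on_target_tol,
            homology_score=float(score),
            homologous=bool(score >= threshold),
        ))
    return out


def replicate_overlap(site_lists, match_window: int = 5) -> dict:
    """Cross-replicate reproducibility of integration sites.

    Sites match when within ``match_window`` on the same strand. Entries
    may be SiteClusters or (position, strand) pairs; clusters labeled
    on-target are counted separately and excluded from the off-target
    overlap. Returns per-pair shared counts and Jaccard indices plus the
    count of off-target sites shared by every replicate.
    """
    if len(site_lists) < 2:
        raise InvalidArgumentError("need at least 2 replicate site lists")

    def norm(lst):
        off, on = [], 0
        for s in lst:
            if isinstance(s, SiteCluster):
                if s.on_target:
                    on += 1
                else:
                    off.append((s.position, s.strand))
            else:
                off.append((s[0], s[1]))
        return sorted(off), on

    normed = [norm(lst) for lst in site_lists]

    def matches(a, b):
        used = set()
        m = 0
        for pos, strand in a:
            for k, (pos2, strand2) in enumerate(b):
                if k in used or strand2 != strand:
                    continue
                if abs(pos - pos2) <= match_window:
                    used.add(k)
                    m += 1
                    break
        return m

    pairs = {}
    for i in range(len(normed)):
        for j in range(i + 1, len(normed)):
            a, b = normed[i][0], normed[j][0]
            m = matches(a, b)
            union = len(a) + len(b) - m
            pairs[(i, j)] = {"shared": m,
                             "jaccard": m / union if union else 1.0}
    shared_all = matches(normed[0][0], normed[1][0])
    for k in range(2, len(normed)):
        shared_all = min(shared_all, matches(normed[0][0], normed[k][0]))
    return {"pairs": pairs, "shared_all_offtarget": shared_all,
            "on_target_counts": [n for _, n in normed]}


def on_target_fraction(clusters: list[SiteCluster]) -> float:
    """Fraction of deduplicated UMIs falling in on-target clusters."""
    total = sum(c.umi_count_dedup for c in clusters)
    if total == 0:
        raise EmptyInputError("zero deduplicated UMIs")
    on = sum(c.umi_count_dedup for c in clusters if c.on_target)
    return on / total
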