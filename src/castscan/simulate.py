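"""Synthetic sequencing-read simulator with ground-truth manifests.

Emulates the read structures produced by a Type I-F CRISPR-associated
transposase (CAST) acting on a genomic target:

* integration ~49 bp downstream of the crRNA-complementary target sequence,
  with a 5-bp target-site duplication (TSD) flanking the inserted transposon;
* a strongly T-RL-biased orientation mixture (right end target-proximal);
* optional substitutions within the downstream TSD copy, emulating errors
  during host repair of the 5-nt gaps left by staggered TnsB
  transesterifications (the upstream copy always matches the reference);
* unintegrated amplicon reads, optionally carrying indels near the
  insertion site;
* UDiTaS-style unidirectional UMI-tagged reads (UMI + transposon-end anchor
  + genomic flank), with rare off-target events receiving a single UMI each;
* long reads spanning whole insertion products, as a mixture of simple
  insertions and cointegrates that retain donor backbone.

All arithmetic runs in the *oriented frame*: the reference as read along the
target strand. Plus-strand targets use the reference as-is; minus-strand
targets mirror coordinates, so downstream always means "past the target
3' end in the direction the crRNA points".

Sequencing errors are substitutions only and never change read length, so
indel truth in the manifest stays unambiguous. Quality strings are a
constant 'I' (Q40).
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError
from .manifest import TruthManifest
from .seq import add_substitution_errors, random_dna, revcomp, substitute_base
from .types import (
    ORIENT_TLR,
    ORIENT_TRL,
    DonorConfig,
    GenomeRef,
    IntegrationEvent,
    TargetSite,
)

# Simulated reads keep at least this much genomic flank and transposon
# sequence on either side of a junction.
MIN_FLANK_SIM = 30
MIN_TX_SIM = 30

DEFAULT_OFFSET_BP = 49
DEFAULT_TSD_LEN = 5
DEFAULT_P_TRL = 0.95
DEFAULT_TSD_SUB_RATE = 0.004  # per base; ~2% of events carry >=1 substitution

OFFTARGET_EXCLUSION_BP = 1000  # off-target draws resample if this close to target
_EDGE_MARGIN = 300  # off-target draws stay clear of reference edges


# ---------------------------------------------------------------------------
# oriented-frame helpers

def oriented_sequence(ref: GenomeRef, site: TargetSite) -> str:
    return ref.sequence if site.strand == "+" else revcomp(ref.sequence)


def oriented_three_prime(site: TargetSite, ref_len: int) -> int:
    return site.end if site.strand == "+" else ref_len - site.start


def oriented_tsd_start(event: IntegrationEvent, site: TargetSite, ref_len: int) -> int:
    if site.strand == "+":
        return event.tsd_start
    return ref_len - (event.tsd_start + event.tsd_len)


def plus_tsd_start(oriented_ts: int, tsd_len: int, site: TargetSite, ref_len: int) -> int:
    if site.strand == "+":
        return oriented_ts
    return ref_len - (oriented_ts + tsd_len)


def expected_insertion_position(
    site: TargetSite, ref_len: int, offset_bp: int = DEFAULT_OFFSET_BP
) -> int:
    """Plus-strand coordinate of the insertion-adjacent base for the modal
    on-target event (the base a unidirectional UDiTaS flank starts on)."""
    ots = oriented_three_prime(site, ref_len) + offset_bp
    return ots if site.strand == "+" else ref_len - 1 - ots


def integrated_allele(
    oref: str, event: IntegrationEvent, site: TargetSite, donor: DonorConfig
) -> tuple[str, int, int]:
    """Oriented integrated-allele sequence and its two junction indices.

    Returns ``(allele, j_up, j_dn)`` where ``j_up`` is the index of the
    first transposon base (upstream junction) and ``j_dn`` the index of the
    first base of the downstream TSD copy.
    """
    ots = oriented_tsd_start(event, site, len(oref))
    cassette = donor.cassette(event.orientation)
    j_up = ots + event.tsd_len
    allele = oref[:j_up] + cassette + event.tsd_seq + oref[j_up:]
    return allele, j_up, j_up + len(cassette)


# ---------------------------------------------------------------------------
# generators

def make_reference(
    length: int, gc: float = 0.5, seed: int = 0, name: str = "ref"
) -> GenomeRef:
    """A random ACGT reference of the given length and GC content."""
    if length < 1:
        raise InvalidArgumentError("reference length must be >= 1")
    if not 0 <= gc <= 1:
        raise InvalidArgumentError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return GenomeRef(name=name, sequence=random_dna(length, rng, gc))


def make_donor(
    end_len: int = 100,
    cargo_len: int = 300,
    backbone_len: int = 800,
    seed: int = 0,
) -> DonorConfig:
    """A random donor with right/left ends, cargo and (optional) backbone."""
    rng = np.random.default_rng(seed)
    return DonorConfig(
        right_end=random_dna(end_len, rng),
        left_end=random_dna(end_len, rng),
        cargo=random_dna(cargo_len, rng),
        backbone=random_dna(backbone_len, rng) if backbone_len else "",
    )


OFFSET_DECAY = 0.15  # weight ratio per bp away from the modal offset


def _draw_offset(mode: int, spread: int, rng: np.random.Generator) -> int:
    """Offset from a peaked symmetric distribution on [mode−spread,
    mode+spread]: weights decay geometrically (``OFFSET_DECAY`` per bp)
    away from the mode, emulating integration that is predominantly
    single-bp precise with rare 1–2 bp wobble."""
    if spread <= 0:
        return mode
    deltas = np.arange(-spread, spread + 1)
    weights = OFFSET_DECAY ** np.abs(deltas)
    return int(mode + rng.choice(deltas, p=weights / weights.sum()))


def simulate_events(
    ref: GenomeRef,
    site: TargetSite,
    n: int,
    offset_mode: int = DEFAULT_OFFSET_BP,
    offset_spread: int = 2,
    p_trl: float = DEFAULT_P_TRL,
    tsd_len: int = DEFAULT_TSD_LEN,
    tsd_sub_rate: float = DEFAULT_TSD_SUB_RATE,
    offtarget_rate: float = 0.0,
    seed: int = 0,
) -> list[IntegrationEvent]:
    """Draw ``n`` ground-truth integration events.

    On-target events insert at offset ``offset_mode ± offset_spread``
    downstream of the target 3' end; off-target events (probability
    ``offtarget_rate``) fall uniformly over the reference, resampled away
    from the on-target window so labels are unambiguous. Orientation is
    T-RL with probability ``p_trl``. Each downstream-copy TSD base is
    substituted independently at ``tsd_sub_rate``.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    for name, val in [("p_trl", p_trl), ("tsd_sub_rate", tsd_sub_rate),
                      ("offtarget_rate", offtarget_rate)]:
        if not 0 <= val <= 1:
            raise InvalidArgumentError(f"{name} must be in [0, 1]")
    site.validate_against(ref)
    L = len(ref)
    oref = oriented_sequence(ref, site)
    o3 = oriented_three_prime(site, L)
    rng = np.random.default_rng(seed)

    events = []
    for i in range(n):
        on_target = bool(rng.random() >= offtarget_rate)
        if on_target:
            ots = o3 + _draw_offset(offset_mode, offset_spread, rng)
        else:
            while True:
                ots = int(rng.integers(_EDGE_MARGIN, L - _EDGE_MARGIN - tsd_len))
                if abs(ots - (o3 + offset_mode)) > OFFTARGET_EXCLUSION_BP:
                    break
        if not (0 <= ots and ots + tsd_len <= L):
            raise InvalidArgumentError(
                "insertion site falls outside the reference; "
                "place the target further from the edge"
            )
        orientation = ORIENT_TRL if rng.random() < p_trl else ORIENT_TLR
        ref_tsd = oref[ots:ots + tsd_len]
        subs = []
        tsd = list(ref_tsd)
        for p in range(tsd_len):
            if rng.random() < tsd_sub_rate:
                tsd[p] = substitute_base(tsd[p], rng)
                subs.append((p, tsd[p]))
        events.append(IntegrationEvent(
            event_id=f"ev{i:05d}",
            ref_name=ref.name,
            tsd_start=plus_tsd_start(ots, tsd_len, site, L),
            offset_bp=ots - o3,
            orientation=orientation,
            tsd_len=tsd_len,
            tsd_subs=tuple(subs),
            tsd_seq="".join(tsd),
            is_on_target=on_target,
        ))
    return events


def _draw_count(spec, rng: np.random.Generator) -> int:
    """Draw a positive integer from an int or a (name, *params) tuple."""
    if isinstance(spec, (int, np.integer)):
        return int(spec)
    kind = spec[0]
    if kind == "poisson":
        return max(1, int(rng.poisson(spec[1])))
    if kind == "geometric":
        return int(rng.geometric(spec[1]))
    if kind == "uniform":
        return int(rng.integers(spec[1], spec[2] + 1))
    raise InvalidArgumentError(f"unknown count distribution {spec!r}")


def emit_amplicon_reads(
    ref: GenomeRef,
    site: TargetSite,
    donor: DonorConfig,
    events: list[IntegrationEvent],
    read_len: int = 150,
    depth: int = 20,
    unintegrated_fraction: float = 0.3,
    indel_profile: dict | None = None,
    error_rate: float = 0.0,
    sides: tuple = ("upstream",),
    seed: int = 0,
) -> tuple[list, TruthManifest]:
    """Amplicon reads spanning the target locus, plus a truth manifest.

    Integrated reads are slices of the integrated allele spanning one
    junction: genomic flank, then the TSD copy, then transposon sequence
    (``upstream`` side), or the mirror layout (``downstream`` side). Each
    event contributes ``depth`` reads per requested side. Unintegrated
    reads are pure amplicon slices spanning the predicted insertion site,
    with indels injected per ``indel_profile``
    (``{"rate", "max_len", "geom_p", "pos_sd"}``).

    Returns ``(reads, manifest)`` with reads as (id, seq, qual) tuples.
    """
    if read_len < MIN_FLANK_SIM + MIN_TX_SIM:
        raise InvalidArgumentError(
            f"read_len must be >= {MIN_FLANK_SIM + MIN_TX_SIM} to span a "
            "junction with anchor and flank"
        )
    if not 0 <= unintegrated_fraction <= 1:
        raise InvalidArgumentError("unintegrated_fraction must be in [0, 1]")
    cassette_len = len(donor.right_end) + len(donor.cargo) + len(donor.left_end)
    if cassette_len < read_len:
        raise InvalidArgumentError(
            "transposon cassette shorter than read_len; reads would span "
            "both junctions"
        )
    for s in sides:
        if s not in ("upstream", "downstream"):
            raise InvalidArgumentError(f"unknown side {s!r}")
    profile = {"rate": 0.0, "max_len": 10, "geom_p": 0.5, "pos_sd": 8.0}
    if indel_profile:
        profile.update(indel_profile)

    L = len(ref)
    oref = oriented_sequence(ref, site)
    o3 = oriented_three_prime(site, L)
    rng = np.random.default_rng(seed)

    reads: list[tuple[str, str, str]] = []
    truth: dict[str, dict] = {}
    counter = 0

    def emit(seq: str, entry: dict) -> None:
        nonlocal counter
        rid = f"amp_{counter:06d}"
        counter += 1
        seq = add_substitution_errors(seq, error_rate, rng)
        reads.append((rid, seq, "I" * len(seq)))
        truth[rid] = entry

    n_int = 0 if unintegrated_fraction >= 1 else len(events) * depth * len(sides)
    if unintegrated_fraction >= 1:
        n_unint = len(events) * depth
    elif unintegrated_fraction == 0:
        n_unint = 0
    else:
        n_unint = round(n_int * unintegrated_fraction / (1 - unintegrated_fraction))

    if unintegrated_fraction < 1:
        for ev in events:
            allele, j_up, j_dn = integrated_allele(oref, ev, site, donor)
            for side in sides:
                for _ in range(depth):
                    if side == "upstream":
                        flank_len = int(rng.integers(
                            MIN_FLANK_SIM, read_len - MIN_TX_SIM + 1))
                        start = j_up - flank_len
                    else:
                        flank_len = int(rng.integers(
                            MIN_FLANK_SIM, read_len - MIN_TX_SIM + 1))
                        start = j_dn - (read_len - flank_len)
                    if start < 0 or start + read_len > len(allele):
                        raise InvalidArgumentError(
                            "read window outside the integrated allele; "
                            "place the target further from the edge"
                        )
                    emit(allele[start:start + read_len], {
                        "kind": "integrated",
                        "event": ev.event_id,
                        "side": side,
                        "allele_start": start,
                    })

    # Unintegrated reads span the predicted insertion site.
    center = o3 + DEFAULT_OFFSET_BP
    margin = 20
    for _ in range(n_unint):
        start = int(rng.integers(center - read_len + margin, center - margin + 1))
        start = max(0, min(start, L - read_len))
        indel = None
        if rng.random() < profile["rate"]:
            kind = "deletion" if rng.random() < 0.5 else "insertion"
            length = min(int(rng.geometric(profile["geom_p"])), profile["max_len"])
            lo = start - center + 5
            hi = start + read_len - center - 5 - length
            d = int(np.clip(round(rng.normal(0, profile["pos_sd"])), lo, hi))
            col = center + d
            if kind == "deletion":
                seq = oref[start:col] + oref[col + length:start + read_len + length]
                indel = {"kind": kind, "length": length, "column": col,
                         "center_offset": d}
            else:
                ins = random_dna(length, rng)
                seq = oref[start:col] + ins + oref[col:start + read_len - length]
                indel = {"kind": kind, "length": length, "column": col,
                         "center_offset": d, "inserted": ins}
        else:
            seq = oref[start:start + read_len]
        emit(seq, {"kind": "unintegrated", "start": start, "indel": indel})

    params = {
        "stage": "amplicon",
        "read_len": read_len, "depth": depth,
        "unintegrated_fraction": unintegrated_fraction,
        "indel_profile": profile, "error_rate": error_rate,
        "sides": list(sides), "ref_name": ref.name, "ref_len": L,
        "site": {"start": site.start, "end": site.end, "strand": site.strand},
    }
    manifest = TruthManifest(seed=seed, parameters=params,
                             events=list(events), reads=truth)
    return reads, manifest


def emit_uditas_reads(
    ref: GenomeRef,
    site: TargetSite,
    donor: DonorConfig,
    events: list[IntegrationEvent],
    umi_len: int = 12,
    umis_per_event=("poisson", 3),
    reads_per_umi=("poisson", 2),
    anchor_len: int = 20,
    flank_len: int = 40,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list, TruthManifest]:
    """UDiTaS-style unidirectional UMI-tagged reads.

    Each read is UMI + transposon right-end anchor + genomic flank read
    outward from the insertion point (the flank starts on the first base of
    the downstream TSD copy). On-target events receive ``umis_per_event``
    UMIs; off-target events receive exactly one UMI each, so each detected
    off-target represents a single integration event. The UMI is also
    appended to the read name after ``_UMI:``.
    """
    if umi_len < 6:
        raise InvalidArgumentError("umi_len must be >= 6")
    if anchor_len > len(donor.right_end):
        raise InvalidArgumentError("anchor_len exceeds right-end length")
    if flank_len < 15:
        raise InvalidArgumentError("flank_len must be >= 15 to be mappable")
    L = len(ref)
    oref = oriented_sequence(ref, site)
    rng = np.random.default_rng(seed)
    anchor = donor.right_end[:anchor_len]

    reads: list[tuple[str, str, str]] = []
    truth: dict[str, dict] = {}
    counter = 0
    for ev in events:
        ots = oriented_tsd_start(ev, site, L)
        if ots + flank_len > L:
            raise InvalidArgumentError("flank window outside reference")
        flank = ev.tsd_seq + oref[ots + ev.tsd_len:ots + flank_len]
        n_umi = 1 if not ev.is_on_target else _draw_count(umis_per_event, rng)
        for _ in range(n_umi):
            umi = random_dna(umi_len, rng)
            for _ in range(_draw_count(reads_per_umi, rng)):
                rid = f"udt_{counter:06d}_UMI:{umi}"
                counter += 1
                seq = add_substitution_errors(umi + anchor + flank,
                                              error_rate, rng)
                reads.append((rid, seq, "I" * len(seq)))
                truth[rid] = {"event": ev.event_id, "umi": umi}

    params = {
        "stage": "uditas",
        "umi_len": umi_len, "anchor_len": anchor_len, "flank_len": flank_len,
        "umis_per_event": list(umis_per_event)
        if isinstance(umis_per_event, tuple) else umis_per_event,
        "reads_per_umi": list(reads_per_umi)
        if isinstance(reads_per_umi, tuple) else reads_per_umi,
        "error_rate": error_rate, "ref_name": ref.name, "ref_len": L,
        "site": {"start": site.start, "end": site.end, "strand": site.strand},
    }
    manifest = TruthManifest(seed=seed, parameters=params,
                             events=list(events), reads=truth)
    return reads, manifest


def emit_long_reads(
    ref: GenomeRef,
    site: TargetSite,
    donor: DonorConfig,
    events: list[IntegrationEvent],
    simple_fraction: float = 0.9,
    read_error: float = 0.0,
    flank_len: int = 150,
    seed: int = 0,
) -> tuple[list, TruthManifest]:
    """Long reads spanning whole insertion products.

    Simple insertions read flank–RE–cargo–LE–flank; cointegrates carry the
    donor backbone and a second right-end copy between the cassette and the
    downstream flank (flank–RE–cargo–LE–backbone–RE–flank). T-LR events
    reverse-complement the internal block. One read per event; the
    product class drawn here is written back onto the event truth.
    """
    if not 0 <= simple_fraction <= 1:
        raise InvalidArgumentError("simple_fraction must be in [0, 1]")
    if simple_fraction < 1 and not donor.backbone:
        raise InvalidArgumentError(
            "cointegrates are unrepresentable with an empty donor backbone"
        )
    L = len(ref)
    oref = oriented_sequence(ref, site)
    rng = np.random.default_rng(seed)

    reads: list[tuple[str, str]] = []
    truth: dict[str, dict] = {}
    for i, ev in enumerate(events):
        ots = oriented_tsd_start(ev, site, L)
        up = oref[max(0, ots + ev.tsd_len - flank_len):ots + ev.tsd_len]
        down = ev.tsd_seq + oref[ots + ev.tsd_len:
                                 min(L, ots + flank_len)]
        simple = bool(rng.random() < simple_fraction)
        internal = donor.right_end + donor.cargo + donor.left_end
        if not simple:
            internal += donor.backbone + donor.right_end
        if ev.orientation == ORIENT_TLR:
            internal = revcomp(internal)
        ev.product_class = "simple" if simple else "cointegrate"
        rid = f"long_{i:05d}"
        seq = add_substitution_errors(up + internal + down, read_error, rng)
        reads.append((rid, seq))
        truth[rid] = {"event": ev.event_id,
                      "product_class": ev.product_class,
                      "orientation": ev.orientation}

    params = {
        "stage": "long", "simple_fraction": simple_fraction,
        "read_error": read_error, "flank_len": flank_len,
        "ref_name": ref.name, "ref_len": L,
        "site": {"start": site.start, "end": site.end, "strand": site.strand},
    }
    manifest = TruthManifest(seed=seed, parameters=params,
                             events=list(events), reads=truth)
    return reads, manifest
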