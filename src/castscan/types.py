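"""Domain types for CAST integration-product analysis.

Conventions fixed across the package:

* All coordinates are 0-based, half-open.
* ``tsd_start`` is the reference (+ strand) coordinate of the first base of
  the target-site duplication (TSD).
* ``offset_bp`` is signed and measured in the *target-strand* frame:
  positive means downstream of the target's 3' end in the direction the
  crRNA-complementary sequence points; minus-strand targets mirror the
  arithmetic.
* Orientation tokens: T-RL means the transposon RIGHT end is target-proximal
  (nearest the target 3' end); T-LR means the LEFT end is. The generator and
  the classifier share this single definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

from .errors import InvalidArgumentError
from .seq import DNA_ALPHABET, revcomp

ORIENT_TRL = "T-RL"
ORIENT_TLR = "T-LR"


@dataclass(frozen=True)
class GenomeRef:
    """A named reference (or amplicon) sequence, strictly over ACGT."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise InvalidArgumentError("reference sequence must be non-empty")
        if set(self.sequence) - set(DNA_ALPHABET):
            raise InvalidArgumentError(
                "reference alphabet must be strictly ACGT (no N)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TargetSite:
    """The crRNA-complementary genomic interval.

    ``three_prime_end`` is the coordinate of the base just past the target's
    3' end in the target-strand frame: ``end`` on +, ``start`` on −.
    """

    ref_name: str
    start: int
    end: int
    strand: str = "+"
    pam: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InvalidArgumentError("target site needs 0 <= start < end")
        if self.strand not in "+-":
            raise InvalidArgumentError("strand must be '+' or '-'")

    @property
    def three_prime_end(self) -> int:
        return self.end if self.strand == "+" else self.start

    def validate_against(self, ref: GenomeRef) -> None:
        if self.end > len(ref):
            raise InvalidArgumentError(
                f"target site [{self.start},{self.end}) outside reference "
                f"{ref.name!r} of length {len(ref)}"
            )


@dataclass(frozen=True)
class DonorConfig:
    """Transposon donor: right/left end sequences, cargo, optional backbone.

    ``backbone`` is the plasmid backbone outside the two ends; empty for
    linear donors (in which case cointegrates cannot be simulated).
    """

    right_end: str
    left_end: str
    cargo: str
    backbone: str = ""

    def __post_init__(self) -> None:
        if len(self.right_end) < 20 or len(self.left_end) < 20:
            raise InvalidArgumentError("transposon ends must each be >= 20 bp")
        if self.right_end == self.left_end:
            raise InvalidArgumentError("right and left ends must differ")

    @property
    def cargo_size_bp(self) -> int:
        return len(self.cargo)

    def cassette(self, orientation: str = ORIENT_TRL) -> str:
        """The inserted sequence reading target-proximal to distal.

        T-RL inserts RE–cargo–LE forward; T-LR inserts the reverse
        complement, so the left end (reverse-complemented) is proximal.
        """
        fwd = self.right_end + self.cargo + self.left_end
        return fwd if orientation == ORIENT_TRL else revcomp(fwd)


@dataclass
class IntegrationEvent:
    """A ground-truth (or inferred) integration event.

    ``tsd_seq`` is the TSD sequence of the downstream copy *after* any
    substitutions arising from gap repair; the upstream copy always matches
    the reference.
    """

    event_id: str
    ref_name: str
    tsd_start: int
    offset_bp: int
    orientation: str
    tsd_len: int = 5
    tsd_subs: tuple = ()
    tsd_seq: str = ""
    is_on_target: bool = True
    product_class: str = "simple"

    def __post_init__(self) -> None:
        if self.tsd_len < 0:
            raise InvalidArgumentError("tsd_len must be >= 0")
        if any(pos >= self.tsd_len for pos, _ in self.tsd_subs):
            raise InvalidArgumentError("TSD substitution position outside TSD")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tsd_subs"] = [list(s) for s in self.tsd_subs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "IntegrationEvent":
        d = dict(d)
        d["tsd_subs"] = tuple((int(p), b) for p, b in d.get("tsd_subs", []))
        return cls(**d)


@dataclass(frozen=True)
class EndMatch:
    """A transposon-end anchor located within a read.

    ``side`` says which genomic junction the anchor abuts: ``upstream``
    anchors follow the flank (read = flank+TSD+end...), ``downstream``
    anchors precede it (read = ...end+TSD+flank).
    """

    read_id: str
    end: str  # "right" | "left"
    end_orient: str  # "forward" | "revcomp"
    read_offset: int  # anchor start in the read
    read_end: int  # one past the anchor's last base in the read
    edit_distance: int
    side: str  # "upstream" | "downstream"


@dataclass(frozen=True)
class JunctionCall:
    """A called genome/transposon junction for one read.

    ``junction_pos`` is the oriented-frame coordinate of the first base of
    the TSD (the first genomic base joined to the transposon);
    ``boundary_pos`` is the raw mapped flank boundary (last flank base for
    upstream-side reads, first flank base for downstream-side reads), used
    for TSD-length inference. ``distance_bp`` = junction_pos − target 3' end.
    """

    read_id: str
    ref_name: str
    junction_pos: int
    end: str
    end_orient: str
    side: str
    boundary_pos: int
    distance_bp: int
    orientation_call: str
    flank_seq: str = ""


@dataclass(frozen=True)
class IndelCall:
    read_id: str
    kind: str  # "insertion" | "deletion"
    length: int
    center_offset: int
    in_window: bool


@dataclass(frozen=True)
class LongReadClass:
    read_id: str
    label: str  # "simple" | "cointegrate" | "unclassified"
    evidence: tuple = ()


@dataclass(frozen=True)
class UmiRead:
    read_id: str
    umi: str
    flank: str


@dataclass
class SiteCluster:
    """A genomic integration locus aggregated from mapped UDiTaS reads."""

    ref_name: str
    position: int
    strand: str
    read_count: int
    umi_count_raw: int
    umi_count_dedup: int
    members: tuple = ()
    on_target: Optional[bool] = None
    homology_score: Optional[float] = None
    homologous: Optional[bool] = None
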