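"""Packaged study scenarios: fixed reference/site/donor geometries.

Two desk-scale fixtures cover the analyses:

* ``amplicon_scenario`` — a 4-kb locus with a 32-bp target mid-sequence,
  used for junction calling, indel quantification and long-read products.
* ``lysate_scenario`` — a 100-kb genome standing in for a bacterial-lysate
  UDiTaS run: one heavily used on-target site plus a rare unguided
  off-target background (each off-target a single integration event).

Scenario seeds fix the *sequences*; the per-run ``seed`` arguments of the
simulators control event and read sampling.
"""

from __future__ import annotations

from .simulate import make_donor, make_reference, simulate_events
from .types import DonorConfig, GenomeRef, TargetSite

TARGET_LEN = 32  # crRNA-complementary target length

# GC fraction typical of human genic loci.
_GC = 0.41

_REF_SEED = 1042
_DONOR_SEED = 7177


def default_donor() -> DonorConfig:
    return make_donor(end_len=100, cargo_len=300, backbone_len=800,
                      seed=_DONOR_SEED)


def amplicon_scenario(strand: str = "+") -> tuple[GenomeRef, TargetSite, DonorConfig]:
    ref = make_reference(4000, gc=_GC, seed=_REF_SEED, name="amplicon_locus")
    start = 2000
    site = TargetSite(ref_name=ref.name, start=start, end=start + TARGET_LEN,
                      strand=strand)
    return ref, site, default_donor()


def lysate_scenario(strand: str = "+") -> tuple[GenomeRef, TargetSite, DonorConfig]:
    ref = make_reference(100_000, gc=_GC, seed=_REF_SEED + 1,
                         name="lysate_genome")
    start = 50_000
    site = TargetSite(ref_name=ref.name, start=start, end=start + TARGET_LEN,
                      strand=strand)
    return ref, site, default_donor()


# Default event-sampling conditions for the lysate UDiTaS run: integration
# dominated by the on-target site, with an unguided off-target background
# well below 1% of events.
LYSATE_EVENTS = dict(n=300, offtarget_rate=0.005)
LYSATE_UDITAS = dict(umi_len=12, umis_per_event=("poisson", 3),
                     reads_per_umi=("poisson", 2), anchor_len=20,
                     flank_len=40)


def simulate_lysate_events(ref, site, seed: int = 3, **overrides):
    params = {**LYSATE_EVENTS, **overrides}
    return simulate_events(ref, site, seed=seed, **params)
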