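"""Call genome-transposon junctions and profile the insertion distance.

Simulates 2,000 error-free junction reads, partitions every read into
exactly one outcome category, and reports the insertion-distance histogram
(modal distance ~49 bp downstream of the target 3' end), the orientation
mixture, and the inferred TSD length from paired junctions.
"""

from castscan import (
    classify_orientation_bulk,
    distance_profile,
    emit_amplicon_reads,
    infer_tsd,
    partition_reads,
    simulate_events,
)
from castscan.scenarios import amplicon_scenario

ref, site, donor = amplicon_scenario()
events = simulate_events(ref, site, n=2000, seed=11)
reads, _ = emit_amplicon_reads(ref, site, donor, events, depth=1,
                               unintegrated_fraction=0.0,
                               sides=("upstream", "downstream"), seed=11)
calls, _, counts = partition_reads(reads, donor, ref, site)
hist, mode = distance_profile(calls)

print("read accounting:", counts)
print(f"modal distance: {mode} bp (target 3' end -> first TSD base)")
print(hist[hist["count"] > 20].to_string(index=False))
orient = classify_orientation_bulk(calls)
print(f"orientation: T-RL {orient['T-RL']:.3f}, T-LR {orient['T-LR']:.3f}")
up = [c for c in calls if c.side == "upstream"]
dn = [c for c in calls if c.side == "downstream"]
tsd_len, interval = infer_tsd(up, dn)
print(f"inferred TSD: {tsd_len} bp, consensus interval {interval}")
# The modal distance and TSD length recover the generator's ground truth
# (49 bp, 5 bp); the orientation fraction estimates the T-RL bias.
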