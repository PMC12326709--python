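"""End-to-end orchestration: simulate → junctions → purity → offtarget.

A :class:`RunConfig` holds every stage parameter with defaults and
round-trips through YAML unchanged. :func:`run_pipeline` executes the
enabled stages in order on a single seed and returns a
:class:`ReportBundle` whose metrics equal the stage-level functions run
individually; metrics of skipped stages are absent, never silently zero.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigError, InvalidArgumentError
from .io import write_bed, write_fasta, write_fastq
from .junctions import classify_orientation_bulk, distance_profile, infer_tsd, partition_reads
from .offtarget import (
    cluster_sites,
    label_and_scan,
    on_target_fraction,
    process_uditas_reads,
)
from .purity import (
    classify_long_read,
    integration_fraction,
    quantify_indels,
    simple_fraction,
    tsd_substitution_rate,
)
from .simulate import (
    emit_amplicon_reads,
    emit_long_reads,
    emit_uditas_reads,
    make_donor,
    make_reference,
    simulate_events,
)
from .types import TargetSite


@dataclass
class RunConfig:
    """Full pipeline configuration; every field has a default."""

    seed: int = 1
    reference: dict = field(default_factory=lambda: dict(
        length=4000, gc=0.41, seed=1042, name="amplicon_locus"))
    site: dict = field(default_factory=lambda: dict(
        start=2000, end=2032, strand="+"))
    donor: dict = field(default_factory=lambda: dict(
        end_len=100, cargo_len=300, backbone_len=800, seed=7177))
    events: dict = field(default_factory=lambda: dict(
        n=100, offset_mode=49, offset_spread=2, p_trl=0.95, tsd_len=5,
        tsd_sub_rate=0.004, offtarget_rate=0.0))
    amplicon: dict = field(default_factory=lambda: dict(
        read_len=150, depth=20, unintegrated_fraction=0.3,
        error_rate=0.0, sides=["upstream", "downstream"]))
    long_reads: dict = field(default_factory=lambda: dict(
        enabled=True, simple_fraction=0.9, read_error=0.0, flank_len=150))
    uditas: dict = field(default_factory=lambda: dict(
        enabled=True, umi_len=12, umis_per_event=["poisson", 3],
        reads_per_umi=["poisson", 2], anchor_len=20, flank_len=40,
        error_rate=0.0, merge_window=5, on_target_tol=100))
    stages: dict = field(default_factory=lambda: dict(
        simulate=True, junctions=True, purity=True, offtarget=True))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        for key, val in d.items():
            if not hasattr(cfg, key):
                raise ConfigError(f"unknown config section {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(val, dict):
                current.update(val)
            else:
                setattr(cfg, key, val)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    metrics: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps({"metrics": self.metrics,
                           "provenance": self.provenance},
                          sort_keys=True, indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _tuplify(spec):
    return tuple(spec) if isinstance(spec, list) else spec


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> ReportBundle:
    """Run every enabled stage and aggregate the readouts.

    Raises :class:`ConfigError` when no stage is enabled. With ``outdir``
    set, writes the bundle JSON plus FASTQ/FASTA, manifests, per-read TSVs
    and BED sidecars.
    """
    stages = config.stages
    if not any(stages.values()):
        raise ConfigError("no stages enabled")
    if (stages.get("junctions") or stages.get("purity")
            or stages.get("offtarget")) and not stages.get("simulate"):
        raise ConfigError("downstream stages require the simulate stage")

    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    ref = make_reference(**config.reference)
    site = TargetSite(ref_name=ref.name, **config.site)
    donor = make_donor(**config.donor)
    metrics: dict = {}

    events = simulate_events(ref, site, seed=config.seed, **config.events)
    metrics["n_events"] = len(events)

    amp_cfg = dict(config.amplicon)
    amp_cfg["sides"] = tuple(amp_cfg.get("sides", ["upstream"]))
    amp_reads, amp_manifest = emit_amplicon_reads(
        ref, site, donor, events, seed=config.seed, **amp_cfg)
    if out:
        write_fastq(amp_reads, out / "amplicon.fastq")
        amp_manifest.save(out / "amplicon.manifest.json")

    calls = counts = unintegrated = None
    if stages.get("junctions"):
        tsd_len = config.events.get("tsd_len", 5)
        calls, unintegrated, counts = partition_reads(
            amp_reads, donor, ref, site, tsd_len=tsd_len)
        hist, mode = distance_profile(calls)
        metrics["distance_mode_bp"] = mode
        metrics["distance_histogram"] = {
            int(d): int(c) for d, c in
            zip(hist["distance_bp"], hist["count"])}
        metrics["orientation"] = classify_orientation_bulk(calls)
        up = [c for c in calls if c.side == "upstream"]
        dn = [c for c in calls if c.side == "downstream"]
        if up and dn:
            tsd_mode, _ = infer_tsd(up, dn, pairing="population")
            metrics["tsd_len_mode"] = tsd_mode
        metrics["read_counts"] = counts
        if out:
            _write_calls(calls, out / "junction_calls.tsv")
            hist.to_csv(out / "distance_histogram.tsv", sep="\t", index=False)
            write_bed(
                [(ref.name, c.junction_pos, c.junction_pos + 1, c.read_id,
                  0, "+" if site.strand == "+" else "-") for c in calls],
                out / "junctions.bed")

    if stages.get("purity"):
        if calls is None:
            raise ConfigError("purity stage requires the junctions stage")
        metrics["integration_fraction"] = integration_fraction(counts)["fraction"]
        center_offset = metrics.get("distance_mode_bp",
                                    config.events.get("offset_mode", 49))
        if unintegrated:
            freq, _ = quantify_indels(unintegrated, ref, site,
                                      predicted_offset=center_offset)
            metrics["indel_freq"] = freq
        metrics["tsd_sub_rate"] = tsd_substitution_rate(
            calls, ref, site, tsd_len=config.events.get("tsd_len", 5))["rate"]
        if config.long_reads.get("enabled", True):
            lr_cfg = {k: v for k, v in config.long_reads.items()
                      if k != "enabled"}
            long_reads, long_manifest = emit_long_reads(
                ref, site, donor, events, seed=config.seed, **lr_cfg)
            classes = [classify_long_read(r, donor) for r in long_reads]
            metrics["simple_fraction"] = simple_fraction(classes)["fraction"]
            if out:
                write_fasta(long_reads, out / "long_reads.fasta")
                long_manifest.save(out / "long_reads.manifest.json")

    if stages.get("offtarget"):
        udt_cfg = dict(config.uditas)
        udt_cfg.pop("enabled", None)
        merge_window = udt_cfg.pop("merge_window", 5)
        on_target_tol = udt_cfg.pop("on_target_tol", 100)
        udt_cfg["umis_per_event"] = _tuplify(udt_cfg["umis_per_event"])
        udt_cfg["reads_per_umi"] = _tuplify(udt_cfg["reads_per_umi"])
        udt_reads, udt_manifest = emit_uditas_reads(
            ref, site, donor, events, seed=config.seed + 1, **udt_cfg)
        anchor = donor.right_end[:udt_cfg.get("anchor_len", 20)]
        mapped, udt_counts = process_uditas_reads(
            udt_reads, ref, anchor, umi_len=udt_cfg.get("umi_len", 12))
        clusters = cluster_sites(mapped, ref_name=ref.name,
                                 merge_window=merge_window)
        clusters = label_and_scan(clusters, site, ref,
                                  on_target_tol=on_target_tol,
                                  offset_bp=config.events.get("offset_mode", 49),
                                  seed=config.seed)
        metrics["uditas_read_counts"] = udt_counts
        metrics["n_sites"] = len(clusters)
        metrics["n_offtarget_sites"] = sum(not c.on_target for c in clusters)
        metrics["on_target_fraction"] = on_target_fraction(clusters)
        if out:
            write_fastq(udt_reads, out / "uditas.fastq")
            udt_manifest.save(out / "uditas.manifest.json")
            write_bed(
                [(c.ref_name, c.position, c.position + 1,
                  "on_target" if c.on_target else "off_target",
                  c.umi_count_dedup, c.strand) for c in clusters],
                out / "sites.bed")
            _write_clusters(clusters, out / "clusters.tsv")

    bundle = ReportBundle(
        metrics=metrics,
        provenance={"config_hash": config.hash(), "seed": config.seed,
                    "castscan_version": __version__},
    )
    if out:
        bundle.save(out / "bundle.json")
        RunConfig.to_yaml(config, out / "config.yaml")
    return bundle


def _write_calls(calls, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tref_name\tjunction_pos\tdistance_bp\tend\t"
                 "end_orient\tside\torientation\n")
        for c in calls:
            fh.write(f"{c.read_id}\t{c.ref_name}\t{c.junction_pos}\t"
                     f"{c.distance_bp}\t{c.end}\t{c.end_orient}\t{c.side}\t"
                     f"{c.orientation_call}\n")


def _write_clusters(clusters, path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_name\tposition\tstrand\tread_count\tumi_count_raw\t"
                 "umi_count_dedup\ton_target\thomology_score\thomologous\n")
        for c in clusters:
            fh.write(f"{c.ref_name}\t{c.position}\t{c.strand}\t"
                     f"{c.read_count}\t{c.umi_count_raw}\t"
                     f"{c.umi_count_dedup}\t{c.on_target}\t"
                     f"{c.homology_score}\t{c.homologous}\n")


def compare_conditions(bundle_a: ReportBundle, bundle_b: ReportBundle) -> dict:
    """Fold changes (b over a) for shared numeric metrics.

    ``integration_fraction`` must be present in both bundles. A zero
    denominator reports the string ``"infinite"`` rather than a number.
    """
    a, b = bundle_a.metrics, bundle_b.metrics
    if "integration_fraction" not in a or "integration_fraction" not in b:
        raise InvalidArgumentError(
            "both bundles must contain integration_fraction")
    folds = {}
    for key in sorted(set(a) & set(b)):
        va, vb = a[key], b[key]
        if not isinstance(va, (int, float)) or not isinstance(vb, (int, float)):
            continue
        if va == 0:
            folds[key] = "infinite" if vb != 0 else 1.0
        else:
            folds[key] = vb / va
    return folds
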