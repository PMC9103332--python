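"""End-to-end orchestration of the annotation/design/quantification stages.

A single YAML configuration drives the run; stages execute in dependency
order (cdna -> protein; dist -> tree; sirna and quantify are independent).
A stage failure aborts its dependents but not the independent stages, and
the consolidated JSON report records every stage output plus provenance
(config hash, seed, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
import yaml

from . import __version__
from . import aligndist, cdna, phylo, protein, quantify, simulate, sirna

log = logging.getLogger("crtkit")

SCHEMA_VERSION = 1

_STAGE_DEFAULTS: dict[str, dict[str, Any]] = {
    "cdna": {"enabled": False, "input": "simulate", "tail_min": 10},
    "protein": {"enabled": False, "pka_set": "bjellqvist"},
    "dist": {"enabled": False, "alignment": "simulate", "gap_mode": "complete"},
    "tree": {"enabled": False, "bootstrap": 1000, "outgroup": None,
             "cutoff": 70.0, "collapse": False},
    "sirna": {"enabled": False, "background": "simulate", "mirnas": None,
              "max_gc": 38.0, "gc_window": "core", "max_run": 4,
              "min_block": 15, "top_k": None},
    "quantify": {"enabled": False, "table": "simulate"},
}


@dataclass
class RunConfig:
    seed: int = 0
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known_top = {"seed"} | set(_STAGE_DEFAULTS)
        unknown = set(raw) - known_top
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        stages = {}
        for name, defaults in _STAGE_DEFAULTS.items():
            user = raw.get(name, {}) or {}
            bad = set(user) - set(defaults)
            if bad:
                raise ValueError(f"unknown keys in [{name}]: {sorted(bad)}")
            merged = {**defaults, **user}
            if name in raw and "enabled" not in user:
                merged["enabled"] = True
            stages[name] = merged
        return cls(seed=int(raw.get("seed", 0)), stages=stages)

    def digest(self) -> str:
        payload = json.dumps({"seed": self.seed, "stages": self.stages},
                             sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _hit_rows(hits) -> list[dict]:
    return [{"start": h.interval.start, "end": h.interval.end,
             "match": h.matched_text} for h in hits]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the consolidated report."""
    report: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {"config_hash": config.digest(), "seed": config.seed,
                       "crtkit_version": __version__},
        "stages": {},
        "errors": [],
    }
    failed: set[str] = set()

    def stage_enabled(name: str) -> bool:
        return bool(config.stages[name]["enabled"])

    def fail(name: str, exc: Exception) -> None:
        log.error("stage %s failed: %s", name, exc)
        failed.add(name)
        report["errors"].append({"stage": name, "error": str(exc)})

    cdna_record = None
    protein_record = None

    if stage_enabled("cdna"):
        cfg = config.stages["cdna"]
        try:
            if cfg["input"] == "simulate":
                cdna_record, truth = simulate.make_cdna(seed=config.seed)
            else:
                cdna_record = cdna.read_fasta(cfg["input"])[0]
            ann = cdna.segment_cdna(cdna_record, tail_min=int(cfg["tail_min"]))
            report["stages"]["cdna"] = {
                "id": ann.record_id,
                "length_bp": ann.length,
                "utr5": dataclasses.astuple(ann.utr5) if ann.utr5 else None,
                "orf": dataclasses.astuple(ann.orf),
                "utr3": dataclasses.astuple(ann.utr3) if ann.utr3 else None,
                "polya_tail": dataclasses.astuple(ann.polya_tail)
                if ann.polya_tail else None,
                "polya_signal": dataclasses.astuple(ann.polya_signal)
                if ann.polya_signal else None,
                "signal_to_tail_bp": ann.signal_to_tail_bp,
            }
            protein_record = protein.translate(
                ann.orf.slice(cdna_record.sequence), cdna_record.id
            )
        except Exception as exc:
            fail("cdna", exc)

    if stage_enabled("protein"):
        cfg = config.stages["protein"]
        if "cdna" in failed:
            report["errors"].append(
                {"stage": "protein", "error": "skipped: cdna stage failed"})
            failed.add("protein")
        elif protein_record is None:
            fail("protein", ValueError("protein stage needs the cdna stage"))
        else:
            try:
                rep = protein.build_feature_report(
                    protein_record, pka_set=cfg["pka_set"])
                report["stages"]["protein"] = json.loads(rep.to_json())
            except Exception as exc:
                fail("protein", exc)

    msa = None
    if stage_enabled("dist"):
        cfg = config.stages["dist"]
        try:
            if cfg["alignment"] == "simulate":
                rng_tree = phylo.random_tree(
                    8, np.random.default_rng(config.seed))
                msa, _ = simulate.evolve_family(rng_tree, 2000, seed=config.seed)
            else:
                msa = aligndist.read_msa(cfg["alignment"])
            dm = aligndist.msa_to_distances(msa, gap_mode=cfg["gap_mode"])
            report["stages"]["dist"] = {
                "taxa": dm.taxa,
                "matrix": [[round(x, 6) for x in row] for row in dm.d],
                "gap_mode": cfg["gap_mode"],
            }
        except Exception as exc:
            fail("dist", exc)

    if stage_enabled("tree"):
        cfg = config.stages["tree"]
        if "dist" in failed or msa is None:
            report["errors"].append(
                {"stage": "tree", "error": "skipped: dist stage unavailable"})
            failed.add("tree")
        else:
            try:
                t = phylo.bootstrap_support(
                    msa, n_reps=int(cfg["bootstrap"]), seed=config.seed,
                    gap_mode=config.stages["dist"]["gap_mode"])
                if cfg["outgroup"]:
                    t = phylo.root_by_outgroup(t, cfg["outgroup"])
                if cfg["collapse"]:
                    t = phylo.collapse_low_support(t, float(cfg["cutoff"]))
                report["stages"]["tree"] = {
                    "newick": phylo.to_newick(t),
                    "n_bootstrap": int(cfg["bootstrap"]),
                    "support_cutoff": float(cfg["cutoff"]),
                    "supports": sorted(
                        round(n.support, 1)
                        for n in phylo.bipartitions(t).values()
                        if n.support is not None),
                }
            except Exception as exc:
                fail("tree", exc)

    if stage_enabled("sirna"):
        cfg = config.stages["sirna"]
        try:
            if cfg["background"] == "simulate":
                target = (cdna_record.sequence if cdna_record is not None
                          else simulate.make_cdna(seed=config.seed)[0].sequence)
                db, _ = simulate.make_transcriptome(target, seed=config.seed)
            else:
                records = cdna.read_fasta(cfg["background"])
                db = sirna.TranscriptDb(
                    {r.id: r.sequence for r in records}, records[0].id)
            mirnas = (sirna.MirnaSeedDb.from_tsv(cfg["mirnas"])
                      if cfg["mirnas"] else None)
            params = sirna.DesignParams(
                max_gc=float(cfg["max_gc"]), gc_window=cfg["gc_window"],
                max_run=int(cfg["max_run"]), min_block=int(cfg["min_block"]))
            result = sirna.design(db, mirnas, params,
                                  top_k=cfg["top_k"])
            top = result.survivors[0] if result.survivors else None
            stage: dict[str, Any] = {
                "n_candidates": len(result.candidates),
                "n_survivors": len(result.survivors),
                "attrition": result.attrition,
            }
            if top is not None:
                control = sirna.scramble_control(
                    top, config.seed, db, min_block=int(cfg["min_block"]))
                stage["top_candidate"] = {
                    "start": top.target_start,
                    "duplex_sense": top.duplex_sense,
                    "duplex_antisense": top.duplex_antisense,
                    "gc_percent": round(top.gc_percent(), 1),
                }
                stage["scrambled_control"] = control.duplex_sense
            report["stages"]["sirna"] = stage
        except Exception as exc:
            fail("sirna", exc)

    if stage_enabled("quantify"):
        cfg = config.stages["quantify"]
        try:
            if cfg["table"] == "simulate":
                table, _ = simulate.make_intensity_table(seed=config.seed)
            else:
                table = quantify.read_table(cfg["table"])
            summary = quantify.summarize(table)
            report["stages"]["quantify"] = json.loads(summary.to_json())
        except Exception as exc:
            fail("quantify", exc)

    return report
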