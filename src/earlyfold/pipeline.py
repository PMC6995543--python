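"""End-to-end orchestration: structures -> codes -> compliance statuses ->
contingency tables -> correlation screen, with a machine-readable manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from importlib.metadata import version as _dist_version

from .contingency import (
    build_table,
    correlation_screen,
    export_screen,
    extract_windows,
    negative_significant,
    scale_smaller,
)
from .early_stage import (
    CodeIntervalTable,
    EllipseSpec,
    default_code_table,
    default_ellipse,
    encode_domain,
    export_encoding,
)
from .errors import EarlyfoldError
from .fod import HydrophobicityScale, default_scale, trim_classify
from .structure_io import (
    DomainStructure,
    load_range_config,
    read_structure,
    require_analysable,
    slice_domain,
)


@dataclass
class PipelineConfig:
    """Thresholds and references driving a run.

    Defaults are the analysis constants: RD threshold 0.5, minimum status
    run 4, window length 4, alpha 0.05, critical value 1.96.
    """

    ellipse: EllipseSpec | None = None
    code_table: CodeIntervalTable | None = None
    scale: HydrophobicityScale | None = None
    fod_threshold: float = 0.5
    min_run: int = 4
    window: int = 4
    alpha: float = 0.05
    critical_value: float = 1.96
    cells: str = "all"
    cutoff_c: float = 9.0
    trim_metric: str = "abs"
    seed: int = 0

    def resolve(self) -> "PipelineConfig":
        return PipelineConfig(
            ellipse=self.ellipse or default_ellipse(),
            code_table=self.code_table or default_code_table(),
            scale=self.scale or default_scale(),
            fod_threshold=self.fod_threshold,
            min_run=self.min_run,
            window=self.window,
            alpha=self.alpha,
            critical_value=self.critical_value,
            cells=self.cells,
            cutoff_c=self.cutoff_c,
            trim_metric=self.trim_metric,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        resolved = self.resolve()
        return {
            "ellipse": resolved.ellipse.to_dict(),
            "code_table": [list(e) for e in resolved.code_table.entries],
            "scale": {k: float(v) for k, v in sorted(resolved.scale.values.items())},
            "fod_threshold": self.fod_threshold,
            "min_run": self.min_run,
            "window": self.window,
            "alpha": self.alpha,
            "critical_value": self.critical_value,
            "cells": self.cells,
            "cutoff_c": self.cutoff_c,
            "trim_metric": self.trim_metric,
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ellipse = EllipseSpec.from_dict(raw["ellipse"]) if "ellipse" in raw else None
        table = (
            CodeIntervalTable(entries=tuple(tuple(e) for e in raw["code_table"]))
            if "code_table" in raw
            else None
        )
        scale = (
            HydrophobicityScale(raw["scale"]) if "scale" in raw else None
        )
        kwargs = {
            k: raw[k]
            for k in (
                "fod_threshold", "min_run", "window", "alpha", "critical_value",
                "cells", "cutoff_c", "trim_metric", "seed",
            )
            if k in raw
        }
        return cls(ellipse=ellipse, code_table=table, scale=scale, **kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunResult:
    out_dir: Path
    manifest: dict
    negative_tetrapeptides: list[str] = field(default_factory=list)


def _load_domains(inputs, ranges_path=None) -> list[DomainStructure]:
    """Inputs: DomainStructure objects, or PDB paths resolved via a range TSV."""
    domains: list[DomainStructure] = []
    if ranges_path is not None:
        config = load_range_config(ranges_path)
        base = Path(ranges_path).parent
        chains: dict[tuple[str, str], DomainStructure] = {}
        for entry in config.entries:
            key = (entry.file, entry.chain)
            if key not in chains:
                chains[key] = read_structure(base / entry.file, entry.chain)
            domains.append(slice_domain(chains[key], entry))
        return domains
    for item in inputs or []:
        if isinstance(item, DomainStructure):
            domains.append(item)
        else:
            raise TypeError(f"unsupported input {item!r}")
    return domains


def run_pipeline(
    config: PipelineConfig,
    inputs=None,
    ranges_path: str | Path | None = None,
    out_dir: str | Path = "earlyfold_run",
) -> RunResult:
    """Run the full flow on a set of domains and write a run directory.

    Per-domain encodings and statuses, the two contingency tables, the
    scaling factor, both screen reports and a manifest land in
    ``out_dir``.  Domains failing a stage are skipped and recorded.
    """
    resolved = config.resolve()
    out = Path(out_dir)
    (out / "domains").mkdir(parents=True, exist_ok=True)
    domains = _load_domains(inputs, ranges_path)

    processed, skipped = [], []
    pairs = []
    for dom in domains:
        try:
            require_analysable(dom)
            assignment = encode_domain(dom, resolved.ellipse, resolved.code_table)
            status = trim_classify(
                dom,
                resolved.scale,
                threshold=resolved.fod_threshold,
                cutoff_c=resolved.cutoff_c,
                trim_metric=resolved.trim_metric,
            )
            dom_pairs = extract_windows(
                dom.sequence,
                assignment.code_string,
                statuses=status.status_string,
                origin_compliant=status.origin_compliant,
                min_run=resolved.min_run,
            )
        except EarlyfoldError as exc:
            reason = str(exc)
            if "too short" in reason:
                reason = "too short"
            skipped.append({"id": dom.id, "reason": reason})
            continue
        pairs.extend(dom_pairs)
        export_encoding(assignment, out / "domains" / f"{dom.id}.encoding.tsv")
        with open(out / "domains" / f"{dom.id}.status.json", "w") as fh:
            json.dump(
                {
                    "id": dom.id,
                    "original_rd": status.original_rd,
                    "final_rd": status.final_rd,
                    "origin_compliant": status.origin_compliant,
                    "never_compliant": status.never_compliant,
                    "statuses": status.status_string,
                },
                fh,
                sort_keys=True,
            )
        processed.append(
            {
                "id": dom.id,
                "n_residues": len(dom),
                "n_windows": len(dom_pairs),
                "origin_compliant": status.origin_compliant,
            }
        )

    if not processed:
        raise EarlyfoldError("empty surviving set: every domain was skipped")

    tc = build_table([p for p in pairs if p.label == "compliant"], "compliant")
    tn = build_table([p for p in pairs if p.label == "noncompliant"], "noncompliant")
    tc.to_tsv(out / "table_compliant.tsv")
    tn.to_tsv(out / "table_noncompliant.tsv")

    screen_info = {}
    negatives: list[str] = []
    factor = None
    if tc.total > 0 and tn.total > 0:
        sc, sn, factor = scale_smaller(tc, tn)
        for mode in ("columns", "rows"):
            records = correlation_screen(
                sc, sn, mode=mode,
                alpha=resolved.alpha,
                critical=resolved.critical_value,
                cells=resolved.cells,
            )
            export_screen(records, out / f"screen_{mode}.tsv")
            neg = negative_significant(records)
            screen_info[mode] = {
                "n_keys": len(records),
                "n_negative_significant": len(neg),
            }
            if mode == "columns":
                negatives = [r.key for r in neg]
        with open(out / "negative_tetrapeptides.tsv", "w") as fh:
            fh.write("seq4\n")
            for key in negatives:
                fh.write(key + "\n")

    manifest = {
        "package_version": _dist_version("earlyfold"),
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_domains": len(domains),
        "processed": processed,
        "skipped": skipped,
        "table_totals": {"compliant": tc.total, "noncompliant": tn.total},
        "scaling_factor": factor,
        "screen": screen_info,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return RunResult(out_dir=out, manifest=manifest, negative_tetrapeptides=negatives)


def tables_from_corpus(corpus) -> tuple:
    """Build the two tables from a :class:`PlantedCorpus`."""
    pairs = []
    for dom in corpus.compliant + corpus.noncompliant:
        pairs.extend(
            extract_windows(
                dom.aa_seq,
                dom.code_seq,
                statuses=dom.statuses,
                origin_compliant=dom.origin_compliant,
            )
        )
    tc = build_table([p for p in pairs if p.label == "compliant"], "compliant")
    tn = build_table([p for p in pairs if p.label == "noncompliant"], "noncompliant")
    return tc, tn
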