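"""Pipeline orchestration, run configuration, and the reference assay panel.

The panel shipped under ``fixtures/hla_class1_assays.tsv`` lists the
validated allele-specific and locus-specific HLA class I assays for the
MSC-Tert clone DD8 typing (primer names carrying ATG-anchored start
coordinates, sequences, fragment lengths, mRNA fold-inductions and
antibody-binding capacities). ``fixtures_check`` re-derives every
quantity that the panel makes checkable — fragment lengths from the
coordinate labels, ABC fold ratios, rounded fold-inductions — and
reports observed vs expected, flagging internally inconsistent rows
rather than silently correcting them.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import cdc_scoring, flow_quant, qpcr_quant
from .allele_db import parse_allele_fasta
from .primer_design import DesignConstraints, amplicon_length_from_labels, design_allele_specific
from .flow_quant import fold_expression

__all__ = [
    "RunConfig",
    "run_pipeline",
    "load_reference_assays",
    "parse_label",
    "fixtures_check",
]

_LABEL_RE = re.compile(r"(minus)?(\d+)\s*[FR]")


def parse_label(primer_name: str) -> int:
    """ATG-anchored start coordinate embedded in a primer name.

    ``HLA-A020101-272F`` → 272; ``HLA A-minus2F`` → −2.
    """
    m = _LABEL_RE.search(primer_name)
    if m is None:
        raise ValueError(f"no coordinate label in primer name {primer_name!r}")
    value = int(m.group(2))
    return -value if m.group(1) else value


def load_reference_assays() -> pd.DataFrame:
    """The shipped HLA class I assay panel as a DataFrame."""
    with resources.files("allelequant.fixtures").joinpath("hla_class1_assays.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"printed_bp": "Int64"})


def fixtures_check() -> dict:
    """Observed-vs-expected table over the shipped assay panel."""
    panel = load_reference_assays()
    label_checks = []
    for row in panel.itertuples():
        if not isinstance(row.rev_name, str) or pd.isna(row.printed_bp):
            continue
        f_label = parse_label(row.fwd_name)
        r_label = parse_label(row.rev_name)
        computed = amplicon_length_from_labels(f_label, r_label)
        label_checks.append(
            {
                "assay": row.assay,
                "f_label": f_label,
                "r_label": r_label,
                "computed_bp": computed,
                "printed_bp": int(row.printed_bp),
                "consistent": computed == int(row.printed_bp),
            }
        )
    abc = panel.dropna(subset=["abc"]).set_index("target")["abc"].to_dict()
    abc_folds = {}
    if {"A*02:01:01", "B*07:02", "B*27:02"} <= set(abc):
        abc_folds = {
            "A2_over_B7": fold_expression(abc["A*02:01:01"], abc["B*07:02"]),
            "A2_over_B27": fold_expression(abc["A*02:01:01"], abc["B*27:02"]),
            "B7_over_B27": fold_expression(abc["B*07:02"], abc["B*27:02"]),
        }
    mrna = panel.dropna(subset=["mrna_fold"]).set_index("target")["mrna_fold"].to_dict()
    mrna_folds = {t: fold_expression(v, 1.0) for t, v in mrna.items()}
    return {"label_checks": label_checks, "abc_folds": abc_folds, "mrna_fold_rounded": mrna_folds}


_CONFIG_KEYS = {
    "alleles",
    "wells",
    "beads",
    "samples",
    "cdc",
    "design_targets",
    "design",
    "plasmid_bp",
    "volume_ul",
    "reference",
    "cdc_threshold",
    "seed",
    "outdir",
}


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run.

    Any stage whose inputs are not configured is skipped; configured
    input paths must exist before anything runs. Unknown keys are
    rejected rather than ignored.
    """

    outdir: str
    alleles: str | None = None
    wells: str | None = None
    beads: str | None = None
    samples: str | None = None
    cdc: str | None = None
    design_targets: list[str] = field(default_factory=list)
    design: dict = field(default_factory=dict)
    plasmid_bp: float = 4031.0
    volume_ul: float = 5.0
    reference: str = "FBXL12"
    cdc_threshold: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alleles", "wells", "beads", "samples", "cdc"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured {name} file does not exist: {path}")
        if self.design_targets and self.alleles is None:
            raise ValueError("design_targets configured without an alleles database")
        if (self.beads is None) != (self.samples is None):
            raise ValueError("flow stage needs both beads and samples tables")
        DesignConstraints.from_dict(self.design)  # validates keys early

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Every stage writes its own JSON report under ``outdir``; a top-level
    ``summary.json`` cross-links them. A stage failure is recorded and
    its dependents are skipped; the summary's ``ok`` flag reflects
    whether every attempted stage succeeded.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}, "reports": {}, "ok": True}

    def record(stage: str, status: str, detail: str = "") -> None:
        summary["stages"][stage] = {"status": status, **({"detail": detail} if detail else {})}
        if status == "failed":
            summary["ok"] = False

    db = None
    if config.alleles:
        try:
            db = parse_allele_fasta(Path(config.alleles).read_text())
            record("allele_db", "done", f"{len(db)} alleles, loci {db.loci()}")
        except Exception as exc:  # noqa: BLE001 - stage errors are reported, not raised
            record("allele_db", "failed", str(exc))
    else:
        record("allele_db", "skipped")

    if config.design_targets:
        if db is None:
            record("design", "skipped", "allele database unavailable")
        else:
            try:
                constraints = DesignConstraints.from_dict(config.design)
                designs = {}
                for target in config.design_targets:
                    result = design_allele_specific(db, target, constraints)
                    designs[target] = {
                        "status": result.status,
                        "n_pairs": len(result.pairs),
                        "failure_counts": result.failure_counts,
                        "pairs": [
                            {
                                "fwd_seq": p.forward.sequence,
                                "fwd_label": p.forward.label_coord,
                                "fwd_tm": p.forward.tm,
                                "rev_seq": p.reverse.sequence,
                                "rev_label": p.reverse.label_coord,
                                "rev_tm": p.reverse.tm,
                                "amplicon_bp": p.amplicon_len,
                            }
                            for p in result.pairs
                        ],
                    }
                path = outdir / "design_report.json"
                path.write_text(json.dumps(designs, indent=1, sort_keys=True))
                summary["reports"]["design"] = path.name
                record("design", "done", f"{len(designs)} targets")
            except Exception as exc:  # noqa: BLE001
                record("design", "failed", str(exc))
    else:
        record("design", "skipped")

    if config.wells:
        try:
            wells = pd.read_csv(config.wells, sep="\t")
            report = qpcr_quant.analyze_qpcr_wells(
                wells,
                plasmid_bp=config.plasmid_bp,
                volume_ul=config.volume_ul,
                reference=config.reference,
            )
            path = outdir / "qpcr_report.json"
            path.write_text(json.dumps(report, indent=1, sort_keys=True))
            summary["reports"]["qpcr"] = path.name
            targets = sorted(wells.target.unique())
            summary["qpcr_targets"] = targets
            record("qpcr", "done", f"{len(targets)} targets")
        except Exception as exc:  # noqa: BLE001
            record("qpcr", "failed", str(exc))
    else:
        record("qpcr", "skipped")

    if config.beads and config.samples:
        try:
            report = flow_quant.analyze_flow(
                pd.read_csv(config.beads, sep="\t"), pd.read_csv(config.samples, sep="\t")
            )
            path = outdir / "flow_report.json"
            path.write_text(json.dumps(report, indent=1, sort_keys=True))
            summary["reports"]["flow"] = path.name
            record("flow", "done", f"{len(report['samples'])} stained populations")
        except Exception as exc:  # noqa: BLE001
            record("flow", "failed", str(exc))
    else:
        record("flow", "skipped")

    if config.cdc:
        try:
            report = cdc_scoring.analyze_cdc(
                pd.read_csv(config.cdc, sep="\t"), threshold=config.cdc_threshold
            )
            path = outdir / "cdc_report.json"
            path.write_text(json.dumps(report, indent=1, sort_keys=True))
            summary["reports"]["cdc"] = path.name
            record("cdc", "done")
        except Exception as exc:  # noqa: BLE001
            record("cdc", "failed", str(exc))
    else:
        record("cdc", "skipped")

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
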