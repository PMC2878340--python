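"""Synthetic inputs with recorded ground truth for every pipeline stage.

Emulates the structural features the pipeline depends on — a polymorphic
multi-locus allele family with engineered 3′-discriminating SNPs and
exon models, qPCR runs with known standard-curve and copy-number truth,
bead panels and cell MFIs with known antibody-binding capacities, and
binomial CDC well counts with known kill fractions — without attempting
to reproduce real IMGT/HLA polymorphism statistics.

Forward models match the fitting models of the analysis modules exactly:
CT = intercept + slope·log10(copies) + N(0, σ); log-normal MFI noise
around a log–log linear calibration; binomial dead-cell counts.

All generators are pure functions of (parameters, seed). A master seed
is split into named sub-streams (one integer id per assay) so adding or
reordering one generator never perturbs another's draws.

The default scenario mirrors the shape of the motivating study: three
loci by four alleles, six typed target alleles plus one reference gene,
four IFNγ timepoints (0/24/48/72 h), three independent qPCR
experiments, and duplicate CDC wells.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .allele_db import AlleleDatabase, AlleleRecord, index_to_coord, write_allele_fasta
from .qpcr_quant import conc_to_copies

__all__ = [
    "stream_rng",
    "gen_allele_family",
    "gen_qpcr_run",
    "gen_bead_panel",
    "gen_cell_mfi",
    "gen_cdc_counts",
    "simulate_scenario",
]

# named sub-streams of the master seed; ids are frozen — never renumber
_STREAMS = {"alleles": 1, "qpcr": 2, "beads": 3, "cells": 4, "cdc": 5}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# study-shaped defaults: constitutive target/reference mRNA ratio and
# 72 h IFNgamma fold-induction per typed allele
DEFAULT_QPCR_TARGETS = {
    "A*01:01": {"ratio_0h": 1.6, "fold_72h": 8.9},
    "A*02:01": {"ratio_0h": 2.0, "fold_72h": 10.7},
    "B*01:01": {"ratio_0h": 0.9, "fold_72h": 30.1},
    "B*02:01": {"ratio_0h": 1.8, "fold_72h": 41.8},
    "C*01:01": {"ratio_0h": 1.7, "fold_72h": 18.6},
    "C*02:01": {"ratio_0h": 7.4, "fold_72h": 5.4},
}
# fraction of the (log) induction reached at each timepoint: fast early
# rise culminating at 72 h
INDUCTION_SHAPE = {0: 0.0, 24: 0.6, 48: 0.85, 72: 1.0}

DEFAULT_ABC_TRUTH = {
    "HLA-A2": {0: 204_370.0, 72: 204_370.0 * 3},
    "HLA-B7": {0: 12_076.0, 72: 12_076.0 * 50},
    "HLA-B27": {0: 5_174.0, 72: 5_174.0 * 92},
}

DEFAULT_CDC_KILL = {"anti-A": 0.96, "anti-B": 0.28, "anti-Cw": 0.09, "AB": 0.09}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one named sub-stream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _exon_model(rng: np.random.Generator, cds_start: int, cds_len: int, exon_count: int):
    min_exon = 30
    if cds_len < min_exon * exon_count:
        raise ValueError("coding region too short for the requested exon count")
    extra = rng.multinomial(cds_len - min_exon * exon_count, [1 / exon_count] * exon_count)
    sizes = min_exon + extra
    exons = []
    pos = cds_start
    for size in sizes:
        exons.append((int(pos), int(pos + size)))
        pos += size
    return tuple(exons)


def gen_allele_family(
    seed: int,
    n_loci: int = 3,
    n_alleles: int = 4,
    length: int = 1200,
    snp_rate: float = 0.005,
    engineered_per_allele: int = 1,
    exon_count: int = 8,
    gc: float = 0.62,
    atg_offset: int = 60,
    utr3_len: int = 45,
) -> tuple[AlleleDatabase, dict]:
    """Generate an equal-length, ungapped multi-locus allele family.

    Loci are drawn independently (so cross-locus divergence far exceeds
    within-locus divergence and every locus has private UTRs); alleles
    within a locus differ by random SNPs at ``snp_rate`` plus, per
    allele, ``engineered_per_allele`` engineered columns at which that
    allele's base differs from EVERY other allele in the family — the
    guaranteed 3′-discriminating sites. The ATG sits at a fixed offset
    with ≥40 nt of 5′UTR so negative ATG-anchored coordinates occur.
    GC content defaults to 0.62, typical of HLA class I cDNA.

    Returns the database and a truth record (engineered sites per allele
    in ATG-anchored coordinates, exon boundaries, all parameters).
    """
    if length < 300:
        raise ValueError("family sequences must be at least 300 nt")
    if atg_offset < 40:
        raise ValueError("need >=40 nt of 5'UTR ahead of the ATG")
    rng = stream_rng(seed, "alleles")
    margin = 50
    atg_span = set(range(atg_offset, atg_offset + 3))
    eligible = [i for i in range(margin, length - margin) if i not in atg_span]
    n_engineered = n_loci * n_alleles * engineered_per_allele
    if n_engineered > len(eligible):
        raise ValueError(
            f"cannot place {n_engineered} engineered sites in {len(eligible)} eligible positions"
        )
    engineered_cols = sorted(rng.choice(len(eligible), size=n_engineered, replace=False).tolist())
    engineered_cols = [eligible[i] for i in engineered_cols]
    protected = set(engineered_cols) | atg_span

    loci = [chr(ord("A") + i) for i in range(n_loci)]
    cds_len = length - atg_offset - utr3_len
    seqs: dict[str, np.ndarray] = {}
    exon_models: dict[str, tuple] = {}
    for locus in loci:
        base = _random_bases(rng, length, gc)
        base[atg_offset : atg_offset + 3] = np.frombuffer(b"ATG", dtype=np.uint8)
        exon_models[locus] = _exon_model(rng, atg_offset, cds_len, exon_count)
        for a in range(n_alleles):
            allele = base.copy()
            if snp_rate > 0:
                hits = np.nonzero(rng.random(length) < snp_rate)[0]
                for pos in hits:
                    if int(pos) in protected:
                        continue
                    current = allele[pos]
                    choices = _BASES[_BASES != current]
                    allele[pos] = rng.choice(choices)
            seqs[f"{locus}*{a + 1:02d}:01"] = allele

    names = list(seqs)
    truth_sites: dict[str, list[int]] = {name: [] for name in names}
    col_iter = iter(engineered_cols)
    for name in names:
        for _ in range(engineered_per_allele):
            col = next(col_iter)
            common = rng.choice(_BASES)
            for other in names:
                seqs[other][col] = common
            variant = rng.choice(_BASES[_BASES != common])
            seqs[name][col] = variant
            truth_sites[name].append(col)

    db = AlleleDatabase()
    for name in names:
        locus = name.split("*", 1)[0]
        db.add(
            AlleleRecord(
                name=name,
                cdna=seqs[name].tobytes().decode("ascii"),
                atg_index=atg_offset,
                exons=exon_models[locus],
            )
        )
    truth = {
        "seed": int(seed),
        "params": {
            "n_loci": n_loci,
            "n_alleles": n_alleles,
            "length": length,
            "snp_rate": snp_rate,
            "engineered_per_allele": engineered_per_allele,
            "exon_count": exon_count,
            "gc": gc,
            "atg_offset": atg_offset,
            "utr3_len": utr3_len,
        },
        "alleles": {
            name: {
                "engineered_indices": truth_sites[name],
                "engineered_coords": [index_to_coord(db[name], i) for i in truth_sites[name]],
            }
            for name in names
        },
        "exons": {locus: [list(e) for e in exon_models[locus]] for locus in loci},
    }
    return db, truth


def gen_qpcr_run(
    seed: int,
    targets: dict[str, dict] | None = None,
    reference: str = "FBXL12",
    sample: str = "DD8",
    timepoints: tuple[int, ...] = (0, 24, 48, 72),
    n_experiments: int = 3,
    n_replicates: int = 2,
    noise_sd_ct: float = 0.1,
    plasmid_bp: float = 4031.0,
    volume_ul: float = 5.0,
    ref_copies: float = 1e5,
    standard_concs: tuple[float, ...] = tuple(2e-2 / 10**k for k in range(6)),
) -> tuple[pd.DataFrame, dict]:
    """Simulate qPCR plates: plasmid standards plus unknown cDNA wells.

    Per experiment and target an amplification line is drawn with slope
    in [−3.45, −3.33] (efficiency 1.95–2.0) and intercept in [38, 40];
    standards follow six serial 10-fold dilutions from 2×10⁻² ng/µL.
    Target copy numbers encode the configured constitutive ratios and
    fold inductions via the log-fractional induction shape. Gaussian CT
    noise is ``noise_sd_ct``.
    """
    if noise_sd_ct < 0:
        raise ValueError("CT noise must be non-negative")
    targets = targets if targets is not None else DEFAULT_QPCR_TARGETS
    for name, spec in targets.items():
        if spec["ratio_0h"] <= 0 or spec["fold_72h"] <= 0:
            raise ValueError(f"target {name}: ratios and folds must be positive")
    rng = stream_rng(seed, "qpcr")
    all_targets = list(targets) + [reference]

    rows = []
    truth_curves = {}
    for exp in range(1, n_experiments + 1):
        run_id = f"exp{exp}"
        for target in all_targets:
            slope = float(rng.uniform(-3.45, -3.33))
            intercept = float(rng.uniform(38.0, 40.0))
            truth_curves[f"{run_id}:{target}"] = {"slope": slope, "intercept": intercept}
            for conc in standard_concs:
                copies = conc_to_copies(conc, volume_ul, plasmid_bp)
                for rep in range(1, n_replicates + 1):
                    ct = intercept + slope * np.log10(copies) + rng.normal(0, noise_sd_ct)
                    rows.append(
                        {
                            "run_id": run_id,
                            "target": target,
                            "sample": "standard",
                            "timepoint_h": -1,
                            "ct": float(ct),
                            "replicate": rep,
                            "role": "standard",
                            "conc_ng_ul": conc,
                        }
                    )
            for tp in timepoints:
                if target == reference:
                    copies = ref_copies
                else:
                    spec = targets[target]
                    fold = spec["fold_72h"] ** INDUCTION_SHAPE[tp]
                    copies = ref_copies * spec["ratio_0h"] * fold
                for rep in range(1, n_replicates + 1):
                    ct = intercept + slope * np.log10(copies) + rng.normal(0, noise_sd_ct)
                    rows.append(
                        {
                            "run_id": run_id,
                            "target": target,
                            "sample": sample,
                            "timepoint_h": tp,
                            "ct": float(ct),
                            "replicate": rep,
                            "role": "unknown",
                            "conc_ng_ul": float("nan"),
                        }
                    )
    truth = {
        "seed": int(seed),
        "curves": truth_curves,
        "reference": reference,
        "ref_copies": ref_copies,
        "plasmid_bp": plasmid_bp,
        "volume_ul": volume_ul,
        "noise_sd_ct": noise_sd_ct,
        "targets": {
            name: {
                "ratio_0h": spec["ratio_0h"],
                "fold_72h": spec["fold_72h"],
                "ratios_by_timepoint": {
                    str(tp): spec["ratio_0h"] * spec["fold_72h"] ** INDUCTION_SHAPE[tp]
                    for tp in timepoints
                },
            }
            for name, spec in targets.items()
        },
    }
    return pd.DataFrame(rows), truth


def gen_bead_panel(
    seed: int,
    abc_levels: tuple[float, ...] = (4700.0, 14500.0, 45000.0, 143000.0, 440000.0),
    slope: float = 1.0,
    intercept: float = 2.3,
    cv: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a bead calibration panel with known IgG loads.

    Truth model: log10(ABC) = intercept + slope·log10(MFI); observed
    MFIs carry multiplicative log-normal noise of coefficient of
    variation ``cv``.
    """
    if cv < 0 or slope <= 0:
        raise ValueError("cv must be non-negative and slope positive")
    rng = stream_rng(seed, "beads")
    sigma = np.sqrt(np.log1p(cv**2))
    rows = []
    for i, abc in enumerate(abc_levels, start=1):
        mfi_true = 10.0 ** ((np.log10(abc) - intercept) / slope)
        mfi = float(mfi_true * np.exp(rng.normal(0, sigma)))
        rows.append({"bead_id": f"bead{i}", "abc": abc, "mfi": round(mfi, 4)})
    truth = {
        "seed": int(seed),
        "slope": slope,
        "intercept": intercept,
        "cv": cv,
        "abc_levels": list(abc_levels),
    }
    return pd.DataFrame(rows), truth


def gen_cell_mfi(
    seed: int,
    calibration_truth: dict,
    abc_truth: dict[str, dict[int, float]] | None = None,
    isotype_mfi: float = 5.0,
    cv: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Simulate stained-cell MFIs from known per-sample ABC values.

    Each specific stain's true MFI inverts the bead calibration at the
    sample's true ABC; isotype controls sit at a fixed low MFI. Both
    carry log-normal noise.
    """
    abc_truth = abc_truth if abc_truth is not None else DEFAULT_ABC_TRUTH
    rng = stream_rng(seed, "cells")
    sigma = np.sqrt(np.log1p(cv**2))
    a, b = calibration_truth["intercept"], calibration_truth["slope"]
    rows = []
    for sample_name, series in abc_truth.items():
        for tp, abc in sorted(series.items()):
            if abc <= 0:
                raise ValueError(f"{sample_name}: true ABC must be positive")
            mfi_true = 10.0 ** ((np.log10(abc) - a) / b)
            rows.append(
                {
                    "sample": sample_name,
                    "stain": "specific",
                    "mfi": round(float(mfi_true * np.exp(rng.normal(0, sigma))), 4),
                    "timepoint_h": tp,
                }
            )
            rows.append(
                {
                    "sample": sample_name,
                    "stain": "isotype",
                    "mfi": round(float(isotype_mfi * np.exp(rng.normal(0, sigma))), 4),
                    "timepoint_h": tp,
                }
            )
    truth = {"seed": int(seed), "abc": abc_truth, "isotype_mfi": isotype_mfi, "cv": cv}
    return pd.DataFrame(rows), truth


def gen_cdc_counts(
    seed: int,
    p_kill: dict[str, float] | None = None,
    n_cells: int = 200,
    n_wells: int = 6,
    sample: str = "MSC",
) -> tuple[pd.DataFrame, dict]:
    """Simulate CDC wells: dead-cell counts are Binomial(n_cells, p_kill)."""
    p_kill = p_kill if p_kill is not None else DEFAULT_CDC_KILL
    if n_cells <= 0 or n_wells <= 0:
        raise ValueError("cells per well and well count must be positive")
    for serum, p in p_kill.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"serum {serum}: kill fraction must be in [0, 1]")
    rng = stream_rng(seed, "cdc")
    rows = []
    for serum, p in p_kill.items():
        for rep in range(1, n_wells + 1):
            red = int(rng.binomial(n_cells, p))
            rows.append(
                {
                    "sample": sample,
                    "serum_id": serum,
                    "replicate": rep,
                    "red": red,
                    "green": n_cells - red,
                }
            )
    truth = {"seed": int(seed), "p_kill": p_kill, "n_cells": n_cells, "n_wells": n_wells}
    return pd.DataFrame(rows), truth


def simulate_scenario(seed: int, outdir: str | Path, scenario: str = "default") -> dict:
    """Write a complete fixture set (FASTA + four TSVs + truth sidecar).

    The default scenario produces a 3-locus × 4-allele family, qPCR
    wells for six typed alleles plus the reference gene over four
    timepoints and three experiments, a five-bead calibration panel,
    cell MFIs for three antigens, and six CDC wells per serum.
    Regeneration from the same (seed, scenario) is byte-identical.
    """
    if scenario != "default":
        raise ValueError(f"unknown scenario {scenario!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    db, family_truth = gen_allele_family(seed)
    wells, qpcr_truth = gen_qpcr_run(seed)
    beads, bead_truth = gen_bead_panel(seed)
    samples, cell_truth = gen_cell_mfi(seed, bead_truth)
    cdc, cdc_truth = gen_cdc_counts(seed)

    (outdir / "alleles.fasta").write_text(write_allele_fasta(db))
    wells.to_csv(outdir / "wells.tsv", sep="\t", index=False)
    beads.to_csv(outdir / "beads.tsv", sep="\t", index=False)
    samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    cdc.to_csv(outdir / "cdc.tsv", sep="\t", index=False)

    truth = {
        "seed": int(seed),
        "scenario": scenario,
        "family": family_truth,
        "qpcr": qpcr_truth,
        "flow_beads": bead_truth,
        "flow_cells": cell_truth,
        "cdc": cdc_truth,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return truth
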