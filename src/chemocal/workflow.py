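"""End-to-end orchestration of the GC-IMS-guided NIRS calibration workflow.

Stage graph (all deterministic given the config seed):

1. simulate GC-IMS peak table and NIR spectra (both instrument ranges);
2. internal-standard normalization and monomer/dimer deduplication;
3. OPLS-DA marker screening for the two contrasts the study reports:
   raw-vs-processed (S vs P2) and early-vs-late storage (P2 vs P56);
4. composite flavor index (processing stage 0/1, all 7 samples) and
   deterioration index (storage months, 6 processed samples);
5. PLSR calibration of each index from each spectral range across the 7
   preprocessing methods (spectrum-level 80/20 split, 5-fold-CV LV choice);
6. 200-iteration permutation validation of the best model per block;
7. optional storage-class classification screen (SVM/KNN/RF, 10-fold CV).

Reports are plain CSV/JSON; ``run_all`` returns everything in a RunBundle
and can additionally write a run directory with a manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from . import index as idx
from .config import RunConfig
from .containers import PeakTable, SpectraSet
from .oplsda import screen_markers
from .preprocess import PreprocessSpec
from .synthetic import generate_peak_table, generate_spectra

FLAVOR = "flavor"
DETERIORATION = "deterioration"

# fixed offsets decorrelate stage RNG streams derived from one user seed
_SEED_SPECTRA = {"900-1700": 11, "1300-2500": 23}
_SEED_SPLIT = 41
_SEED_CV = 59
_SEED_PERM = 67
_SEED_SCREEN = 73
_SEED_CLASSIFY = 89


@dataclass
class CalibrationBlock:
    kind: str
    range_name: str
    report: pd.DataFrame
    results: dict
    best_method: str
    split: cal.SplitPlan
    permutation: cal.PermutationReport | None = None


@dataclass
class RunBundle:
    config: RunConfig
    peak_table: PeakTable
    dedup_log: pd.DataFrame
    markers: dict
    indices: dict
    spectra: dict
    blocks: dict
    classification: pd.DataFrame | None = None

    @property
    def calibration_report(self) -> pd.DataFrame:
        return pd.concat([b.report for b in self.blocks.values()], ignore_index=True)

    @property
    def permutation_summary(self) -> pd.DataFrame:
        rows = []
        for (kind, rng), block in self.blocks.items():
            p = block.permutation
            if p is None:
                continue
            rows.append(
                {
                    "kind": kind,
                    "range": rng,
                    "best_method": block.best_method,
                    "original_R2": p.original_r2,
                    "original_Q2": p.original_q2,
                    "R2_intercept": p.r2_intercept,
                    "Q2_intercept": p.q2_intercept,
                    "passed": p.passed,
                }
            )
        return pd.DataFrame(rows)


def prepare_volatiles(config: RunConfig):
    """Stages 1-2 on the GC-IMS side: simulate, normalize, deduplicate."""
    raw = generate_peak_table(config.design, config.volatile, seed=config.seed)
    normalized = idx.normalize_to_internal_standard(raw)
    dedup, log = idx.deduplicate_forms(normalized)
    return raw, dedup, log


def screen_study_markers(config: RunConfig, table: PeakTable) -> dict:
    """Stage 3: OPLS-DA VIP screening for the study's two contrasts."""
    design = config.design
    matrix = table.replicate_matrix()
    contrasts = {
        FLAVOR: (design.raw_label, design.processed_labels[0]),
        DETERIORATION: (design.processed_labels[0], design.processed_labels[-1]),
    }
    markers = {}
    for kind, (a, b) in contrasts.items():
        sub = matrix.loc[[a, b]]
        groups = sub.index.get_level_values("sample").to_numpy()
        markers[kind] = screen_markers(
            sub.reset_index(drop=True),
            groups,
            threshold=config.thresholds.vip,
            highlight=config.thresholds.vip_highlight,
            seed=config.seed + _SEED_SCREEN,
            sample_groups=groups,
        )
    return markers


def build_study_indices(config: RunConfig, table: PeakTable, markers: dict) -> dict:
    """Stage 4: composite flavor and deterioration indices.

    Flavor: processing stage coded 0 (raw) / 1 (processed) over all 7
    samples. Deterioration: storage months over the 6 processed samples
    (raw excluded, per protocol).
    """
    design = config.design
    all_samples = list(design.sample_labels)
    flavor_response = pd.Series(
        [1.0 if design.is_processed(s) else 0.0 for s in all_samples], index=all_samples
    )
    processed = design.processed_labels
    months_response = pd.Series(
        [design.months_of(s) for s in processed], index=processed
    )
    return {
        FLAVOR: idx.build_index(
            table, all_samples, flavor_response,
            markers[FLAVOR]["compound"].tolist(), kind=FLAVOR,
        ),
        DETERIORATION: idx.build_index(
            table, processed, months_response,
            markers[DETERIORATION]["compound"].tolist(), kind=DETERIORATION,
        ),
    }


def calibrate_block(
    config: RunConfig,
    spectra: SpectraSet,
    composite: idx.CompositeIndex,
    kind: str,
    range_name: str,
    run_permutation: bool = True,
) -> CalibrationBlock:
    """Stages 5-6 for one (index kind, spectral range) block."""
    if kind == DETERIORATION:
        keep = spectra.meta["processed"].to_numpy(dtype=bool)
        spectra = spectra.subset(keep)
    split = cal.make_split(
        spectra, ratio=config.thresholds.split_ratio, seed=config.seed + _SEED_SPLIT
    )
    report, results = cal.calibrate_index(
        spectra,
        composite.values,
        config.preprocess_specs(),
        split,
        lv_grid=config.lv_grid,
        cv_k=config.thresholds.cv_k_pls,
        seed=config.seed + _SEED_CV,
        kind=kind,
        range_name=range_name,
    )
    best_method = report.loc[report["best"], "method"].iloc[0]
    permutation = None
    if run_permutation:
        best = results[best_method]
        permutation = cal.permutation_test(
            best.X_train,
            best.y_train,
            n_lv=best.n_lv,
            n_iter=config.thresholds.n_permutations,
            cv_k=config.thresholds.cv_k_pls,
            seed=config.seed + _SEED_PERM,
            stratify=best.train_labels,
            threshold=config.thresholds.q2_intercept,
        )
    return CalibrationBlock(kind, range_name, report, results, best_method, split, permutation)


def run_all(
    config: RunConfig,
    outdir: str | Path | None = None,
    kinds=(FLAVOR, DETERIORATION),
    ranges=None,
    run_permutation: bool = True,
    run_classification: bool = False,
) -> RunBundle:
    """Execute the full experiment graph; optionally write a run directory."""
    ranges = list(config.range_names if ranges is None else ranges)

    _, table, dedup_log = prepare_volatiles(config)
    markers = screen_study_markers(config, table)
    indices = build_study_indices(config, table, markers)

    spectra = {
        rng: generate_spectra(
            config.design,
            config.spectral_config_for_range(rng),
            seed=config.seed + _SEED_SPECTRA[rng],
        )
        for rng in ranges
    }

    blocks = {}
    for rng in ranges:
        for kind in kinds:
            blocks[(kind, rng)] = calibrate_block(
                config, spectra[rng], indices[kind], kind, rng,
                run_permutation=run_permutation,
            )

    classification = None
    if run_classification:
        screen_specs = [
            PreprocessSpec(m, config.sg_window, config.sg_polyorder)
            for m in ("RAW", "SGFD", "MSCFD", "SNVFD")
        ]
        frames = []
        for rng in ranges:
            split = cal.make_split(
                spectra[rng],
                ratio=config.thresholds.split_ratio,
                seed=config.seed + _SEED_SPLIT,
            )
            frame, _ = cal.classify_screen(
                spectra[rng], screen_specs, split,
                cv_k=config.thresholds.cv_k_classify,
                seed=config.seed + _SEED_CLASSIFY,
                range_name=rng,
            )
            frames.append(frame)
        classification = pd.concat(frames, ignore_index=True)

    bundle = RunBundle(
        config, table, dedup_log, markers, indices, spectra, blocks, classification
    )
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: RunBundle, outdir: str | Path) -> None:
    """Persist all reports as CSV plus a JSON manifest (seeds, checksum)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.peak_table.to_csv(out / "peak_table_normalized.csv")
    bundle.dedup_log.to_csv(out / "dedup_log.csv", index=False)
    for kind, table in bundle.markers.items():
        table.to_csv(out / f"markers_{kind}.csv", index=False, float_format="%.6f")
    index_rows = []
    for kind, composite in bundle.indices.items():
        for sample, value in composite.values.items():
            index_rows.append(
                {
                    "sample": sample,
                    "kind": kind,
                    "value": value,
                    "n_markers": len(composite.markers),
                }
            )
    pd.DataFrame(index_rows).to_csv(
        out / "index_table.csv", index=False, float_format="%.6f"
    )
    bundle.calibration_report.to_csv(
        out / "calibration_report.csv", index=False, float_format="%.6f"
    )
    summary = bundle.permutation_summary
    if not summary.empty:
        summary.to_csv(out / "permutation_summary.csv", index=False, float_format="%.6f")
    if bundle.classification is not None:
        bundle.classification.to_csv(
            out / "classification_report.csv", index=False, float_format="%.6f"
        )
    manifest = {
        "seed": bundle.config.seed,
        "config_checksum": bundle.config.checksum(),
        "ranges": [rng for (_, rng) in bundle.blocks],
        "kinds": sorted({kind for (kind, _) in bundle.blocks}),
        "n_markers": {k: int(len(v)) for k, v in bundle.markers.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
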