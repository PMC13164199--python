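"""Composite flavor / deterioration indices from GC-IMS peak tables.

The GC-IMS side of the workflow: peak volumes are normalized to the
2-octanol-D internal standard (cancelling per-injection intensity factors),
monomer/dimer ion pairs are collapsed to the more stable form, replicates
are averaged to sample level, and a PLS1 model of the VIP-selected marker
volumes against the response (storage months, or the raw/processed
processing stage) yields a single latent-variable score per sample — the
composite index later used as the NIRS calibration response.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .containers import PeakTable
from .pls import PLSModel, fit_pls1


def normalize_to_internal_standard(table: PeakTable) -> PeakTable:
    """Divide every volume by the same-replicate internal-standard volume.

    Removes the internal-standard row from the analyte set. Raises (naming
    the replicate) if the standard is missing or non-positive anywhere.
    """
    data = table.data
    is_rows = data[data["compound"] == table.internal_standard]
    is_map = {}
    for _, row in is_rows.iterrows():
        key = (row["sample"], row["replicate"])
        if row["volume"] <= 0:
            raise ValueError(
                f"internal standard non-positive in sample {key[0]!r} replicate {key[1]}"
            )
        is_map[key] = row["volume"]

    analytes = data[data["compound"] != table.internal_standard].copy()
    keys = list(zip(analytes["sample"], analytes["replicate"]))
    missing = sorted({k for k in keys if k not in is_map})
    if missing:
        raise ValueError(
            f"internal standard missing for sample/replicate pairs: {missing[:5]}"
        )
    analytes["volume"] = analytes["volume"].to_numpy() / np.array(
        [is_map[k] for k in keys]
    )
    return replace(table, data=analytes.reset_index(drop=True))


def _replicate_cv(sub: pd.DataFrame) -> float:
    """Mean across samples of the within-sample replicate CV."""
    grouped = sub.groupby("sample")["volume"]
    mean = grouped.mean()
    sd = grouped.std(ddof=1).fillna(0.0)
    return float((sd / mean).mean())


def deduplicate_forms(table: PeakTable):
    """Collapse monomer/dimer pairs to one form per CAS number.

    For each CAS carrying both an M and a D signal the form with the higher
    stability ratio (mean volume / mean replicate CV) is retained — the more
    intense *and* more reproducible ion. Ties go to the monomer. A per-pair
    consistency check (Spearman correlation of the M and D sample-mean
    profiles) is recorded in the returned log.

    Returns (deduplicated PeakTable, log DataFrame).
    """
    data = table.data
    keep_masks = []
    log_rows = []
    for cas, sub in data.groupby("cas"):
        forms = set(sub["form"])
        if forms != {"M", "D"}:
            keep_masks.append(sub.index)
            continue
        m_sub = sub[sub["form"] == "M"]
        d_sub = sub[sub["form"] == "D"]
        stats = {}
        for tag, s in (("M", m_sub), ("D", d_sub)):
            mean = float(s["volume"].mean())
            cv = _replicate_cv(s)
            stats[tag] = mean / cv if cv > 0 else np.inf
        kept = "M" if stats["M"] >= stats["D"] else "D"
        m_profile = m_sub.groupby("sample")["volume"].mean()
        d_profile = d_sub.groupby("sample")["volume"].mean().reindex(m_profile.index)
        if m_profile.nunique() <= 1 or d_profile.nunique() <= 1:
            rho = float("nan")  # flat profile: rank correlation undefined
        else:
            rho = float(spearmanr(m_profile, d_profile).statistic)
        log_rows.append(
            {
                "cas": cas,
                "compound": m_sub["compound"].iloc[0],
                "kept_form": kept,
                "discarded_form": "D" if kept == "M" else "M",
                "md_spearman": rho,
            }
        )
        keep_masks.append(sub[sub["form"] == kept].index)
    kept_idx = np.concatenate([np.asarray(ix) for ix in keep_masks])
    dedup = replace(table, data=data.loc[np.sort(kept_idx)].reset_index(drop=True))
    log = pd.DataFrame(
        log_rows, columns=["cas", "compound", "kept_form", "discarded_form", "md_spearman"]
    )
    return dedup, log


@dataclass
class CompositeIndex:
    """Per-sample composite score plus the fitted projection model.

    kind is "flavor" (raw/processed contrast, all samples) or
    "deterioration" (storage months, processed samples only). orientation
    is +-1, chosen so the index increases with the response on the training
    samples; values are first-latent-variable scores in that orientation.
    """

    values: pd.Series
    kind: str
    markers: list
    orientation: float
    model: PLSModel
    response: pd.Series

    def project(self, sample_matrix: pd.DataFrame) -> pd.Series:
        """Score new samples with the stored centering/scaling/weights."""
        missing = [m for m in self.markers if m not in sample_matrix.columns]
        if missing:
            raise KeyError(f"marker columns missing from new data: {missing[:5]}")
        X = sample_matrix[self.markers].to_numpy(dtype=float)
        scores = self.model.transform(X)[:, 0] * self.orientation
        return pd.Series(scores, index=sample_matrix.index, name=f"{self.kind}_index")


def build_index(
    table: PeakTable,
    samples,
    response: pd.Series,
    markers,
    kind: str = "deterioration",
    n_lv: int = 1,
) -> CompositeIndex:
    """Fit the composite index on replicate-averaged marker volumes.

    The marker matrix (samples x markers) is column-centered and autoscaled
    inside the PLS fit; the index is the first-latent-variable score,
    sign-oriented to correlate positively with the response.
    """
    samples = list(samples)
    markers = list(markers)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to build an index")
    if not markers:
        raise ValueError("marker set is empty")
    response = pd.Series(response).loc[samples].astype(float)
    if response.nunique() < 2:
        raise ValueError("response is constant; index undefined")

    matrix = table.sample_means().loc[samples]
    missing = [m for m in markers if m not in matrix.columns]
    if missing:
        raise KeyError(f"markers not present in the peak table: {missing[:5]}")
    X = matrix[markers].to_numpy(dtype=float)
    model = fit_pls1(X, response.to_numpy(), n_lv=n_lv, scale_x=True)

    scores = model.T[:, 0]
    corr = np.corrcoef(scores, response.to_numpy())[0, 1]
    orientation = -1.0 if corr < 0 else 1.0
    values = pd.Series(scores * orientation, index=samples, name=f"{kind}_index")
    return CompositeIndex(values, kind, markers, orientation, model, response)


def project_index(index: CompositeIndex, table: PeakTable, samples=None) -> pd.Series:
    """Project (new) samples of a peak table onto a fitted index."""
    matrix = table.sample_means()
    if samples is not None:
        matrix = matrix.loc[list(samples)]
    return index.project(matrix)
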