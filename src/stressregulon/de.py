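"""Replicate-free differential-expression calling with the D1 statistic.

With a single pooled array per condition there is no within-condition
variance to estimate, so genes are ranked by a J5-family global-difference
statistic: each gene's between-condition difference is normalized by the
genome-wide mean absolute difference of the same contrast,

    d1_g = d_g / ((1/N) * sum_j |d_j|),   d_g = x_treated,g - x_untreated,g,

where x is the signal intensity on the chosen scale (linear by default,
log2 optionally) and N is the number of background genes.  A gene is called
up when d1 >= threshold and down when d1 <= -threshold (boundary inclusive);
the conventional threshold is 3.

Note the structural asymmetry of the linear scale: a downregulated gene's
difference is bounded below by -SI_untreated, so very strong downregulation
saturates while upregulation does not.  The log2 scale treats both
directions symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContrastError, DegenerateContrastError
from .simulate import UNTREATED

DEFAULT_THRESHOLD = 3.0

#: Heuristic bound: normalized linear intensities virtually never stay below
#: this, while log-scale data do; used only to emit a warning, never to switch.
_LOG_SCALE_SUSPICION_MAX = 25.0


@dataclass(frozen=True)
class Contrast:
    """A treated-vs-untreated comparison within one strain."""

    strain: str
    stress: str
    treated_sample: str
    untreated_sample: str

    def __post_init__(self):
        if self.treated_sample == self.untreated_sample:
            raise ContrastError(
                f"treated and untreated samples are identical: {self.treated_sample!r}")


def contrasts_from_design(design: pd.DataFrame, untreated: str = UNTREATED) -> list[Contrast]:
    """Build one contrast per (strain, stress) pair present in a design table."""
    out = []
    for strain, group in design.groupby("strain", sort=False):
        base = group.loc[group["condition"] == untreated, "sample_id"]
        if len(base) != 1:
            raise ContrastError(
                f"strain {strain!r} needs exactly one {untreated!r} sample, found {len(base)}")
        base_id = base.iloc[0]
        for _, row in group.iterrows():
            if row["condition"] == untreated:
                continue
            out.append(Contrast(strain, row["condition"], row["sample_id"], base_id))
    return out


def _sample_column(matrix: pd.DataFrame, sample: str) -> np.ndarray:
    if sample not in matrix.columns:
        raise ContrastError(f"sample {sample!r} not present in expression matrix")
    return matrix[sample].to_numpy(dtype=float)


def compute_log2r(matrix: pd.DataFrame, contrast: Contrast) -> pd.Series:
    """log2 of the treated/untreated signal-intensity ratio, per gene."""
    treated = _sample_column(matrix, contrast.treated_sample)
    untreated = _sample_column(matrix, contrast.untreated_sample)
    return pd.Series(np.log2(treated / untreated), index=matrix.index, name="log2R")


def compute_d1(matrix: pd.DataFrame, contrast: Contrast, scale: str = "linear") -> pd.Series:
    """Per-gene D1 for one contrast over the background gene set of *matrix*.

    ``scale="linear"`` uses raw signal intensities (the J5 convention);
    ``scale="log2"`` uses log2 intensities, making the statistic symmetric
    in direction and, at zero noise, independent of a gene's baseline.
    """
    if scale not in ("linear", "log2"):
        raise ValueError(f"scale must be 'linear' or 'log2', got {scale!r}")
    if len(matrix) < 2:
        raise ContrastError("D1 needs at least 2 background genes")
    treated = _sample_column(matrix, contrast.treated_sample)
    untreated = _sample_column(matrix, contrast.untreated_sample)
    if scale == "log2":
        treated, untreated = np.log2(treated), np.log2(untreated)
    diff = treated - untreated
    mean_abs = np.mean(np.abs(diff))
    if mean_abs == 0:
        raise DegenerateContrastError(
            f"all per-gene differences are zero for contrast "
            f"{contrast.strain}/{contrast.stress}")
    return pd.Series(diff / mean_abs, index=matrix.index, name="d1")


def call_regulation(d1: pd.Series, threshold: float = DEFAULT_THRESHOLD) -> pd.Series:
    """Classify each gene as up/down/none at an inclusive |d1| threshold."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    values = d1.to_numpy(dtype=float)
    call = np.where(values >= threshold, "up", np.where(values <= -threshold, "down", "none"))
    return pd.Series(call, index=d1.index, name="call")


def de_table(matrix: pd.DataFrame, design: pd.DataFrame, *, scale: str = "linear",
             threshold: float = DEFAULT_THRESHOLD, untreated: str = UNTREATED) -> pd.DataFrame:
    """Run every contrast of a design: long table (gene, strain, stress, log2R, d1, call).

    The matrix is expected to be post-revision-filter; its gene set is the
    D1 denominator population for every contrast.
    """
    if scale == "linear" and float(matrix.to_numpy().max()) < _LOG_SCALE_SUSPICION_MAX:
        import logging
        logging.getLogger(__name__).warning(
            "all intensities < %.0f — input may already be log-scale; "
            "D1 still computed on scale='linear' as requested",
            _LOG_SCALE_SUSPICION_MAX)
    frames = []
    for contrast in contrasts_from_design(design, untreated=untreated):
        d1 = compute_d1(matrix, contrast, scale=scale)
        frame = pd.DataFrame({
            "gene_id": matrix.index,
            "strain": contrast.strain,
            "stress": contrast.stress,
            "log2R": compute_log2r(matrix, contrast).to_numpy(),
            "d1": d1.to_numpy(),
            "call": call_regulation(d1, threshold).to_numpy(),
        })
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
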