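"""Age-correlation site selection and probe-type-aware quantile normalization.

Normalization maps every sample's beta distribution, separately per probe
design type, onto a reference built from the per-rank medians of the training
samples.  Site selection retains probes whose |Pearson correlation| with age
exceeds a strict threshold.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Sequence

import numpy as np

from .datasets import InputError, MethylationDataset, PROBE_TYPES


@dataclasses.dataclass
class NormalizationReference:
    """Per-probe-type sorted reference distributions (non-decreasing)."""

    references: Dict[str, np.ndarray]   # probe type -> sorted reference vector
    site_order: Dict[str, list]         # probe type -> probe ids in that type

    def __post_init__(self) -> None:
        for t, ref in self.references.items():
            ref = np.asarray(ref, dtype=float)
            if (np.diff(ref) < 0).any():
                raise InputError(f"reference for type {t} is not sorted")
            self.references[t] = ref


@dataclasses.dataclass
class SiteSelection:
    probe_ids: list
    pcc: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.pcc = np.asarray(self.pcc, dtype=float)
        if (np.abs(self.pcc) <= self.threshold).any():
            raise InputError("retained site violates |pcc| > threshold")


def site_age_correlation(dataset: MethylationDataset) -> np.ndarray:
    """Per-site Pearson correlation between beta values and sample age.

    Zero-variance rows yield NaN (an undefined marker), never a number.
    Requires >= 3 samples and non-constant ages.
    """
    if dataset.n_samples < 3:
        raise InputError("need at least 3 samples for a correlation")
    ages = dataset.ages
    if np.ptp(ages) == 0:
        raise InputError("ages are all identical")
    x = ages - ages.mean()
    betas = dataset.betas
    bc = betas - betas.mean(axis=1, keepdims=True)
    num = bc @ x
    row_ss = (bc ** 2).sum(axis=1)
    denom = np.sqrt(row_ss * (x @ x))
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = np.where(row_ss > 0, num / denom, np.nan)
    return pcc


def select_sites(probe_ids: Sequence[str], pcc: np.ndarray, threshold: float) -> SiteSelection:
    """Retain sites with |PCC| strictly greater than ``threshold``.

    Sites with undefined (NaN) correlation are always excluded.
    """
    if not 0.0 <= threshold < 1.0:
        raise InputError("threshold must lie in [0, 1)")
    pcc = np.asarray(pcc, dtype=float)
    with np.errstate(invalid="ignore"):
        keep = np.abs(pcc) > threshold
    keep &= ~np.isnan(pcc)
    return SiteSelection(
        probe_ids=[p for p, k in zip(probe_ids, keep) if k],
        pcc=pcc[keep],
        threshold=threshold,
    )


def build_reference(train: MethylationDataset) -> NormalizationReference:
    """Per-rank median of the sorted training columns, one vector per probe type."""
    if train.n_samples == 0 or train.n_sites == 0:
        raise InputError("training dataset is empty")
    references: Dict[str, np.ndarray] = {}
    site_order: Dict[str, list] = {}
    for t in PROBE_TYPES:
        mask = train.probe_types == t
        if not mask.any():
            continue
        block = np.sort(train.betas[mask, :], axis=0)
        references[t] = np.median(block, axis=1)
        site_order[t] = [p for p, m in zip(train.probe_ids, mask) if m]
    if not references:
        raise InputError("no recognized probe types in training data")
    return NormalizationReference(references=references, site_order=site_order)


def _normalize_column(values: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Map one sample's values within one probe type onto the reference.

    Sorted position k of m values maps to the reference quantile k/(m-1)
    (linear interpolation between reference ranks when lengths differ); tied
    input values receive the mean of the reference values at their occupied
    ranks, making the map deterministic and rank-preserving.
    """
    m = len(values)
    L = len(ref)
    order = np.argsort(values, kind="stable")
    if m == 1:
        pos = np.array([0.5 * (L - 1)])
    else:
        pos = np.arange(m) * (L - 1) / (m - 1)
    target = np.interp(pos, np.arange(L), ref)

    sorted_vals = values[order]
    out_sorted = target.copy()
    start = 0
    for i in range(1, m + 1):
        if i == m or sorted_vals[i] != sorted_vals[start]:
            if i - start > 1:
                out_sorted[start:i] = target[start:i].mean()
            start = i
    out = np.empty(m)
    out[order] = out_sorted
    return out


def quantile_normalize(dataset: MethylationDataset,
                       reference: NormalizationReference) -> MethylationDataset:
    """Quantile-normalize every sample against the training reference, per probe type."""
    types_present = set(dataset.probe_types)
    missing = types_present - set(reference.references)
    if missing:
        raise InputError(f"reference lacks probe types: {sorted(missing)}")
    out = dataset.betas.copy()
    for t in sorted(types_present):
        mask = dataset.probe_types == t
        ref = reference.references[t]
        block = out[mask, :]
        for j in range(block.shape[1]):
            block[:, j] = _normalize_column(block[:, j], ref)
        out[mask, :] = block
    return dataset.with_betas(np.clip(out, 0.0, 1.0))
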