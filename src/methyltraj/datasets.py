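"""Core data container for methylation cohorts plus plain-text (TSV) round-trip I/O.

A cohort is a beta-value matrix (CpG sites x samples, values in [0, 1]) with
per-sample chronological ages and a per-probe design-type annotation
("I" / "II").  All on-disk formats are tab-separated text; floats are written
with 10 significant digits so files round-trip losslessly at that precision.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PROBE_TYPES = ("I", "II")
# 17 significant digits: exact float64 round trip (and >= the documented
# 10-significant-digit precision of the exchange format)
FLOAT_FMT = "%.17g"


class InputError(ValueError):
    """Raised when input data violates a documented precondition."""


@dataclasses.dataclass
class MethylationDataset:
    """Beta matrix with sample ages and probe annotations.

    Attributes
    ----------
    betas : ndarray, shape (n_sites, n_samples)
        Methylation beta values in [0, 1]; no missing values allowed.
    sample_ids : list of str
    ages : ndarray, shape (n_samples,)
        Chronological ages in years, >= 0.
    probe_ids : list of str
    probe_types : ndarray of str, shape (n_sites,)
        Design type per probe, each "I" or "II".
    """

    betas: np.ndarray
    sample_ids: list
    ages: np.ndarray
    probe_ids: list
    probe_types: np.ndarray

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.probe_types = np.asarray(self.probe_types, dtype=object)
        if self.betas.ndim != 2:
            raise InputError("betas must be a 2-D (sites x samples) matrix")
        n_sites, n_samples = self.betas.shape
        if len(self.probe_ids) != n_sites or len(self.probe_types) != n_sites:
            raise InputError("probe annotation length does not match beta rows")
        if len(self.sample_ids) != n_samples or len(self.ages) != n_samples:
            raise InputError("sample annotation length does not match beta columns")
        if np.isnan(self.betas).any():
            raise InputError("betas contain missing values")
        if self.betas.min(initial=0.0) < 0.0 or self.betas.max(initial=1.0) > 1.0:
            raise InputError("betas must lie in [0, 1]")
        if (self.ages < 0).any():
            raise InputError("ages must be >= 0")
        bad = set(self.probe_types) - set(PROBE_TYPES)
        if bad:
            raise InputError(f"unknown probe design types: {sorted(bad)}")

    @property
    def n_sites(self) -> int:
        return self.betas.shape[0]

    @property
    def n_samples(self) -> int:
        return self.betas.shape[1]

    def select_samples(self, indices: Sequence[int]) -> "MethylationDataset":
        idx = np.asarray(indices, dtype=int)
        return MethylationDataset(
            betas=self.betas[:, idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            ages=self.ages[idx].copy(),
            probe_ids=list(self.probe_ids),
            probe_types=self.probe_types.copy(),
        )

    def select_probes(self, probe_ids: Iterable[str]) -> "MethylationDataset":
        """Subset to the given probes, preserving the requested order.

        Raises
        ------
        InputError
            Naming the probes that are absent from this dataset.
        """
        wanted = list(probe_ids)
        pos = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in wanted if p not in pos]
        if missing:
            shown = ", ".join(missing[:10])
            raise InputError(f"{len(missing)} probes missing from dataset: {shown}")
        idx = np.array([pos[p] for p in wanted], dtype=int)
        return MethylationDataset(
            betas=self.betas[idx, :].copy(),
            sample_ids=list(self.sample_ids),
            ages=self.ages.copy(),
            probe_ids=wanted,
            probe_types=self.probe_types[idx].copy(),
        )

    def with_betas(self, betas: np.ndarray) -> "MethylationDataset":
        """Return a copy holding a replacement beta matrix of the same shape."""
        return MethylationDataset(
            betas=np.asarray(betas, dtype=float),
            sample_ids=list(self.sample_ids),
            ages=self.ages.copy(),
            probe_ids=list(self.probe_ids),
            probe_types=self.probe_types.copy(),
        )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def _write_table(df: pd.DataFrame, path: Path, header_lines: Sequence[str] = ()) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def _read_table(path: Path) -> pd.DataFrame:
    # round_trip parser: floats written by _write_table reload bit-identically
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


def write_betas_tsv(dataset: MethylationDataset, path, header_lines: Sequence[str] = ()) -> None:
    df = pd.DataFrame(dataset.betas, columns=dataset.sample_ids)
    df.insert(0, "probe_id", dataset.probe_ids)
    _write_table(df, Path(path), header_lines)


def write_metadata_tsv(dataset: MethylationDataset, path, split_labels=None,
                       header_lines: Sequence[str] = ()) -> None:
    df = pd.DataFrame({"sample_id": dataset.sample_ids, "age": dataset.ages})
    if split_labels is not None:
        df["split"] = list(split_labels)
    _write_table(df, Path(path), header_lines)


def write_probes_tsv(dataset: MethylationDataset, path, header_lines: Sequence[str] = ()) -> None:
    df = pd.DataFrame({"probe_id": dataset.probe_ids,
                       "design_type": list(dataset.probe_types)})
    _write_table(df, Path(path), header_lines)


def read_dataset(betas_path, metadata_path, probes_path) -> MethylationDataset:
    """Assemble a dataset from the three TSV files written by this module."""
    betas = _read_table(Path(betas_path))
    meta = _read_table(Path(metadata_path))
    probes = _read_table(Path(probes_path))
    probe_ids = betas["probe_id"].astype(str).tolist()
    sample_ids = [c for c in betas.columns if c != "probe_id"]
    meta = meta.set_index(meta["sample_id"].astype(str))
    missing = [s for s in sample_ids if s not in meta.index]
    if missing:
        raise InputError(f"samples missing from metadata: {missing[:10]}")
    ages = meta.loc[sample_ids, "age"].to_numpy(dtype=float)
    type_map = dict(zip(probes["probe_id"].astype(str), probes["design_type"].astype(str)))
    try:
        probe_types = np.array([type_map[p] for p in probe_ids], dtype=object)
    except KeyError as exc:
        raise InputError(f"probe missing from annotation: {exc}") from exc
    return MethylationDataset(
        betas=betas[sample_ids].to_numpy(dtype=float),
        sample_ids=sample_ids,
        ages=ages,
        probe_ids=probe_ids,
        probe_types=probe_types,
    )


def write_series_tsv(ids: Sequence[str], values: np.ndarray, path,
                     value_name: str, header_lines: Sequence[str] = (),
                     id_name: str = "sample_id") -> None:
    df = pd.DataFrame({id_name: list(ids), value_name: np.asarray(values, dtype=float)})
    _write_table(df, Path(path), header_lines)


def read_series_tsv(path, value_name: str, id_name: str = "sample_id"):
    df = _read_table(Path(path))
    return df[id_name].astype(str).tolist(), df[value_name].to_numpy(dtype=float)
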