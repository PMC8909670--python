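"""Plain-text (TSV / JSON) persistence for fitted models.

Every writer accepts ``header_lines`` so pipeline outputs can carry their
config hash and seed; readers skip ``#`` comment lines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import FLOAT_FMT, _read_table, _write_table
from .pacemaker import EPMModel
from .preprocess import NormalizationReference, SiteSelection
from .reduce_cluster import EmbeddingModel, GMMModel
from .trajectory import ClusterGraph, PrincipalCurve, TrajectoryModel


def _write_json(obj, path: Path, header: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({"_meta": header, **obj}, fh, indent=1, sort_keys=True)


def _read_json(path: Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# -- embedding ---------------------------------------------------------------

def save_embedding(model: EmbeddingModel, probe_ids: Sequence[str], path,
                   header_lines=()) -> None:
    df = pd.DataFrame({"probe_id": list(probe_ids), "mean": model.training_mean})
    for c in range(model.n_components):
        df[f"pc{c + 1}"] = model.basis[:, c]
    ev = ",".join(FLOAT_FMT % v for v in model.explained_variance)
    _write_table(df, Path(path), [*header_lines, f"explained_variance\t{ev}"])


def load_embedding(path):
    ev = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# explained_variance"):
                ev = np.array([float(v) for v in line.split("\t")[1].split(",")])
            if not line.startswith("#"):
                break
    df = _read_table(Path(path))
    pcs = [c for c in df.columns if c.startswith("pc")]
    model = EmbeddingModel(training_mean=df["mean"].to_numpy(),
                           basis=df[pcs].to_numpy(),
                           explained_variance=ev,
                           n_components=len(pcs))
    return model, df["probe_id"].astype(str).tolist()


# -- GMM ---------------------------------------------------------------------

def save_gmm(model: GMMModel, path, header: dict) -> None:
    _write_json({
        "k": model.k,
        "family": model.family,
        "weights": model.weights.tolist(),
        "means": model.means.tolist(),
        "covariances": model.covariances.tolist(),
        "log_likelihood": model.log_likelihood,
        "n_params": model.n_params,
        "converged": model.converged,
    }, Path(path), header)


def load_gmm(path) -> GMMModel:
    d = _read_json(Path(path))
    return GMMModel(k=int(d["k"]), family=d["family"],
                    weights=np.array(d["weights"]),
                    means=np.array(d["means"]),
                    covariances=np.array(d["covariances"]),
                    log_likelihood=float(d["log_likelihood"]),
                    n_params=int(d["n_params"]),
                    converged=bool(d["converged"]))


# -- graph & curve -----------------------------------------------------------

def save_graph(graph: ClusterGraph, path, header: dict) -> None:
    _write_json({
        "centers": graph.centers.tolist(),
        "edges": [list(e) for e in graph.edges],
        "start_cluster": graph.start_cluster,
    }, Path(path), header)


def load_graph(path) -> ClusterGraph:
    d = _read_json(Path(path))
    return ClusterGraph(centers=np.array(d["centers"]),
                        edges=[tuple(e) for e in d["edges"]],
                        start_cluster=int(d["start_cluster"]))


def save_curve(curve: PrincipalCurve, path, header_lines=()) -> None:
    df = pd.DataFrame(curve.control_points,
                      columns=[f"x{d + 1}" for d in range(curve.control_points.shape[1])])
    df["cumulative_arc_length"] = curve.cumulative_arc_length
    _write_table(df, Path(path), header_lines)


def load_curve(path) -> PrincipalCurve:
    df = _read_table(Path(path))
    dims = [c for c in df.columns if c.startswith("x")]
    cum = df["cumulative_arc_length"].to_numpy()
    return PrincipalCurve(control_points=df[dims].to_numpy(),
                          cumulative_arc_length=cum,
                          total_length=float(cum[-1]))


def save_trajectory(model: TrajectoryModel, outdir, header: dict) -> None:
    outdir = Path(outdir)
    lines = [f"{k}\t{v}" for k, v in header.items()]
    save_embedding(model.embedding, model.probe_ids, outdir / "embedding.tsv", lines)
    save_gmm(model.gmm, outdir / "gmm.json", header)
    save_graph(model.graph, outdir / "graph.json", header)
    save_curve(model.curve, outdir / "curve.tsv", lines)


def load_trajectory(outdir) -> TrajectoryModel:
    outdir = Path(outdir)
    embedding, probe_ids = load_embedding(outdir / "embedding.tsv")
    return TrajectoryModel(embedding=embedding,
                           gmm=load_gmm(outdir / "gmm.json"),
                           graph=load_graph(outdir / "graph.json"),
                           curve=load_curve(outdir / "curve.tsv"),
                           probe_ids=probe_ids)


# -- preprocessing artefacts -------------------------------------------------

def save_reference(ref: NormalizationReference, path, header_lines=()) -> None:
    rows = []
    for t, values in sorted(ref.references.items()):
        for rank, v in enumerate(values):
            rows.append((t, rank, v))
    _write_table(pd.DataFrame(rows, columns=["design_type", "rank", "value"]),
                 Path(path), header_lines)


def load_reference(path) -> NormalizationReference:
    df = _read_table(Path(path))
    refs = {t: g.sort_values("rank")["value"].to_numpy()
            for t, g in df.groupby("design_type")}
    return NormalizationReference(references=refs,
                                  site_order={t: [] for t in refs})


def save_selection(sel: SiteSelection, path, header_lines=()) -> None:
    df = pd.DataFrame({"probe_id": sel.probe_ids, "pcc": sel.pcc})
    _write_table(df, Path(path),
                 [*header_lines, f"threshold\t{FLOAT_FMT % sel.threshold}"])


def load_selection(path) -> SiteSelection:
    threshold = 0.0
    with open(path) as fh:
        for line in fh:
            if line.startswith("# threshold"):
                threshold = float(line.split("\t")[1])
            if not line.startswith("#"):
                break
    df = _read_table(Path(path))
    return SiteSelection(probe_ids=df["probe_id"].astype(str).tolist(),
                         pcc=df["pcc"].to_numpy(), threshold=threshold)


# -- pacemaker ---------------------------------------------------------------

def save_epm(model: EPMModel, path, header_lines=()) -> None:
    df = pd.DataFrame({"probe_id": model.site_ids,
                       "intercept": model.intercepts,
                       "rate": model.rates})
    _write_table(df, Path(path), header_lines)


def load_epm(path) -> EPMModel:
    df = _read_table(Path(path))
    return EPMModel(site_ids=df["probe_id"].astype(str).tolist(),
                    intercepts=df["intercept"].to_numpy(),
                    rates=df["rate"].to_numpy(),
                    states=np.array([]), rss=0.0, n_iterations=0,
                    converged=True)
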