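"""Readers and writers for the package's plain-text artifacts.

Count matrices travel as TSV (first column feature ID, header row of sample
IDs, integer cells) with a separate two-column sample-to-treatment map;
fitted parameters and simulation truth as JSON; assignments, posteriors and
traces as TSV.  Everything written here reads back to an equal in-memory
object.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .em import ClusteringResult
from .hurdle import CountMatrix, HurdleParams


def read_counts(path, treatments_path) -> CountMatrix:
    """Read and validate a count TSV plus its treatment map.

    Samples are reordered grouping treatments in the map's order of first
    appearance (within a treatment, counts-file order is kept).  Raises a
    descriptive error on non-integer or negative cells, duplicate feature
    IDs or samples missing from the map.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate feature id {dup!r} in {path}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise ValueError(
                f"non-numeric count at feature {row!r}, sample {col!r}"
            )
        if (vals < 0).any():
            row = df.index[vals < 0][0]
            raise ValueError(
                f"negative count at feature {row!r}, sample {col!r}"
            )
        if (vals != np.round(vals)).any():
            row = df.index[vals != np.round(vals)][0]
            raise ValueError(
                f"non-integer count at feature {row!r}, sample {col!r}"
            )
    tmap = pd.read_csv(treatments_path, sep="\t")
    if tmap.shape[1] < 2:
        raise ValueError("treatment map needs two columns: sample, treatment")
    sample_col, treat_col = tmap.columns[:2]
    mapping = dict(zip(tmap[sample_col].astype(str), tmap[treat_col].astype(str)))
    missing = [c for c in df.columns if str(c) not in mapping]
    if missing:
        raise ValueError(f"samples missing from treatment map: {missing}")
    treat_order = list(dict.fromkeys(tmap[treat_col].astype(str)))
    ordered = [c for t in treat_order for c in df.columns if mapping[str(c)] == t]
    df = df[ordered]
    return CountMatrix(
        counts=df.to_numpy(dtype=np.int64),
        treatment_of_sample=np.array([mapping[str(c)] for c in df.columns]),
        feature_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
    )


def write_counts(cm: CountMatrix, path, treatments_path) -> None:
    df = pd.DataFrame(cm.counts, index=pd.Index(cm.feature_ids, name="feature"),
                      columns=cm.sample_ids)
    df.to_csv(path, sep="\t")
    pd.DataFrame({"sample": cm.sample_ids,
                  "treatment": cm.treatment_of_sample}).to_csv(
        treatments_path, sep="\t", index=False)


def write_params(params: HurdleParams, path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=1))


def read_params(path) -> HurdleParams:
    return HurdleParams.from_dict(json.loads(Path(path).read_text()))


def write_assignments(result: ClusteringResult, cm: CountMatrix, path) -> None:
    pd.DataFrame({"feature": cm.feature_ids,
                  "cluster": result.assignments + 1}).to_csv(
        path, sep="\t", index=False)


def read_assignments(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["cluster"].to_numpy() - 1


def write_posterior(result: ClusteringResult, cm: CountMatrix, path) -> None:
    K = result.posterior.shape[1]
    pd.DataFrame(result.posterior,
                 index=pd.Index(cm.feature_ids, name="feature"),
                 columns=[f"cluster{k + 1}" for k in range(K)]).to_csv(
        path, sep="\t")


def write_trace(result: ClusteringResult, path) -> None:
    rows = pd.DataFrame({"iteration": np.arange(len(result.loglik_trace)),
                         "loglik": result.loglik_trace})
    rows.to_csv(path, sep="\t", index=False)


def write_truth(labels, path, extra: dict | None = None) -> None:
    payload = {"labels": np.asarray(labels).astype(int).tolist()}
    if extra:
        payload.update({k: np.asarray(v).tolist() for k, v in extra.items()})
    Path(path).write_text(json.dumps(payload))


def read_truth(path) -> np.ndarray:
    return np.asarray(json.loads(Path(path).read_text())["labels"], dtype=int)
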