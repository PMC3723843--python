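"""Readers and writers for the package's plain-text formats.

Matrices travel as TSV with target IDs in the first row and column and
"NA" for unobserved entries; traces as CSV with one row per tested
pair.  Every writer embeds a comment header carrying the seed and a
config hash so any artifact can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .completion import SimilarityMatrix
from .matrix import InteractionMatrix
from .metrics import ScreenTrace, TraceRecord, discovery_curve

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_similarity",
    "read_group_labels",
    "write_trace",
    "read_trace",
    "write_manifest",
]

TRACE_COLUMNS = ["step", "mode", "target_i", "target_j", "score", "synergy", "f", "F"]


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                     na_values=["NA"], keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate target ids")
    if set(df.index) != set(df.columns):
        raise ValueError(f"{path}: row and column id sets differ")
    return df.loc[:, df.index]  # align column order to row order


def read_matrix(path) -> InteractionMatrix:
    """Read a score matrix TSV; "NA" cells become unobserved entries.

    Values asymmetric beyond 1e-9 raise; asymmetry within tolerance is
    averaged away.  Diagonal entries are ignored (self-pairs are not
    screened).
    """
    df = _read_tsv(path)
    values = df.to_numpy(dtype=float)
    mask = np.isfinite(values)
    np.fill_diagonal(mask, False)
    if not np.array_equal(mask, mask.T):
        raise ValueError(f"{path}: observation pattern is not symmetric")
    both = mask & mask.T
    if np.any(np.abs(np.where(both, values, 0) - np.where(both, values, 0).T) > 1e-9):
        raise ValueError(f"{path}: matrix asymmetric beyond tolerance 1e-9")
    sym = np.where(both, 0.5 * (np.nan_to_num(values) + np.nan_to_num(values).T), 0.0)
    return InteractionMatrix(sym, mask, list(df.index))


def write_matrix(path, M: InteractionMatrix, header: dict | None = None) -> None:
    """Write a score matrix TSV with NA for unobserved entries."""
    values = np.where(M.mask, M.values, np.nan)
    df = pd.DataFrame(values, index=M.target_ids, columns=M.target_ids)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {json.dumps(header, sort_keys=True)}\n")
        df.to_csv(fh, sep="\t", na_rep="NA")


def read_similarity(path) -> SimilarityMatrix:
    """Read a similarity kernel from a matrix TSV (no NA allowed)."""
    df = _read_tsv(path)
    Q = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(Q)):
        raise ValueError(f"{path}: similarity matrix has missing entries")
    return SimilarityMatrix(Q)


def write_similarity(path, Q: SimilarityMatrix, target_ids, header: dict | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {json.dumps(header, sort_keys=True)}\n")
        pd.DataFrame(Q.Q, index=target_ids, columns=target_ids).to_csv(fh, sep="\t")


def read_group_labels(path) -> tuple[list[str], np.ndarray]:
    """Two-column TSV (target_id, group) -> (ids, labels)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (target_id, group)")
    ids = df.iloc[:, 0].tolist()
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate target ids")
    return ids, df.iloc[:, 1].to_numpy()


def write_trace(path, trace: ScreenTrace, header: dict | None = None) -> None:
    """Write a trace CSV with cumulative (f, F) columns."""
    rows = []
    if len(trace) > 0:
        curve = discovery_curve(trace) if trace.total_synergies > 0 else None
        for idx, r in enumerate(trace.records):
            ti = trace.target_ids[r.i] if trace.target_ids else str(r.i)
            tj = trace.target_ids[r.j] if trace.target_ids else str(r.j)
            f, F = (curve[idx] if curve is not None else (np.nan, np.nan))
            rows.append([r.step, r.mode, ti, tj, r.score, int(r.synergy), f, F])
    df = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    with open(path, "w") as fh:
        hdr = dict(header or {})
        hdr.update(
            total_pairs=trace.total_pairs,
            total_synergies=trace.total_synergies,
            ground_truth_known=trace.ground_truth_known,
            target_ids=trace.target_ids,
        )
        fh.write(f"# {json.dumps(hdr, sort_keys=True)}\n")
        df.to_csv(fh, index=False)


def read_trace(path) -> ScreenTrace:
    """Read a trace CSV; duplicate pairs or unknown modes raise."""
    with open(path) as fh:
        first = fh.readline()
        meta = json.loads(first.lstrip("# ").strip()) if first.startswith("#") else {}
        df = pd.read_csv(fh)
    ids = meta.get("target_ids") or sorted(
        set(df["target_i"].astype(str)) | set(df["target_j"].astype(str))
    )
    index = {t: k for k, t in enumerate(ids)}
    trace = ScreenTrace(
        total_pairs=int(meta.get("total_pairs", len(ids) * (len(ids) - 1) // 2)),
        total_synergies=int(meta.get("total_synergies", int(df["synergy"].sum()))),
        ground_truth_known=bool(meta.get("ground_truth_known", False)),
        target_ids=list(ids),
    )
    for _, row in df.iterrows():
        i, j = index[str(row["target_i"])], index[str(row["target_j"])]
        i, j = min(i, j), max(i, j)
        trace.append(
            TraceRecord(int(row["step"]), str(row["mode"]), i, j,
                        float(row["score"]), bool(row["synergy"]))
        )
    return trace


def write_propensity_state(path, state, target_ids) -> None:
    """Serialize per-target counts and posterior propensities as TSV."""
    pd.DataFrame(
        {"target_id": target_ids, "s": state.s, "n": state.n, "pi": state.pi}
    ).to_csv(path, sep="\t", index=False)


def read_propensity_state(path, a: float, b: float):
    """Load counts from TSV; (a, b) come from the run config, and the
    posterior propensities are recomputed rather than trusted."""
    from .propensity import PropensityState

    df = pd.read_csv(path, sep="\t", comment="#")
    state = PropensityState(df["s"].to_numpy(), df["n"].to_numpy(), a, b)
    return df["target_id"].astype(str).tolist(), state


def write_manifest(path, seed: int, config: dict, extra: dict | None = None) -> None:
    """JSON run manifest: seed, config and a hash for exact reproduction."""
    payload = {"seed": seed, "config": config}
    payload["config_hash"] = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
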