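"""Readers and writers for the package's network and report formats.

Networks travel as JSON documents with fields ``n``, ``R`` (n x n signed
integer matrix), ``p``, ``target`` and optional ``uncertain_positions``
(1-based (regulated, regulator) pairs), or as a TSV edge list with columns
``regulator  regulated  sign``.  Both round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import DEFAULT_P, validate_regulatory_matrix
from .uncertainty import UncertaintyClass

__all__ = [
    "write_network_json",
    "read_network_json",
    "write_edge_list",
    "read_edge_list",
    "uncertainty_class_from_json",
]


def write_network_json(
    path,
    R: np.ndarray,
    p: float = DEFAULT_P,
    target: int = 1,
    uncertain_positions=None,
) -> None:
    R = validate_regulatory_matrix(R)
    doc = {
        "n": int(R.shape[0]),
        "R": R.astype(int).tolist(),
        "p": float(p),
        "target": int(target),
    }
    if uncertain_positions:
        doc["uncertain_positions"] = [[int(i), int(j)] for i, j in uncertain_positions]
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_network_json(path) -> dict:
    doc = json.loads(Path(path).read_text())
    allowed = {"n", "R", "p", "target", "uncertain_positions"}
    unknown = set(doc) - allowed
    if unknown:
        raise ValueError(f"unknown keys in network file: {sorted(unknown)}")
    R = validate_regulatory_matrix(np.array(doc["R"]))
    if R.shape[0] != doc["n"]:
        raise ValueError("n does not match the R matrix dimension")
    out = {
        "R": R,
        "p": float(doc.get("p", DEFAULT_P)),
        "target": int(doc.get("target", 1)),
        "uncertain_positions": tuple(
            (int(i), int(j)) for i, j in doc.get("uncertain_positions", [])
        ),
    }
    return out


def uncertainty_class_from_json(path) -> UncertaintyClass:
    doc = read_network_json(path)
    if not doc["uncertain_positions"]:
        raise ValueError("network file declares no uncertain positions")
    return UncertaintyClass(
        doc["R"], doc["uncertain_positions"], p=doc["p"], target=doc["target"]
    )


def write_edge_list(path, R: np.ndarray) -> None:
    """TSV edge list: regulator, regulated, sign (1-based gene indices)."""
    R = validate_regulatory_matrix(R)
    rows = [
        {"regulator": j + 1, "regulated": i + 1, "sign": int(R[i, j])}
        for i, j in np.argwhere(R != 0)
    ]
    pd.DataFrame(rows, columns=["regulator", "regulated", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path, n: int | None = None) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if n is None:
        n = int(max(df["regulator"].max(), df["regulated"].max()))
    R = np.zeros((n, n), dtype=np.int8)
    for _, row in df.iterrows():
        R[int(row["regulated"]) - 1, int(row["regulator"]) - 1] = int(row["sign"])
    return validate_regulatory_matrix(R)
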