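"""Per-residue connectivity scores and result tables.

conn(k) counts the significantly correlated pairs a position belongs to;
conz(k) = (conn(k) - mean) / sigma standardizes the counts over all
positions with conn > 0 (population sigma). Positions with conz at or
above a threshold (2.0 by default) are reported as important.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .significance import PairCorrelation


@dataclass
class ResidueScore:
    """Connectivity of one residue position (1-based)."""

    position: int
    conn: int
    conz: float | None
    mean_conn: float | None
    std_conn: float | None


def conn_values(pairs: list[PairCorrelation], L: int) -> np.ndarray:
    """conn(k) for k = 1..L: membership counts in significant pairs."""
    conn = np.zeros(L, dtype=int)
    for pair in pairs:
        if pair.significant:
            conn[pair.k - 1] += 1
            conn[pair.l - 1] += 1
    return conn


def conz_values(conn: np.ndarray) -> list[ResidueScore]:
    """z-scores of the positive conn(k) values.

    Mean and (population) standard deviation are taken over positions
    with conn > 0 only; positions with conn = 0 carry no conz. With
    fewer than two positive positions, or zero spread, conz is undefined
    everywhere and reported as missing.
    """
    conn = np.asarray(conn)
    positive = conn[conn > 0]
    mean = std = None
    if positive.size < 2:
        if positive.size:
            warnings.warn("fewer than 2 positions with conn > 0; "
                          "conz undefined", stacklevel=2)
    else:
        mean = float(positive.mean())
        std = float(positive.std(ddof=0))
        if std == 0.0:
            warnings.warn("all positive conn values identical; conz undefined",
                          stacklevel=2)
            mean = std = None
    scores = []
    for pos0, c in enumerate(conn):
        conz = None
        if c > 0 and std is not None:
            conz = (float(c) - mean) / std
        scores.append(ResidueScore(
            position=pos0 + 1, conn=int(c), conz=conz,
            mean_conn=mean, std_conn=std,
        ))
    return scores


def select_important(scores: list[ResidueScore],
                     conz_threshold: float = 2.0) -> list[int]:
    """Positions with conz >= threshold, ascending."""
    return sorted(s.position for s in scores
                  if s.conz is not None and s.conz >= conz_threshold)


# ---------------------------------------------------------------------------
# result tables

def _fmt(value, digits=10) -> str:
    if value is None:
        return "NA"
    if isinstance(value, (bool, np.bool_)):
        return "1" if value else "0"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return f"{value:.{digits}g}"


def _header(params: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in params.items())


def write_pair_table(path, pairs: list[PairCorrelation], params: dict) -> None:
    """Tab-separated per-pair results (1-based columns)."""
    with open(path, "w") as fh:
        fh.write(_header(params))
        fh.write("k\tl\tstatistic\tmode\tp_value\tcutoff\tsignificant\tdegenerate\n")
        for p in pairs:
            fh.write("\t".join([
                str(p.k), str(p.l), _fmt(p.statistic), p.mode,
                _fmt(p.p_value), _fmt(p.cutoff), _fmt(p.significant),
                _fmt(p.degenerate),
            ]) + "\n")


def write_residue_table(path, scores: list[ResidueScore],
                        selected: list[int], params: dict) -> None:
    """Tab-separated per-residue results (1-based positions)."""
    chosen = set(selected)
    with open(path, "w") as fh:
        fh.write(_header(params))
        fh.write("k\tconn\tconz\tselected\n")
        for s in scores:
            fh.write("\t".join([
                str(s.position), str(s.conn), _fmt(s.conz),
                "1" if s.position in chosen else "0",
            ]) + "\n")
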