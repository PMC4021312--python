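"""Proximity-based evaluation of predicted residue positions.

Residues within a van der Waals gap of at most 1 Å of any annotated
functional-site residue count as positives, all others as negatives;
predictions are scored by specificity TN/(TN+FP) and precision
TP/(TP+FP). The vdW gap between two atoms is the center distance minus
both radii.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import biotite.structure as struc

from .errors import AnnotationError

#: Element-wise van der Waals radii in Å (heavy atoms; fallback 1.70).
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
VDW_DEFAULT = 1.70


@dataclass
class ResidueClassification:
    """Positive/negative label of one residue with its minimal vdW gap."""

    chain: str
    position: int
    label: str
    distance: float


@dataclass
class PerformanceTable:
    """Contingency counts and the derived metrics."""

    tp: int
    tn: int
    fp: int
    fn: int
    specificity: float
    precision: float | None


def _radii(atoms: struc.AtomArray) -> np.ndarray:
    return np.array([VDW_RADII.get(e, VDW_DEFAULT) for e in atoms.element])


def _protein_heavy(structure: struc.AtomArray) -> struc.AtomArray:
    mask = (
        struc.filter_amino_acids(structure)
        & ~structure.hetero
        & (structure.element != "H")
    )
    atoms = structure[mask]
    if atoms.array_length() == 0:
        raise AnnotationError("structure contains no protein chain")
    return atoms


def _normalize_sites(atoms: struc.AtomArray, site_positions) -> set[tuple[str, int]]:
    chains = np.unique(atoms.chain_id)
    sites = set()
    for site in site_positions:
        if isinstance(site, tuple):
            chain, pos = str(site[0]), int(site[1])
        else:
            chain, pos = str(chains[0]), int(site)
        present = ((atoms.chain_id == chain) & (atoms.res_id == pos)).any()
        if not present:
            raise AnnotationError(
                f"site residue {pos} (chain {chain}) absent from structure"
            )
        sites.add((chain, pos))
    return sites


def classify_residues(structure: struc.AtomArray, site_positions,
                      gap_cutoff_A: float = 1.0) -> list[ResidueClassification]:
    """Label every residue positive/negative by vdW-gap proximity to sites.

    ``site_positions`` is a list of residue ids (single-chain shorthand)
    or (chain, residue id) tuples. Site residues themselves are positives
    at distance 0. Heavy atoms only.
    """
    atoms = _protein_heavy(structure)
    sites = _normalize_sites(atoms, site_positions)
    site_mask = np.zeros(atoms.array_length(), dtype=bool)
    for chain, pos in sites:
        site_mask |= (atoms.chain_id == chain) & (atoms.res_id == pos)
    site_atoms = atoms[site_mask]
    site_radii = _radii(site_atoms)

    results = []
    for chain_id in np.unique(atoms.chain_id):
        chain = atoms[atoms.chain_id == chain_id]
        for rid in np.unique(chain.res_id):
            key = (str(chain_id), int(rid))
            if key in sites:
                results.append(ResidueClassification(
                    chain=key[0], position=key[1], label="positive",
                    distance=0.0,
                ))
                continue
            res = chain[chain.res_id == rid]
            diff = res.coord[:, None, :] - site_atoms.coord[None, :, :]
            center = np.sqrt((diff * diff).sum(axis=-1))
            gaps = center - _radii(res)[:, None] - site_radii[None, :]
            gap = float(gaps.min())
            results.append(ResidueClassification(
                chain=key[0], position=key[1],
                label="positive" if gap <= gap_cutoff_A else "negative",
                distance=gap,
            ))
    return results


def expand_sites(structure: struc.AtomArray, site_positions,
                 distance_A: float = 5.0) -> list[tuple[str, int]]:
    """Neighborhood expansion of a site annotation.

    Adds the direct sequence neighbors of each site residue and every
    residue whose minimal heavy-atom distance to a site residue is at
    most ``distance_A`` — the annotation rule used for detailed
    case-by-case assessment of predictions.
    """
    atoms = _protein_heavy(structure)
    sites = _normalize_sites(atoms, site_positions)
    expanded = set(sites)
    for chain, pos in sites:
        for neighbor in (pos - 1, pos + 1):
            if ((atoms.chain_id == chain) & (atoms.res_id == neighbor)).any():
                expanded.add((chain, neighbor))
    site_mask = np.zeros(atoms.array_length(), dtype=bool)
    for chain, pos in sites:
        site_mask |= (atoms.chain_id == chain) & (atoms.res_id == pos)
    site_coords = atoms.coord[site_mask]
    for chain_id in np.unique(atoms.chain_id):
        chain = atoms[atoms.chain_id == chain_id]
        for rid in np.unique(chain.res_id):
            if (str(chain_id), int(rid)) in expanded:
                continue
            res = chain[chain.res_id == rid]
            diff = res.coord[:, None, :] - site_coords[None, :, :]
            if np.sqrt((diff * diff).sum(axis=-1)).min() <= distance_A:
                expanded.add((str(chain_id), int(rid)))
    return sorted(expanded)


def performance(predicted, classes: list[ResidueClassification]) -> PerformanceTable:
    """Specificity and precision of a predicted position set.

    ``predicted`` holds positions (ints, or (chain, position) tuples)
    that must all appear in ``classes``. Precision is undefined (None)
    when nothing is predicted.
    """
    by_key = {}
    for c in classes:
        by_key[(c.chain, c.position)] = c.label
        by_key.setdefault(c.position, c.label)
    pred_keys = set()
    for p in predicted:
        key = (str(p[0]), int(p[1])) if isinstance(p, tuple) else int(p)
        if key not in by_key:
            raise ValueError(f"predicted position {p!r} was never classified")
        pred_keys.add(key if isinstance(key, tuple) else key)
    tp = tn = fp = fn = 0
    for c in classes:
        hit = (c.chain, c.position) in pred_keys or c.position in pred_keys
        if c.label == "positive":
            tp += hit
            fn += not hit
        else:
            fp += hit
            tn += not hit
    specificity = tn / (tn + fp) if (tn + fp) else 1.0
    precision = tp / (tp + fp) if (tp + fp) else None
    return PerformanceTable(tp=tp, tn=tn, fp=fp, fn=fn,
                            specificity=specificity, precision=precision)
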