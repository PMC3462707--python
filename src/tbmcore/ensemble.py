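"""Operations over an ensemble of candidate models of one target.

A model-building run typically produces on the order of 100 alternative
structures for the same sequence.  Two consensus quantities drive the rest
of the pipeline: the *representative* model (the member of the largest
structural cluster nearest its center) and the per-residue *fluctuation
profile* (how much each residue moves across the ensemble once the rigid
consensus core is superposed), which is the basis of unreliable-local-
region detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from tbmcore.metrics import kabsch
from tbmcore.structio import Structure

__all__ = ["ModelEnsemble", "FluctuationProfile", "representative",
           "fluctuation", "pairwise_rmsd", "single_linkage_clusters"]

DEFAULT_CLUSTER_CUTOFF = 2.0  # A, CA-RMSD neighbour threshold


@dataclass
class ModelEnsemble:
    """Ordered models of a single target; all share sequence and length."""

    models: list[Structure]

    def __post_init__(self) -> None:
        if len(self.models) < 2:
            raise ValueError("ensemble needs at least 2 models")
        seq = self.models[0].sequence
        for i, m in enumerate(self.models):
            if m.sequence != seq:
                raise ValueError(f"model {i} sequence differs from model 0")

    @property
    def n(self) -> int:
        return len(self.models)

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class FluctuationProfile:
    """Mean per-residue CA deviation (A) across an ensemble."""

    per_residue: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.per_residue, dtype=float)
        if arr.ndim != 1 or np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError("profile must be a 1-D array of non-negative reals")
        object.__setattr__(self, "per_residue", arr)

    def __len__(self) -> int:
        return len(self.per_residue)


def pairwise_rmsd(ens: ModelEnsemble) -> np.ndarray:
    """Symmetric matrix of full-chain CA RMSDs after optimal superposition."""
    coords = [m.ca_coords() for m in ens.models]
    n = ens.n
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = kabsch(coords[i], coords[j]).rmsd
    return out


def single_linkage_clusters(dist: np.ndarray, cutoff: float) -> list[list[int]]:
    """Connected components of the graph joining models within ``cutoff``."""
    n = len(dist)
    seen = [False] * n
    clusters = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in range(n):
                if not seen[j] and dist[i, j] <= cutoff:
                    seen[j] = True
                    stack.append(j)
        clusters.append(sorted(comp))
    return clusters


def representative(ens: ModelEnsemble,
                   cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF) -> int:
    """Index of the representative model: the member of the largest cluster
    nearest the cluster center.

    Models are clustered by single linkage on the pairwise CA-RMSD matrix
    at ``cluster_cutoff``; within the largest cluster (ties: the cluster
    containing the lowest index) the member minimizing the mean RMSD to its
    co-members wins (ties: lowest index).
    """
    dist = pairwise_rmsd(ens)
    clusters = single_linkage_clusters(dist, cluster_cutoff)
    clusters.sort(key=lambda c: (-len(c), min(c)))
    largest = clusters[0]
    if len(largest) == 1:
        return largest[0]
    best, best_mean = largest[0], np.inf
    for i in largest:
        m = float(np.mean([dist[i, j] for j in largest if j != i]))
        if m < best_mean - 1e-12:
            best, best_mean = i, m
    return best


def _core_superpose(mobile: np.ndarray, fixed: np.ndarray,
                    max_iter: int = 10) -> np.ndarray:
    """Superpose on the consensus core by iteratively trimming outliers.

    Starts from all residues; residues deviating by more than twice the
    median deviation are dropped and the fit repeated, up to ``max_iter``
    times or until the kept set stabilizes (never below 4 residues).
    Returns the transformed mobile coordinates.
    """
    keep = np.arange(len(mobile))
    sup = kabsch(mobile, fixed)
    for _ in range(max_iter):
        d = np.linalg.norm(sup.apply(mobile) - fixed, axis=1)
        med = np.median(d[keep])
        if med <= 1e-9:
            break
        new_keep = np.flatnonzero(d <= 2.0 * med)
        if len(new_keep) < 4 or set(new_keep) == set(keep):
            break
        keep = new_keep
        sup = kabsch(mobile, fixed, subset=keep)
    return sup.apply(mobile)


def fluctuation(ens: ModelEnsemble,
                reference: int | None = None) -> FluctuationProfile:
    """Per-residue consensus fluctuation profile of an ensemble.

    Every model is superposed onto the reference model (default: the
    representative) on the rigid consensus core — an iterative fit that
    trims residues deviating more than twice the median — and the profile
    is the mean CA deviation from the reference over all other models.
    """
    if reference is None:
        reference = representative(ens)
    if not (0 <= reference < ens.n):
        raise IndexError("reference index out of range")
    ref = ens.models[reference].ca_coords()
    devs = []
    for i, m in enumerate(ens.models):
        if i == reference:
            continue
        moved = _core_superpose(m.ca_coords(), ref)
        devs.append(np.linalg.norm(moved - ref, axis=1))
    return FluctuationProfile(np.mean(devs, axis=0))
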