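"""Robustness statistics for multi-region signature evaluation.

Three complementary statistics quantify whether a signature groups samples
by patient-of-origin or by region-of-origin:

* **patient clade concordance** — on a dendrogram, a patient clusters
  concordantly when the smallest clade containing all of that patient's
  samples contains nobody else's (a pure clade).  The fraction of
  concordant patients is the headline clustering score.
* **normalized patient similarity** — for each patient p, the mean Pearson
  correlation among p's own samples minus the mean correlation between p's
  samples and everyone else's.  Zero means no within-patient excess
  correlation; 1 is the perfect-within / null-between limit.
* **PGOR** (patient group overall ratio) — cut the dendrogram into
  k = 1..k_max groups and report, at each k, the fraction of patients whose
  samples all land in one cluster.  Because cuts are nested the curve is
  monotone non-increasing, starting at 1 for k = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .cluster import Dendrogram, cut_tree

__all__ = [
    "ConcordanceResult",
    "SimilarityMatrix",
    "PatientSimilarityScores",
    "PGORCurve",
    "patient_clade_concordance",
    "pearson_similarity",
    "normalized_patient_similarity",
    "pgor_curve",
]


@dataclass
class ConcordanceResult:
    per_patient: dict[str, bool]  # patient -> concordant?
    fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"concordant": pd.Series(self.per_patient)}
        ).rename_axis("patient")


@dataclass
class SimilarityMatrix:
    ids: list[str]
    r: np.ndarray  # Pearson correlations, unit diagonal

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.shape != (len(self.ids), len(self.ids)):
            raise ValueError("similarity matrix shape mismatch")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(r)) > 1 + 1e-8:
                raise ValueError("correlations outside [-1, 1]")
        self.r = r


@dataclass
class PatientSimilarityScores:
    per_patient: dict[str, float]
    median: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": pd.Series(self.per_patient)}
        ).rename_axis("patient")


@dataclass
class PGORCurve:
    points: list[tuple[int, float]]  # (k, pgor)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["k", "pgor"])

    def at(self, k: int) -> float:
        for kk, v in self.points:
            if kk == k:
                return v
        raise KeyError(k)


def _patient_leaves(tree: Dendrogram, ann: pd.DataFrame) -> dict[str, frozenset[int]]:
    missing = [s for s in tree.leaf_ids if s not in ann.index]
    if missing:
        raise ValueError(f"leaves without annotation: {missing[:5]}")
    idx = {s: i for i, s in enumerate(tree.leaf_ids)}
    groups: dict[str, set[int]] = {}
    for s in tree.leaf_ids:
        groups.setdefault(str(ann.loc[s, "patient_id"]), set()).add(idx[s])
    return {p: frozenset(v) for p, v in groups.items()}


def patient_clade_concordance(tree: Dendrogram, ann: pd.DataFrame) -> ConcordanceResult:
    """Fraction of patients whose samples form a pure clade.

    The smallest clade containing all of a patient's samples is located on
    the merge tree; the patient is concordant iff that clade contains no
    other patient's samples.  Patients with a single sample are trivially
    concordant (their leaf is the clade).
    """
    leafsets = tree.node_leafsets()
    patients = _patient_leaves(tree, ann)
    per_patient: dict[str, bool] = {}
    for p, leaves in patients.items():
        smallest = min(
            (s for s in leafsets if leaves <= s), key=len
        )
        per_patient[p] = smallest == leaves
    fraction = float(np.mean([v for v in per_patient.values()]))
    return ConcordanceResult(per_patient=per_patient, fraction=fraction)


def pearson_similarity(matrix: pd.DataFrame) -> SimilarityMatrix:
    """Pearson correlation between every pair of sample columns over the
    (signature) genes.  A zero-variance sample yields NaN entries, which
    downstream scoring treats as missing."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 genes to correlate samples")
    x = matrix.to_numpy(dtype=float).T
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.asarray(r, dtype=float)
    for i in np.flatnonzero(sd == 0):
        r[i, :] = np.nan
        r[:, i] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return SimilarityMatrix(ids=[str(c) for c in matrix.columns], r=r)


def normalized_patient_similarity(
    sim: SimilarityMatrix, ann: pd.DataFrame
) -> PatientSimilarityScores:
    """Within-minus-between mean correlation per patient.

    s_p = mean r over p's within-patient sample pairs
          - mean r over (sample-of-p, sample-of-other) pairs.

    Patients with fewer than two samples are excluded with a warning; a NaN
    correlation on any of a patient's within-pairs is an error (the score
    would be undefined).
    """
    idx = {s: i for i, s in enumerate(sim.ids)}
    groups: dict[str, list[int]] = {}
    for s in sim.ids:
        groups.setdefault(str(ann.loc[s, "patient_id"]), []).append(idx[s])

    scores: dict[str, float] = {}
    for p, members in groups.items():
        if len(members) < 2:
            warnings.warn(f"patient {p} has <2 samples; excluded from "
                          "similarity scoring", stacklevel=2)
            continue
        within = [sim.r[i, j] for i, j in combinations(members, 2)]
        if np.any(np.isnan(within)):
            raise ValueError(f"undefined within-patient correlation for {p}")
        others = [i for i in range(len(sim.ids)) if i not in members]
        between = sim.r[np.ix_(members, others)].ravel()
        between = between[~np.isnan(between)]
        scores[p] = float(np.mean(within) - np.mean(between))
    if not scores:
        raise ValueError("no patient with >=2 samples")
    return PatientSimilarityScores(
        per_patient=scores, median=float(np.median(list(scores.values())))
    )


def pgor_curve(tree: Dendrogram, ann: pd.DataFrame, k_max: int) -> PGORCurve:
    """PGOR at every k = 1..k_max.

    PGOR_k = (number of patients with all samples in one cluster of the
    k-group cut) / (total number of patients).  Monotone non-increasing in
    k by cut nesting; asserted on every run.
    """
    if k_max > tree.n_leaves:
        raise ValueError("k_max exceeds number of samples")
    patients = _patient_leaves(tree, ann)
    n_pat = len(patients)
    points: list[tuple[int, float]] = []
    prev = np.inf
    for k in range(1, k_max + 1):
        labels = cut_tree(tree, k)
        arr = [labels[s] for s in tree.leaf_ids]
        grouped = 0
        for p, leaves in patients.items():
            labs = {arr[i] for i in leaves}
            if len(labs) == 1:
                grouped += 1
        pgor = grouped / n_pat
        assert pgor <= prev + 1e-12, "PGOR must be non-increasing in k"
        prev = pgor
        points.append((k, pgor))
    return PGORCurve(points=points)
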