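"""Nearest-template prediction (NTP) subtype assignment.

Each subtype is represented by a binary template vector over the union of
the classifier's marker genes (1 on the subtype's own markers, 0
elsewhere).  A sample, restricted to the matched marker genes of a
median-standardized gene-level matrix, is assigned the subtype whose
template is nearest in cosine distance.  Significance is assessed by
resampling: random gene sets of the same size drawn from the full matrix
gene universe supply a null distribution of distances to the assigned
template, with the add-one correction p = (b + 1) / (n + 1); p-values are
then Benjamini-Hochberg corrected across samples and calls are flagged
significant when FDR falls below the threshold (labels are retained either
way — the flag distinguishes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .io import AliasTable, SignatureGeneSet, resolve_symbols

logger = logging.getLogger(__name__)

__all__ = [
    "TemplateSet",
    "SubtypeCall",
    "RegionConcordanceTable",
    "build_templates",
    "ntp_classify",
    "region_concordance",
    "calls_to_frame",
]


@dataclass
class TemplateSet:
    """Binary subtype templates over the union of marker genes."""

    subtypes: list[str]
    genes: list[str]  # union, order of first appearance
    vectors: np.ndarray  # (n_subtypes, n_genes) in {0, 1}

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (len(self.subtypes), len(self.genes)):
            raise ValueError("template matrix shape mismatch")
        if np.any(v.sum(axis=1) == 0):
            empty = [s for s, row in zip(self.subtypes, v) if row.sum() == 0]
            raise ValueError(f"subtypes with no marker genes: {empty}")
        self.vectors = v


@dataclass
class SubtypeCall:
    sample_id: str
    label: str
    distance: float  # cosine distance in [0, 2]
    p_value: float
    fdr: float
    significant: bool


@dataclass
class RegionConcordanceTable:
    """Per region subset: how many patients carry one shared label
    (concordant) and how many share no label between any two regions."""

    n_patients: int
    rows: dict[tuple[str, ...], dict[str, float]]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for subset, row in self.rows.items():
            recs.append({"regions": "+".join(subset), **row})
        return pd.DataFrame(recs)


def build_templates(sig: SignatureGeneSet) -> TemplateSet:
    """Binary template per subtype from a labelled signature.

    A gene listed under several subtypes contributes a 1 to each of its
    templates.  Subtype order is the order of first appearance along the
    signature's gene list.
    """
    unlabeled = [g for g in sig.genes if not sig.subtype_of.get(g)]
    if unlabeled:
        raise ValueError(
            f"signature {sig.name!r}: genes without subtype labels: "
            f"{unlabeled[:5]}"
        )
    subtypes = sig.subtypes
    genes = list(sig.genes)
    vectors = np.zeros((len(subtypes), len(genes)))
    pos = {s: i for i, s in enumerate(subtypes)}
    for j, g in enumerate(genes):
        for lab in sig.subtype_of[g]:
            vectors[pos[lab], j] = 1.0
    return TemplateSet(subtypes=subtypes, genes=genes, vectors=vectors)


def _cosine_distance(x: np.ndarray, t: np.ndarray) -> float:
    nx = np.linalg.norm(x)
    nt = np.linalg.norm(t)
    if nx == 0 or nt == 0:
        return 1.0  # orthogonal by convention for a degenerate vector
    return float(1.0 - np.dot(x, t) / (nx * nt))


def ntp_classify(
    matrix: pd.DataFrame,
    templates: TemplateSet,
    n_resamples: int = 1000,
    fdr_threshold: float = 0.2,
    seed: int = 0,
    aliases: AliasTable | None = None,
) -> list[SubtypeCall]:
    """Assign every sample its nearest subtype template.

    ``matrix`` must be gene-level and median-standardized.  Template genes
    are matched onto the matrix rows through ``aliases`` (dropout logged);
    every subtype needs at least two matched markers.  The resampling null
    draws ``n_resamples`` random gene sets of the matched size from all
    matrix genes (one shared draw per run, fixed by ``seed``) and compares
    the sample's distance to its assigned template against the distances
    obtained on the random gene sets.
    """
    mapped, report = resolve_symbols(templates.genes, aliases, matrix.index)
    if report.n_dropped:
        logger.info("NTP: %d/%d template genes not on platform",
                    report.n_dropped, report.n_input)
    keep = [i for i, g in enumerate(templates.genes)
            if report.match_route[g] != "unmatched"]
    if len(mapped) != len(keep):
        raise ValueError("template genes collapse onto duplicate matrix rows")
    tvec = templates.vectors[:, keep]
    for s, row in zip(templates.subtypes, tvec):
        if row.sum() < 2:
            raise ValueError(
                f"subtype {s!r} has <2 marker genes after platform matching"
            )

    x = matrix.loc[mapped].to_numpy(dtype=float)  # (n_genes, n_samples)
    n_genes, n_samples = x.shape

    # observed assignment
    dists = np.empty((len(templates.subtypes), n_samples))
    for ti, t in enumerate(tvec):
        dists[ti] = [_cosine_distance(x[:, j], t) for j in range(n_samples)]
    best = dists.argmin(axis=0)  # ties -> lowest subtype index (declared order)
    for j in range(n_samples):
        tied = np.flatnonzero(np.isclose(dists[:, j], dists[best[j], j]))
        if len(tied) > 1:
            logger.info("NTP: distance tie for sample %s between %s; "
                        "taking %s", matrix.columns[j],
                        [templates.subtypes[t] for t in tied],
                        templates.subtypes[best[j]])

    # resampling null: random gene sets of the matched size from the full
    # matrix universe, shared across samples for a fixed seed
    rng = np.random.default_rng(seed)
    universe = matrix.to_numpy(dtype=float)
    draws = np.stack([
        rng.choice(universe.shape[0], size=n_genes, replace=False)
        for _ in range(n_resamples)
    ])
    p_values = np.empty(n_samples)
    for j in range(n_samples):
        t = tvec[best[j]]
        obs = dists[best[j], j]
        null_x = universe[:, j][draws]  # (n_resamples, n_genes)
        tn = t / np.linalg.norm(t)
        norms = np.linalg.norm(null_x, axis=1)
        norms[norms == 0] = np.inf
        null_d = 1.0 - (null_x @ tn) / norms
        b = int(np.sum(null_d <= obs))
        p_values[j] = (b + 1) / (n_resamples + 1)

    fdr = false_discovery_control(p_values, method="bh")
    calls = []
    for j, sample in enumerate(matrix.columns):
        calls.append(SubtypeCall(
            sample_id=str(sample),
            label=templates.subtypes[best[j]],
            distance=float(dists[best[j], j]),
            p_value=float(p_values[j]),
            fdr=float(fdr[j]),
            significant=bool(fdr[j] < fdr_threshold),
        ))
    return calls


def calls_to_frame(calls: list[SubtypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(c) for c in calls]
    ).set_index("sample_id")


def region_concordance(
    calls: list[SubtypeCall],
    ann: pd.DataFrame,
    regions: tuple[str, ...] | None = None,
    require_significant: bool = False,
) -> RegionConcordanceTable:
    """Cross-region agreement of subtype calls, per patient.

    For every pair of regions and for the full region set, a patient is
    *concordant* when all its calls in that subset share one label, and
    *no-overlap* when no two regions of the subset share a label.  By
    default the assigned label is used regardless of significance;
    ``require_significant`` relabels non-significant calls "unclassified"
    first.
    """
    frame = calls_to_frame(calls)
    if require_significant:
        frame.loc[~frame["significant"], "label"] = "unclassified"
    label_of: dict[tuple[str, str], str] = {}
    for sample, row in frame.iterrows():
        if sample not in ann.index:
            raise ValueError(f"call for unannotated sample {sample}")
        key = (str(ann.loc[sample, "patient_id"]), str(ann.loc[sample, "region"]))
        label_of[key] = row["label"]

    if regions is None:
        regions = tuple(sorted(ann["region"].unique()))
    patients = sorted(ann["patient_id"].unique())

    subsets: list[tuple[str, ...]] = []
    from itertools import combinations
    if len(regions) > 2:
        subsets.extend(combinations(regions, 2))
    subsets.append(tuple(regions))

    rows: dict[tuple[str, ...], dict[str, float]] = {}
    for subset in subsets:
        n_conc = n_noov = 0
        for p in patients:
            labels = []
            for r in subset:
                if (p, r) not in label_of:
                    raise ValueError(f"missing call for patient {p} region {r}")
                labels.append(label_of[(p, r)])
            if len(set(labels)) == 1:
                n_conc += 1
            if all(a != b for a, b in combinations(labels, 2)):
                n_noov += 1
        rows[subset] = {
            "n_concordant": n_conc,
            "frac_concordant": n_conc / len(patients),
            "n_no_overlap": n_noov,
            "frac_no_overlap": n_noov / len(patients),
        }
    return RegionConcordanceTable(n_patients=len(patients), rows=rows)
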