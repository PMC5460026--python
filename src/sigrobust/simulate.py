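"""Synthetic multi-region tumour expression data.

The generator emulates the statistical structure that the robustness
analyses assume about multi-region bulk profiling of solid tumours:

* every patient contributes one sample per region (central tumour CT,
  invasive front IF, lymph-node metastasis LN by default);
* *epithelial* genes carry a patient-intrinsic effect — each (patient, gene)
  pair draws a stable offset, shared by all of that patient's regions;
* *stromal* genes (fibroblast, leukocyte, endothelial) track the cellular
  composition of the sampled region: each sample draws a compartment
  fraction around a region-specific mean (the invasive front is the most
  fibroblast-rich, the lymph node the most leukocyte-rich), and each stromal
  gene responds with its own positive loading;
* additive Gaussian measurement noise on the log2 scale.

The generative model for gene g in sample s (patient p, region r) is

    x_{g,s} = b_g + delta_{p,g} * [comp(g) = epithelial]
                  + lambda_g * f_{p,r,comp(g)} * [comp(g) != epithelial]
                  + eps_{g,s}

with b_g ~ N(baseline_mean, baseline_sd), delta ~ N(0, patient_effect_sd),
lambda_g ~ |N(stromal_loading_mean, 0.5)|, f clipped to [0, 1] around the
region mean, and eps ~ N(0, noise_sd).  Mixing is additive on the log scale
— a deliberate simplification of linear-scale convex mixing that keeps the
stromal signal monotone in the fraction.

Ground truth (gene compartments and per-sample fractions) is returned
alongside the matrix so parameter-recovery tests can score the pipeline
against what was actually planted.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

COMPARTMENTS = ("epithelial", "fibroblast", "leukocyte", "endothelial")

_DEFAULT_GENES = {c: 250 for c in COMPARTMENTS}
_DEFAULT_FRACTIONS = {
    "CT": {"fibroblast": 0.20, "leukocyte": 0.15, "endothelial": 0.05},
    "IF": {"fibroblast": 0.50, "leukocyte": 0.20, "endothelial": 0.05},
    "LN": {"fibroblast": 0.35, "leukocyte": 0.40, "endothelial": 0.05},
}

__all__ = [
    "COMPARTMENTS",
    "SimulationParams",
    "SyntheticDataset",
    "simulate_multiregion",
    "simulate_facs_reference",
    "compartment_signature",
]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the multi-region generator.  All expression quantities are in
    log2 units; fractions are cell-composition proportions in [0, 1]."""

    n_patients: int = 24
    regions: tuple[str, ...] = ("CT", "IF", "LN")
    genes_per_compartment: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_GENES))
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    patient_effect_sd: float = 1.0
    stromal_loading_mean: float = 2.0
    stromal_loading_sd: float = 0.5
    region_fraction_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {r: dict(v) for r, v in _DEFAULT_FRACTIONS.items()})
    fraction_sd: float = 0.05
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not self.regions:
            raise ValueError("at least one region required")
        for comp, n in self.genes_per_compartment.items():
            if comp not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {comp!r}")
            if n <= 0:
                raise ValueError(f"gene count for {comp} must be positive")
        for r in self.regions:
            if r not in self.region_fraction_means:
                raise ValueError(f"no fraction means for region {r!r}")
        for sd in (self.baseline_sd, self.patient_effect_sd,
                   self.fraction_sd, self.noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be nonnegative")

    def with_(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)


@dataclass
class SyntheticDataset:
    """A generated dataset plus the ground truth that produced it."""

    matrix: pd.DataFrame  # genes x samples, log2
    annotation: pd.DataFrame  # sample_id index; patient_id, region
    truth_compartment: pd.Series  # gene -> compartment
    truth_fractions: pd.DataFrame  # (patient, region, compartment) -> fraction
    params: SimulationParams

    def signature(self, compartment: str):
        """Ground-truth gene set for one compartment (see
        :func:`compartment_signature`)."""
        return compartment_signature(self, compartment)


def _patient_labels(n: int) -> list[str]:
    """Alphabetic patient labels; for cohorts of up to 25 these follow the
    A..Y convention of multi-region studies (M reserved for QC dropout when
    exactly 24 are requested)."""
    letters = [c for c in string.ascii_uppercase[:25]]
    if n == 24:
        letters = [c for c in letters if c != "M"]
    if n <= len(letters):
        return letters[:n]
    return [f"P{i:03d}" for i in range(1, n + 1)]


def _gene_ids(genes_per_compartment: Mapping[str, int]) -> tuple[list[str], list[str]]:
    prefix = {"epithelial": "EPI", "fibroblast": "FIB",
              "leukocyte": "LEU", "endothelial": "END"}
    ids: list[str] = []
    comps: list[str] = []
    for comp in COMPARTMENTS:
        n = genes_per_compartment.get(comp, 0)
        ids.extend(f"{prefix[comp]}{i:04d}" for i in range(1, n + 1))
        comps.extend([comp] * n)
    return ids, comps


def simulate_multiregion(params: SimulationParams | None = None) -> SyntheticDataset:
    """Generate a patient x region expression dataset under the additive
    log-scale mixture model described in the module docstring.

    Deterministic for a fixed ``params.seed`` (bit-identical matrices).
    """
    params = params or SimulationParams()
    params.validate()
    rng = np.random.default_rng(params.seed)

    patients = _patient_labels(params.n_patients)
    gene_ids, gene_comp = _gene_ids(params.genes_per_compartment)
    comp_arr = np.asarray(gene_comp)
    n_genes = len(gene_ids)
    samples = [f"{p}_{r}" for p in patients for r in params.regions]

    baseline = rng.normal(params.baseline_mean, params.baseline_sd, n_genes)
    loading = np.abs(rng.normal(params.stromal_loading_mean,
                                params.stromal_loading_sd, n_genes))

    epi_mask = comp_arr == "epithelial"
    # one stable offset per (patient, epithelial gene)
    delta = rng.normal(0.0, params.patient_effect_sd,
                       (len(patients), int(epi_mask.sum())))

    frac_records = []
    fractions: dict[tuple[str, str], dict[str, float]] = {}
    for p in patients:
        for r in params.regions:
            means = params.region_fraction_means[r]
            f = {}
            for comp in COMPARTMENTS:
                if comp == "epithelial":
                    continue
                mu = means.get(comp, 0.0)
                f[comp] = float(np.clip(rng.normal(mu, params.fraction_sd), 0.0, 1.0))
                frac_records.append((p, r, comp, f[comp]))
            fractions[(p, r)] = f

    values = np.empty((n_genes, len(samples)))
    col = 0
    for ip, p in enumerate(patients):
        for r in params.regions:
            x = baseline.copy()
            x[epi_mask] += delta[ip]
            for comp in COMPARTMENTS:
                if comp == "epithelial":
                    continue
                mask = comp_arr == comp
                x[mask] += loading[mask] * fractions[(p, r)][comp]
            values[:, col] = x
            col += 1
    values += rng.normal(0.0, params.noise_sd, values.shape)

    matrix = pd.DataFrame(values, index=gene_ids, columns=samples)
    annotation = pd.DataFrame(
        {
            "patient_id": [s.split("_")[0] for s in samples],
            "region": [s.split("_", 1)[1] for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    truth_fractions = pd.DataFrame(
        frac_records, columns=["patient", "region", "compartment", "fraction"]
    )
    return SyntheticDataset(
        matrix=matrix,
        annotation=annotation,
        truth_compartment=pd.Series(gene_comp, index=gene_ids, name="compartment"),
        truth_fractions=truth_fractions,
        params=params,
    )


def simulate_facs_reference(
    params: SimulationParams | None = None,
    n_cells_per_compartment: int = 4,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Generate a flow-sorted compartment reference over the same gene
    universe as :func:`simulate_multiregion`.

    Each compartment-specific gene is expressed at baseline + its own
    loading lambda_g in samples of its own compartment and at baseline
    elsewhere, plus noise — the idealized analogue of profiling sorted
    epithelial / fibroblast / leukocyte / endothelial populations.

    Returns the reference matrix and a sample -> compartment label map.
    The seed is offset from the multi-region seed so the reference is
    independent of the bulk dataset while staying reproducible.
    """
    params = params or SimulationParams()
    params.validate()
    if n_cells_per_compartment < 2:
        raise ValueError("need at least 2 sorted samples per compartment")
    rng = np.random.default_rng((params.seed + 101) % (2**31))

    gene_ids, gene_comp = _gene_ids(params.genes_per_compartment)
    comp_arr = np.asarray(gene_comp)
    n_genes = len(gene_ids)

    baseline = rng.normal(params.baseline_mean, params.baseline_sd, n_genes)
    loading = np.abs(rng.normal(params.stromal_loading_mean,
                                params.stromal_loading_sd, n_genes))

    columns: list[str] = []
    labels: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    for comp in COMPARTMENTS:
        for i in range(1, n_cells_per_compartment + 1):
            sample = f"{comp}_{i}"
            columns.append(sample)
            labels[sample] = comp
            x = baseline + loading * (comp_arr == comp)
            blocks.append(x)
    values = np.column_stack(blocks)
    values += rng.normal(0.0, params.noise_sd, values.shape)
    return pd.DataFrame(values, index=gene_ids, columns=columns), labels


def compartment_signature(dataset: SyntheticDataset, compartment: str):
    """Ground-truth signature: all generated genes of one compartment."""
    from .io import SignatureGeneSet

    if compartment not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}")
    genes = dataset.truth_compartment.index[
        dataset.truth_compartment == compartment
    ].tolist()
    return SignatureGeneSet(
        name=f"synthetic-{compartment}",
        genes=genes,
        provenance="generator ground truth",
    )
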