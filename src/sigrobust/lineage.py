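"""Cell-compartment attribution of signature genes.

Bulk tumour expression mixes transcripts from neoplastic epithelium with
fibroblast, leukocyte and endothelial contributions.  Given a reference of
flow-sorted compartment profiles, each signature gene gets a median log2
expression per compartment; the compartment whose per-gene medians are
collectively highest (median of medians) is declared the signature's
dominant transcript source.  Signatures dominated by fibroblast-derived
genes are the ones most exposed to region-of-origin confounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AliasTable, SignatureGeneSet, resolve_symbols

__all__ = [
    "CompartmentProfile",
    "DominanceResult",
    "compartment_medians",
    "dominant_compartment",
    "one_way_anova",
    "signature_overlap",
]


@dataclass
class CompartmentProfile:
    """Per-gene compartment medians for one signature.

    ``medians`` is a genes x compartments DataFrame of median log2
    expression across each compartment's sorted samples.
    """

    signature: str
    medians: pd.DataFrame
    n_dropped: int = 0

    @property
    def compartments(self) -> list[str]:
        return list(self.medians.columns)


@dataclass
class DominanceResult:
    label: str
    margin: float  # median-of-medians gap to the runner-up compartment
    tie: bool
    per_compartment: pd.Series


def compartment_medians(
    ref: pd.DataFrame,
    comp_labels: Mapping[str, str],
    sig: SignatureGeneSet,
    aliases: AliasTable | None = None,
) -> CompartmentProfile:
    """Median expression of each signature gene in each sorted compartment.

    ``comp_labels`` maps every reference sample to its compartment; each
    compartment needs at least two sorted samples for a meaningful median.
    Genes that do not resolve onto the reference platform are dropped (the
    count is retained on the profile).
    """
    labels = pd.Series({str(k): str(v) for k, v in comp_labels.items()})
    missing = [s for s in ref.columns if s not in labels.index]
    if missing:
        raise ValueError(f"reference samples without compartment label: {missing[:5]}")
    counts = labels.loc[list(ref.columns)].value_counts()
    thin = counts[counts < 2]
    if not thin.empty:
        raise ValueError(f"compartments with <2 samples: {list(thin.index)}")

    mapped, report = resolve_symbols(sig, aliases, ref.index)
    if not mapped:
        raise ValueError(f"signature {sig.name!r}: no genes on the reference")
    sub = ref.loc[mapped]
    medians = {}
    for comp in sorted(counts.index):
        cols = [s for s in ref.columns if labels[s] == comp]
        medians[comp] = sub[cols].median(axis=1)
    return CompartmentProfile(
        signature=sig.name,
        medians=pd.DataFrame(medians),
        n_dropped=report.n_dropped,
    )


def dominant_compartment(profile: CompartmentProfile) -> DominanceResult:
    """Compartment with the highest median of per-gene medians.

    The margin to the runner-up is reported; an exact tie is flagged (the
    lexicographically first tied compartment is returned as the label).
    """
    if profile.medians.empty:
        raise ValueError("empty compartment profile")
    summary = profile.medians.median(axis=0).sort_index()
    order = summary.sort_values(ascending=False, kind="stable")
    top, runner = order.iloc[0], order.iloc[1] if len(order) > 1 else -np.inf
    tied = summary.index[summary == top].tolist()
    return DominanceResult(
        label=sorted(tied)[0] if len(tied) > 1 else str(order.index[0]),
        margin=float(top - runner),
        tie=len(tied) > 1,
        per_compartment=summary,
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA: F = MS_between / MS_within with the
    F-distribution p-value.

    Degenerate inputs: zero within-group variance with unequal means gives
    (inf, 0.0); zero within-group variance with equal means leaves F
    undefined, returned as (nan, nan).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")

    means = [a.mean() for a in arrays]
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0:
        if np.allclose(means, means[0]):
            return float("nan"), float("nan")
        return float("inf"), 0.0
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def signature_overlap(
    a: SignatureGeneSet,
    b: SignatureGeneSet,
    aliases: AliasTable | None = None,
) -> list[str]:
    """Genes shared by two signatures after alias resolution.

    Both gene lists are canonicalized through the same alias table
    (approved symbol where known, else the upper-cased input symbol) and
    intersected; the result keeps the order of ``a``.
    """
    canon_a = [_canonical(sym, aliases) for sym in a.genes]
    canon_b = {_canonical(sym, aliases) for sym in b.genes}
    out: list[str] = []
    for sym in canon_a:
        if sym in canon_b and sym not in out:
            out.append(sym)
    return out


def _canonical(symbol: str, aliases: AliasTable | None) -> str:
    if aliases is None:
        return symbol.upper()
    app = aliases.lookup_approved(symbol)
    if app is not None:
        return app
    for candidates in (aliases.lookup_previous(symbol), aliases.lookup_alias(symbol)):
        if candidates:
            return sorted(candidates)[0]
    return symbol.upper()
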