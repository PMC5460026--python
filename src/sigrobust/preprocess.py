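"""Standardization and signature subsetting ahead of clustering.

Clustering of signature genes operates on matrices standardized to the
per-row (per probe-set / gene) median: each row is shifted so its median
across samples is zero.  This is shift-only — no variance scaling — so
Euclidean distances between samples still reflect absolute log2 effect
sizes; ``scale=True`` additionally divides by the row standard deviation
for sensitivity analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import AliasTable, ResolutionReport, SignatureGeneSet, resolve_symbols

__all__ = ["median_standardize", "subset_to_signature"]


def median_standardize(matrix: pd.DataFrame, scale: bool = False) -> pd.DataFrame:
    """Center every row at its across-sample median (idempotent).

    The median of an even number of samples is the mean of the two central
    order statistics.  With ``scale`` set, rows are also divided by their
    standard deviation (constant rows are left unscaled to stay finite).
    """
    if matrix.shape[1] < 1:
        raise ValueError("matrix has no samples")
    centered = matrix.sub(matrix.median(axis=1), axis=0)
    if scale:
        sd = centered.std(axis=1, ddof=1).replace(0.0, 1.0)
        centered = centered.div(sd, axis=0)
    return centered


def subset_to_signature(
    matrix: pd.DataFrame,
    sig: SignatureGeneSet,
    aliases: AliasTable | None = None,
) -> tuple[pd.DataFrame, ResolutionReport]:
    """Restrict a gene-level matrix to a signature's genes.

    Symbols are resolved against the matrix rows through the alias table
    (approved -> previous -> alias -> Entrez); rows come back in signature
    order restricted to matches, and the report records the dropout.  A
    signature with no resolvable gene on the platform is unusable and raises.
    """
    mapped, report = resolve_symbols(sig, aliases, matrix.index)
    if not mapped:
        raise ValueError(
            f"signature {sig.name!r}: none of {report.n_input} genes match "
            "the expression platform"
        )
    subset = matrix.loc[mapped]
    return subset, report
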