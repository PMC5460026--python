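"""Reading and writing of expression matrices, sample annotations, signature
gene lists and gene-symbol alias tables.

Conventions
-----------
An *expression matrix* is a :class:`pandas.DataFrame` of log2 intensities with
gene (or probe-set) identifiers on the index and sample identifiers on the
columns.  A *sample annotation* is a DataFrame indexed by ``sample_id`` with
columns ``patient_id`` and ``region`` (closed vocabulary, by default
CT / IF / LN for central tumour, invasive front and lymph-node metastasis).

Signature gene lists travel as :class:`SignatureGeneSet`; mapping of published
symbols onto the identifiers actually present on an array platform goes
through an HGNC-style :class:`AliasTable` and :func:`resolve_symbols`, which
accounts for gene dropout explicitly rather than silently.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_REGIONS = ("CT", "IF", "LN")

__all__ = [
    "DEFAULT_REGIONS",
    "SignatureGeneSet",
    "AliasTable",
    "ResolutionReport",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotation",
    "write_annotation",
    "read_gene_set",
    "read_alias_table",
    "resolve_symbols",
    "collapse_probes",
    "validate_expression_matrix",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class IntegrityError(ValueError):
    """Parsed content violates a structural invariant (e.g. duplicate ids)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SignatureGeneSet:
    """A named gene signature.

    ``subtype_of`` maps a gene symbol to the tuple of subtype labels it marks
    (a tuple because e.g. template classifiers may list a gene under more than
    one subtype).  Empty for plain prognostic signatures.
    """

    name: str
    genes: list[str]
    subtype_of: dict[str, tuple[str, ...]] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")
        unknown = set(self.subtype_of) - set(self.genes)
        if unknown:
            raise ValueError(
                f"subtype labels for genes not in signature {self.name!r}: "
                f"{sorted(unknown)}"
            )

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def subtypes(self) -> list[str]:
        """Subtype labels in order of first appearance along the gene list."""
        seen: list[str] = []
        for g in self.genes:
            for lab in self.subtype_of.get(g, ()):
                if lab not in seen:
                    seen.append(lab)
        return seen


@dataclass
class AliasTable:
    """HGNC-style symbol lookup: approved symbols, previous symbols, aliases
    and Entrez ids.  All symbol lookups are case-insensitive."""

    approved: list[str]
    previous: dict[str, list[str]]  # lower-cased previous symbol -> approved
    alias: dict[str, list[str]]  # lower-cased alias -> approved symbols
    entrez: dict[str, str]  # entrez id -> approved symbol

    _approved_lower: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.approved)) != len(self.approved):
            raise IntegrityError("duplicate approved symbols in alias table")
        self._approved_lower = {a.lower(): a for a in self.approved}

    def lookup_approved(self, symbol: str) -> str | None:
        return self._approved_lower.get(symbol.lower())

    def lookup_previous(self, symbol: str) -> list[str]:
        return self.previous.get(symbol.lower(), [])

    def lookup_alias(self, symbol: str) -> list[str]:
        return self.alias.get(symbol.lower(), [])

    def lookup_entrez(self, symbol: str) -> str | None:
        return self.entrez.get(symbol)

    @classmethod
    def empty(cls) -> "AliasTable":
        return cls(approved=[], previous={}, alias={}, entrez={})


@dataclass
class ResolutionReport:
    """Book-keeping for mapping signature symbols onto a platform.

    ``match_route`` records, per input symbol, which lookup succeeded:
    ``approved`` (symbol present on the platform as-is), ``previous``,
    ``alias``, ``entrez`` or ``unmatched``.  Dropout is a report, never a
    silent loss.
    """

    n_input: int
    n_matched: int
    n_dropped: int
    dropped_symbols: list[str]
    match_route: dict[str, str]

    def __post_init__(self) -> None:
        if self.n_input != self.n_matched + self.n_dropped:
            raise ValueError("resolution counts do not conserve")

    @property
    def dropout_fraction(self) -> float:
        return self.n_dropped / self.n_input if self.n_input else 0.0


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def validate_expression_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check the structural invariants of an expression matrix."""
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise IntegrityError(f"duplicate row identifiers: {dups[:5]}")
    if matrix.columns.has_duplicates:
        dups = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise IntegrityError(f"duplicate sample identifiers: {dups[:5]}")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ParseError("expression values are not numeric")
    if not np.all(np.isfinite(values)):
        bad = matrix.index[~np.isfinite(values).all(axis=1)][:5].tolist()
        raise IntegrityError(f"non-finite expression values in rows {bad}")
    return matrix


def read_expression_matrix(
    path: str | Path,
    format: str = "tsv",
    log2_transform: bool = False,
) -> pd.DataFrame:
    """Read a genes x samples expression matrix.

    Parameters
    ----------
    format
        ``"tsv"`` — first column row ids, header row sample ids; or
        ``"geo_series_matrix"`` — the table block of a GEO series-matrix
        file, delimited by the ``!series_matrix_table_begin`` /
        ``!series_matrix_table_end`` markers.
    log2_transform
        Apply ``log2(x + 1)`` for matrices deposited on linear scale.
        Values are otherwise assumed to be log2 intensities already.
    """
    path = Path(path)
    if format == "tsv":
        matrix = _read_tsv_matrix(path)
    elif format == "geo_series_matrix":
        matrix = _read_series_matrix(path)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    if log2_transform:
        matrix = np.log2(matrix + 1.0)
    return validate_expression_matrix(matrix)


def _read_tsv_matrix(path: Path) -> pd.DataFrame:
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise IntegrityError(f"{path}: duplicate sample header (line 1): {dups}")
    try:
        matrix = pd.read_csv(path, sep="\t", index_col=0,
                             float_precision="round_trip")
    except Exception as exc:  # pandas raises several distinct parse errors
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if matrix.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found (line 1)")
    non_numeric = [c for c in matrix.columns
                   if not np.issubdtype(matrix[c].dtype, np.number)]
    if non_numeric:
        raise ParseError(f"{path}: non-numeric cells in columns {non_numeric}")
    matrix.index = matrix.index.astype(str)
    matrix.columns = [str(c) for c in matrix.columns]
    return matrix


def _read_series_matrix(path: Path) -> pd.DataFrame:
    lines = path.read_text().splitlines()
    begin = end = None
    for i, line in enumerate(lines):
        if line.startswith("!series_matrix_table_begin"):
            begin = i
        elif line.startswith("!series_matrix_table_end"):
            end = i
    if begin is None or end is None or end <= begin + 1:
        raise ParseError(
            f"{path}: series-matrix table markers missing or empty "
            f"(begin={begin}, end={end})"
        )
    from io import StringIO

    block = "\n".join(lines[begin + 1 : end])
    matrix = pd.read_csv(StringIO(block), sep="\t", index_col=0,
                         float_precision="round_trip")
    matrix.index = [str(i).strip('"') for i in matrix.index]
    matrix.columns = [str(c).strip('"') for c in matrix.columns]
    non_numeric = [c for c in matrix.columns
                   if not np.issubdtype(matrix[c].dtype, np.number)]
    if non_numeric:
        raise ParseError(f"{path}: non-numeric cells in columns {non_numeric}")
    return matrix


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write the TSV dialect read by :func:`read_expression_matrix`.

    Floats are written at full precision so read(write(x)) round-trips
    bit-exactly.
    """
    validate_expression_matrix(matrix)
    # %.17g guarantees exact float64 round-trip through text
    matrix.to_csv(path, sep="\t", index_label="id", float_format="%.17g")


# ---------------------------------------------------------------------------
# sample annotations
# ---------------------------------------------------------------------------

def read_annotation(
    path: str | Path,
    regions: Sequence[str] = DEFAULT_REGIONS,
) -> pd.DataFrame:
    """Read a sample annotation CSV with columns sample_id,patient_id,region.

    Regions outside the declared vocabulary are rejected — a closed
    vocabulary prevents silent label typos from corrupting the per-region
    analyses.  Pass an extended ``regions`` sequence for other designs.
    """
    ann = pd.read_csv(path, dtype=str)
    required = {"sample_id", "patient_id", "region"}
    missing = required - set(ann.columns)
    if missing:
        raise ParseError(f"{path}: missing annotation columns {sorted(missing)}")
    if ann["sample_id"].duplicated().any():
        raise IntegrityError(f"{path}: duplicate sample_id entries")
    bad = set(ann["region"]) - set(regions)
    if bad:
        raise IntegrityError(
            f"{path}: unknown regions {sorted(bad)}; allowed: {list(regions)}"
        )
    return ann.set_index("sample_id")


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, index_label="sample_id")


def check_annotation_covers(matrix: pd.DataFrame, ann: pd.DataFrame) -> None:
    """Every sample in the matrix must carry exactly one annotation."""
    missing = [s for s in matrix.columns if s not in ann.index]
    if missing:
        raise IntegrityError(f"samples without annotation: {missing[:5]}")


# ---------------------------------------------------------------------------
# gene sets and alias tables
# ---------------------------------------------------------------------------

def read_gene_set(path: str | Path, name: str | None = None) -> SignatureGeneSet:
    """Read a signature gene list.

    Accepts either plain text (one symbol per line) or CSV with columns
    ``symbol[,subtype]``.  Duplicate symbols are collapsed with a logged
    warning count; a symbol listed under several subtypes keeps all labels.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ParseError(f"{path}: empty gene list")
    name = name or path.stem

    rows: list[tuple[str, str | None]] = []
    first = text.splitlines()[0]
    if "," in text or path.suffix.lower() == ".csv":
        frame = pd.read_csv(path, dtype=str)
        if "symbol" not in frame.columns:
            # headerless single/double column CSV
            frame = pd.read_csv(
                path, dtype=str, header=None,
                names=["symbol", "subtype"][: frame.shape[1]],
            )
        for _, r in frame.iterrows():
            sub = r.get("subtype")
            rows.append((str(r["symbol"]).strip(),
                         None if pd.isna(sub) else str(sub).strip()))
    else:
        del first
        for line in text.splitlines():
            sym = line.strip()
            if sym:
                rows.append((sym, None))

    genes: list[str] = []
    subtype_of: dict[str, list[str]] = {}
    n_dup = 0
    for sym, sub in rows:
        if sym in genes:
            n_dup += 1
        else:
            genes.append(sym)
        if sub is not None:
            labels = subtype_of.setdefault(sym, [])
            if sub not in labels:
                labels.append(sub)
    if n_dup:
        logger.warning("%s: collapsed %d duplicate symbols", path, n_dup)

    sig = SignatureGeneSet(
        name=name,
        genes=genes,
        subtype_of={g: tuple(v) for g, v in subtype_of.items()},
        provenance=str(path),
    )
    sig.n_duplicates = n_dup  # type: ignore[attr-defined]
    return sig


def read_alias_table(path: str | Path) -> AliasTable:
    """Read a TSV alias table with columns approved_symbol,
    previous_symbols, alias_symbols (pipe-separated lists) and entrez_id."""
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"approved_symbol", "previous_symbols", "alias_symbols"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing alias columns {sorted(missing)}")

    approved: list[str] = []
    previous: dict[str, list[str]] = {}
    alias: dict[str, list[str]] = {}
    entrez: dict[str, str] = {}
    for _, r in frame.iterrows():
        app = r["approved_symbol"].strip()
        approved.append(app)
        for sym in _split_pipe(r["previous_symbols"]):
            previous.setdefault(sym.lower(), []).append(app)
        for sym in _split_pipe(r["alias_symbols"]):
            alias.setdefault(sym.lower(), []).append(app)
        eid = str(r.get("entrez_id", "")).strip()
        if eid:
            entrez[eid] = app
    for table in (previous, alias):
        for key in table:
            table[key] = sorted(set(table[key]))
    return AliasTable(approved=approved, previous=previous,
                      alias=alias, entrez=entrez)


def _split_pipe(cell: str) -> list[str]:
    return [s.strip() for s in re.split(r"\|", cell) if s.strip()]


# ---------------------------------------------------------------------------
# symbol resolution and probe collapse
# ---------------------------------------------------------------------------

def resolve_symbols(
    genes: SignatureGeneSet | Sequence[str],
    aliases: AliasTable | None,
    matrix_genes: Iterable[str],
) -> tuple[list[str], ResolutionReport]:
    """Map signature symbols onto the identifiers present on a platform.

    Each input symbol is tried in a fixed order: exact (case-insensitive)
    match in the matrix -> previous-symbol lookup -> alias lookup -> Entrez
    id lookup.  When two approved symbols share a previous symbol or alias,
    the lexicographically smaller approved symbol wins and the tie is
    logged.  Unmatched symbols are reported as dropout, never raised.

    Returns the matched matrix identifiers (signature order, duplicates
    collapsed) and a :class:`ResolutionReport`.
    """
    symbols = list(genes.genes) if isinstance(genes, SignatureGeneSet) else list(genes)
    aliases = aliases or AliasTable.empty()
    matrix_lower = {}
    for g in matrix_genes:
        matrix_lower.setdefault(str(g).lower(), str(g))

    mapped: list[str] = []
    seen: set[str] = set()
    route: dict[str, str] = {}
    dropped: list[str] = []

    for sym in symbols:
        target, how = _resolve_one(sym, aliases, matrix_lower)
        route[sym] = how
        if target is None:
            dropped.append(sym)
        elif target not in seen:
            seen.add(target)
            mapped.append(target)

    report = ResolutionReport(
        n_input=len(symbols),
        n_matched=len(symbols) - len(dropped),
        n_dropped=len(dropped),
        dropped_symbols=dropped,
        match_route=route,
    )
    return mapped, report


def _resolve_one(
    sym: str,
    aliases: AliasTable,
    matrix_lower: Mapping[str, str],
) -> tuple[str | None, str]:
    hit = matrix_lower.get(sym.lower())
    if hit is not None:
        return hit, "approved"
    for candidates, how in (
        (aliases.lookup_previous(sym), "previous"),
        (aliases.lookup_alias(sym), "alias"),
    ):
        in_matrix = [a for a in candidates if a.lower() in matrix_lower]
        if in_matrix:
            if len(in_matrix) > 1:
                logger.info(
                    "symbol %s maps to several approved symbols %s via %s; "
                    "taking %s", sym, in_matrix, how, sorted(in_matrix)[0],
                )
            return matrix_lower[sorted(in_matrix)[0].lower()], how
    app = aliases.lookup_entrez(sym)
    if app is not None and app.lower() in matrix_lower:
        return matrix_lower[app.lower()], "entrez"
    return None, "unmatched"


def collapse_probes(
    matrix: pd.DataFrame,
    probe_to_gene: Mapping[str, str],
    keep_unmapped: bool = False,
    stat: str = "median",
) -> pd.DataFrame:
    """Collapse a probe-level matrix to one row per gene.

    The per-sample summary across a gene's probes is the median (robust to a
    stray probe; ``stat="mean"`` for the arithmetic alternative).  Output
    rows are sorted by gene identifier for determinism.  Probes absent from
    the mapping pass through unchanged when ``keep_unmapped`` is set and are
    dropped otherwise.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    missing = [p for p in probe_to_gene if p not in matrix.index]
    if missing:
        raise IntegrityError(f"mapped probes absent from matrix: {missing[:5]}")
    if stat not in ("median", "mean"):
        raise ValueError(f"unknown collapse statistic {stat!r}")

    mapped_rows = matrix.loc[list(probe_to_gene)]
    groups = mapped_rows.groupby(
        pd.Series(probe_to_gene, name="gene"), sort=True
    )
    collapsed = groups.median() if stat == "median" else groups.mean()

    if keep_unmapped:
        rest = matrix.loc[[p for p in matrix.index if p not in probe_to_gene]]
        collapsed = pd.concat([collapsed, rest])
    collapsed.index.name = matrix.index.name
    return collapsed
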