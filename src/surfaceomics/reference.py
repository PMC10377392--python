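"""Surfaceome annotation catalogue and drug-target mapping.

The catalogue is a SURFY-style table of predicted cell-surface proteins:
one row per gene symbol, flagged as surfaceome member or not, with an
Almen functional classification (main class and optional subclass) and
three glycosylation-motif presence flags (GlycoMine O-linked, C-linked,
and non-cytosolic N-linked at the N-X-S/T sequon). "Present" means the
gene has at least one predicted site of that motif class; the catalogue
stores the collapsed boolean, not site lists.

Gene identity is the symbol string, case-sensitive, after trimming
whitespace. Platform-specific identifier schemes are accommodated by a
column-name dialect on read, not by built-in ID translation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import pandas as pd

logger = logging.getLogger(__name__)

ALMEN_MAIN_CLASSES = (
    "Receptors",
    "Transporters",
    "Enzymes",
    "Miscellaneous",
    "Unclassified",
)

#: Canonical catalogue column order for TSV round-trips.
CATALOGUE_COLUMNS = (
    "symbol",
    "is_surfaceome",
    "almen_main",
    "almen_sub",
    "glycomineO_present",
    "glycomineC_present",
    "noncyt_nxst_present",
)

_TRUE_TOKENS = frozenset({"true", "yes", "y", "1", "t"})
_FALSE_TOKENS = frozenset({"false", "no", "n", "0", "f"})


class CatalogueFormatError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


class CatalogueValidationError(ValueError):
    """Parsed rows violate a catalogue invariant (e.g. duplicate symbols)."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One catalogue row.

    Non-surfaceome genes carry no annotation: class and motif fields are
    all ``None``. For surfaceome genes the three motif flags are always
    defined booleans.
    """

    symbol: str
    is_surfaceome: bool
    almen_main: Optional[str] = None
    almen_sub: Optional[str] = None
    glycomineO_present: Optional[bool] = None
    glycomineC_present: Optional[bool] = None
    noncyt_nxst_present: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.symbol:
            raise CatalogueValidationError("gene symbol must be non-empty")
        if self.almen_sub is not None and self.almen_main is None:
            raise CatalogueValidationError(
                f"{self.symbol}: almen_sub set without almen_main"
            )
        if self.almen_main is not None and self.almen_main not in ALMEN_MAIN_CLASSES:
            raise CatalogueValidationError(
                f"{self.symbol}: unknown Almen main class {self.almen_main!r}"
            )
        if self.is_surfaceome:
            for flag in (
                "glycomineO_present",
                "glycomineC_present",
                "noncyt_nxst_present",
            ):
                if getattr(self, flag) is None:
                    raise CatalogueValidationError(
                        f"{self.symbol}: surfaceome gene missing motif flag {flag}"
                    )
        else:
            if any(
                getattr(self, f) is not None
                for f in CATALOGUE_COLUMNS[2:]
            ):
                raise CatalogueValidationError(
                    f"{self.symbol}: non-surfaceome gene carries annotation fields"
                )

    @property
    def main_class_label(self) -> str:
        """Almen main class, with missing annotation bucketed as Unclassified."""
        return self.almen_main if self.almen_main is not None else "Unclassified"


class Catalogue:
    """An ordered, symbol-keyed collection of :class:`GeneAnnotation`."""

    def __init__(self, annotations: Iterable[GeneAnnotation]):
        self._by_symbol: dict[str, GeneAnnotation] = {}
        for ann in annotations:
            if ann.symbol in self._by_symbol:
                raise CatalogueValidationError(
                    f"duplicate symbol in catalogue: {ann.symbol}"
                )
            self._by_symbol[ann.symbol] = ann

    def __len__(self) -> int:
        return len(self._by_symbol)

    def __iter__(self) -> Iterator[GeneAnnotation]:
        return iter(self._by_symbol.values())

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def __getitem__(self, symbol: str) -> GeneAnnotation:
        return self._by_symbol[symbol]

    def get(self, symbol: str) -> Optional[GeneAnnotation]:
        return self._by_symbol.get(symbol)

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(self._by_symbol)

    @property
    def surfaceome_symbols(self) -> frozenset[str]:
        return frozenset(s for s, a in self._by_symbol.items() if a.is_surfaceome)

    def to_frame(self) -> pd.DataFrame:
        """Catalogue as a DataFrame in canonical column order."""
        rows = [
            {col: getattr(a, col) for col in CATALOGUE_COLUMNS} for a in self
        ]
        return pd.DataFrame(rows, columns=list(CATALOGUE_COLUMNS))


@dataclass(frozen=True)
class DrugTargetMap:
    """Mapping gene symbol -> deduplicated set of compound identifiers."""

    entries: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def compounds(self, symbol: str) -> frozenset[str]:
        return self.entries.get(symbol, frozenset())

    def n_compounds(self, symbol: str) -> int:
        return len(self.compounds(symbol))

    def __len__(self) -> int:
        return len(self.entries)


def _parse_bool(token: object, *, column: str, true_tokens: frozenset[str],
                false_tokens: frozenset[str]) -> Optional[bool]:
    if token is None or (isinstance(token, float) and pd.isna(token)):
        return None
    if isinstance(token, bool):
        return token
    text = str(token).strip().lower()
    if text == "":
        return None
    if text in true_tokens:
        return True
    if text in false_tokens:
        return False
    raise CatalogueFormatError(f"cannot parse boolean {token!r} in column {column!r}")


def read_catalogue(
    path: str | Path,
    dialect: Optional[Mapping[str, str]] = None,
    true_tokens: Iterable[str] = _TRUE_TOKENS,
    false_tokens: Iterable[str] = _FALSE_TOKENS,
) -> Catalogue:
    """Read a surfaceome annotation catalogue from TSV.

    Parameters
    ----------
    path:
        TSV file with a header row. Required columns: ``symbol`` and
        ``is_surfaceome``; annotation columns are optional (absent columns
        mean no annotation of that kind).
    dialect:
        Optional map from canonical column name to the actual column name
        in the file, e.g. ``{"symbol": "gene", "glycomineO_present": "O_motif"}``.
    true_tokens / false_tokens:
        Case-insensitive tokens accepted as boolean values, so catalogues
        using ``yes``/``no`` or ``1``/``0`` parse without preprocessing.

    Raises
    ------
    CatalogueFormatError
        A required column is missing (the error names it) or a boolean
        cell cannot be parsed.
    CatalogueValidationError
        Duplicate symbols (the error lists the offenders) or invariant
        violations in individual rows.
    """
    dialect = dict(dialect or {})
    true_tokens = frozenset(t.lower() for t in true_tokens)
    false_tokens = frozenset(t.lower() for t in false_tokens)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=[""])
    rename = {actual: canonical for canonical, actual in dialect.items()}
    df = df.rename(columns=rename)
    for required in ("symbol", "is_surfaceome"):
        if required not in df.columns:
            raise CatalogueFormatError(
                f"catalogue file {path} is missing required column {required!r}"
            )

    symbols = df["symbol"].astype(str).str.strip()
    duplicated = sorted(symbols[symbols.duplicated()].unique())
    if duplicated:
        raise CatalogueValidationError(
            f"duplicate symbols in catalogue: {', '.join(duplicated)}"
        )

    bool_cols = (
        "is_surfaceome",
        "glycomineO_present",
        "glycomineC_present",
        "noncyt_nxst_present",
    )
    annotations = []
    for idx, row in df.iterrows():
        parsed: dict[str, object] = {"symbol": symbols.loc[idx]}
        for col in bool_cols:
            if col in df.columns:
                parsed[col] = _parse_bool(
                    row[col], column=col,
                    true_tokens=true_tokens, false_tokens=false_tokens,
                )
        for col in ("almen_main", "almen_sub"):
            if col in df.columns and not pd.isna(row[col]):
                text = str(row[col]).strip()
                if text:
                    parsed[col] = text
        if parsed.get("is_surfaceome") is None:
            raise CatalogueFormatError(
                f"row {idx}: is_surfaceome must be a boolean, got {row['is_surfaceome']!r}"
            )
        annotations.append(GeneAnnotation(**parsed))  # type: ignore[arg-type]
    return Catalogue(annotations)


def write_catalogue(catalogue: Catalogue, path: str | Path) -> None:
    """Write a catalogue to TSV (booleans as true/false, absent as empty)."""
    df = catalogue.to_frame()
    for col in df.columns:
        if df[col].dtype == object or col != "symbol":
            df[col] = df[col].map(
                lambda v: "" if v is None or (isinstance(v, float) and pd.isna(v))
                else ("true" if v is True else "false" if v is False else str(v))
            )
    df.to_csv(path, sep="\t", index=False)


def read_drug_table(path: str | Path) -> DrugTargetMap:
    """Read a drug-target table (TSV columns ``symbol``, ``compound_id``).

    One target-compound pair per row; repeated pairs collapse to one.
    An empty file yields an empty map with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for required in ("symbol", "compound_id"):
        if required not in df.columns:
            raise CatalogueFormatError(
                f"drug table {path} is missing required column {required!r}"
            )
    if df.empty:
        logger.warning("drug table %s is empty", path)
        return DrugTargetMap({})
    entries = {
        str(sym).strip(): frozenset(str(c).strip() for c in group)
        for sym, group in df.groupby("symbol")["compound_id"]
    }
    return DrugTargetMap(entries)


def write_drug_table(drugs: DrugTargetMap, path: str | Path) -> None:
    rows = [
        {"symbol": sym, "compound_id": comp}
        for sym in sorted(drugs.entries)
        for comp in sorted(drugs.entries[sym])
    ]
    pd.DataFrame(rows, columns=["symbol", "compound_id"]).to_csv(
        path, sep="\t", index=False
    )


def annotation_join(
    symbols: Iterable[str], catalogue: Catalogue
) -> tuple[pd.DataFrame, int]:
    """Restrict the catalogue to a gene set.

    Returns the annotation table for symbols found in the catalogue
    (sorted by symbol) and the count of query symbols with no catalogue
    entry. Idempotent: joining the matched symbols again returns the
    same table.
    """
    query = {str(s).strip() for s in symbols}
    matched = sorted(query & catalogue.symbols)
    unmatched = len(query) - len(matched)
    if unmatched:
        logger.info("annotation_join: %d symbols not in catalogue", unmatched)
    rows = [
        {col: getattr(catalogue[s], col) for col in CATALOGUE_COLUMNS}
        for s in matched
    ]
    return pd.DataFrame(rows, columns=list(CATALOGUE_COLUMNS)), unmatched
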