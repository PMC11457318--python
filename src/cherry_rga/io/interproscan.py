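"""InterProScan annotation input.

Two dialects are supported: the standard InterProScan-5 tab-separated output
(one row per signature match) and "tabsheets", an xlsx workbook with one sheet
per member database (Pfam, SUPERFAMILY, Phobius, ProSiteProfiles, ...) as the
genome annotation was deposited.  Both parse to the same row type, so the rest
of the pipeline never sees the difference.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)


class Analysis(str, Enum):
    """InterProScan member database a hit came from."""

    PFAM = "PFAM"
    SUPERFAMILY = "SUPERFAMILY"
    PHOBIUS = "PHOBIUS"
    PROSITE_PROFILES = "PROSITE_PROFILES"
    OTHER = "OTHER"


# Spellings seen in InterProScan output / deposited sheet names.
_ANALYSIS_ALIASES: Mapping[str, Analysis] = {
    "pfam": Analysis.PFAM,
    "superfamily": Analysis.SUPERFAMILY,
    "ssf": Analysis.SUPERFAMILY,
    "phobius": Analysis.PHOBIUS,
    "prositeprofiles": Analysis.PROSITE_PROFILES,
    "prosite_profiles": Analysis.PROSITE_PROFILES,
    "prosite profiles": Analysis.PROSITE_PROFILES,
}


def parse_analysis(label: str) -> Analysis:
    """Map an analysis column value to the closed enum; unknown -> OTHER."""
    a = _ANALYSIS_ALIASES.get(label.strip().lower())
    if a is None:
        log.debug("unknown analysis source %r mapped to OTHER", label)
        return Analysis.OTHER
    return a


@dataclass(frozen=True)
class DomainHit:
    """One raw InterProScan annotation row.

    Coordinates are 1-based inclusive amino-acid positions, as InterProScan
    reports them.
    """

    transcript_id: str
    analysis: Analysis
    signature_id: str
    start: int
    end: int
    signature_desc: str = ""
    interpro_id: str = ""
    go_terms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValueError("transcript_id must be non-empty")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid coordinates {self.start}..{self.end} for {self.transcript_id}"
            )


class ParseError(ValueError):
    """Raised for malformed rows; message names the file and line number."""


# Standard InterProScan-5 TSV column indices (0-based).  Trailing columns
# (InterPro accession/description, GO, pathways) are optional in real output.
_IPS_MIN_COLS = 11
_IPS_MAX_COLS = 15
_COL_PROTEIN = 0
_COL_ANALYSIS = 3
_COL_SIGNATURE = 4
_COL_DESC = 5
_COL_START = 6
_COL_STOP = 7
_COL_INTERPRO = 11
_COL_GO = 13

_MISSING = {"", "-", "None", "NULL"}


def _clean(value: str) -> str:
    return "" if value.strip() in _MISSING else value.strip()


def _split_go(value: str) -> frozenset[str]:
    value = _clean(value)
    if not value:
        return frozenset()
    # InterProScan 5 separates terms with "|"; newer versions suffix the
    # evidence source in parentheses, which is stripped here.
    terms = (t.split("(")[0].strip() for t in value.split("|"))
    return frozenset(t for t in terms if t)


def _row_to_hit(row: Sequence[str], where: str) -> DomainHit:
    if not (_IPS_MIN_COLS <= len(row) <= _IPS_MAX_COLS):
        raise ParseError(
            f"{where}: expected {_IPS_MIN_COLS}-{_IPS_MAX_COLS} columns, got {len(row)}"
        )
    try:
        start = int(row[_COL_START])
        stop = int(row[_COL_STOP])
    except ValueError as exc:
        raise ParseError(f"{where}: non-integer coordinates {row[_COL_START]!r}/{row[_COL_STOP]!r}") from exc
    return DomainHit(
        transcript_id=row[_COL_PROTEIN].strip(),
        analysis=parse_analysis(row[_COL_ANALYSIS]),
        signature_id=row[_COL_SIGNATURE].strip(),
        signature_desc=_clean(row[_COL_DESC]),
        start=start,
        end=stop,
        interpro_id=_clean(row[_COL_INTERPRO]) if len(row) > _COL_INTERPRO else "",
        go_terms=_split_go(row[_COL_GO]) if len(row) > _COL_GO else frozenset(),
    )


@dataclass(frozen=True)
class TabsheetSpec:
    """Layout of a deposited workbook: which sheet holds which analysis.

    ``columns`` maps the logical fields onto 0-based sheet column indices; the
    default mirrors the InterProScan TSV column order.  The first ``skip_rows``
    rows of each sheet (headers) are ignored.
    """

    sheets: Mapping[str, Analysis]
    columns: Mapping[str, int] = field(
        default_factory=lambda: {
            "transcript_id": _COL_PROTEIN,
            "signature_id": _COL_SIGNATURE,
            "signature_desc": _COL_DESC,
            "start": _COL_START,
            "end": _COL_STOP,
            "interpro_id": _COL_INTERPRO,
            "go_terms": _COL_GO,
        }
    )
    skip_rows: int = 1


def read_interproscan(
    path: str | Path,
    dialect: str = "tsv",
    tabsheet_spec: TabsheetSpec | None = None,
) -> list[DomainHit]:
    """Read InterProScan annotation into a flat list of :class:`DomainHit`.

    Parameters
    ----------
    path
        TSV file (``dialect="tsv"``) or xlsx workbook (``dialect="tabsheets"``).
    dialect
        ``"tsv"`` for standard InterProScan-5 output, ``"tabsheets"`` for the
        per-analysis workbook; the latter requires ``tabsheet_spec``.
    """
    dialect = dialect.lower()
    if dialect == "tsv":
        return _read_tsv(Path(path))
    if dialect == "tabsheets":
        if tabsheet_spec is None:
            raise ValueError("tabsheets dialect requires a TabsheetSpec")
        return _read_tabsheets(Path(path), tabsheet_spec)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(path: Path) -> list[DomainHit]:
    hits: list[DomainHit] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            hits.append(_row_to_hit(row, f"{path.name}:{lineno}"))
    if not hits:
        log.warning("no annotation rows in %s", path)
    return hits


def _read_tabsheets(path: Path, spec: TabsheetSpec) -> list[DomainHit]:
    import openpyxl

    cols = spec.columns
    hits: list[DomainHit] = []
    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    try:
        for sheet_name, analysis in spec.sheets.items():
            if sheet_name not in wb.sheetnames:
                raise ParseError(f"{path.name}: missing sheet {sheet_name!r}")
            ws = wb[sheet_name]
            for rowno, row in enumerate(ws.iter_rows(values_only=True), start=1):
                if rowno <= spec.skip_rows:
                    continue
                cells = ["" if v is None else str(v) for v in row]
                if not any(c.strip() for c in cells):
                    continue
                where = f"{path.name}[{sheet_name}]:{rowno}"
                needed = max(cols["start"], cols["end"], cols["transcript_id"], cols["signature_id"])
                if len(cells) <= needed:
                    raise ParseError(f"{where}: expected >{needed} columns, got {len(cells)}")

                def cell(key: str) -> str:
                    i = cols[key]
                    return cells[i] if i < len(cells) else ""

                try:
                    start = int(float(cell("start")))
                    end = int(float(cell("end")))
                except ValueError as exc:
                    raise ParseError(f"{where}: non-integer coordinates") from exc
                hits.append(
                    DomainHit(
                        transcript_id=cell("transcript_id").strip(),
                        analysis=analysis,
                        signature_id=cell("signature_id").strip(),
                        signature_desc=_clean(cell("signature_desc")),
                        start=start,
                        end=end,
                        interpro_id=_clean(cell("interpro_id")),
                        go_terms=_split_go(cell("go_terms")),
                    )
                )
    finally:
        wb.close()
    return hits


def write_interproscan_tsv(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the standard InterProScan-5 TSV column layout.

    Score/status/date columns are emitted as placeholders ("-"); they carry no
    information the pipeline uses.
    """
    analysis_label = {
        Analysis.PFAM: "Pfam",
        Analysis.SUPERFAMILY: "SUPERFAMILY",
        Analysis.PHOBIUS: "Phobius",
        Analysis.PROSITE_PROFILES: "ProSiteProfiles",
        Analysis.OTHER: "Other",
    }
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            w.writerow(
                [
                    h.transcript_id,
                    "-",  # MD5
                    "-",  # sequence length
                    analysis_label[h.analysis],
                    h.signature_id,
                    h.signature_desc or "-",
                    h.start,
                    h.end,
                    "-",  # score
                    "T",
                    "-",  # date
                    h.interpro_id or "-",
                    "-",  # InterPro description
                    "|".join(sorted(h.go_terms)) or "-",
                ]
            )
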