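"""Reading and writing of the delimited data files used throughout the pipeline.

Three file shapes are supported, mirroring the layout commonly used to
distribute seasonal-calving herd data:

* **lactation data** (``s1`` schema) — one row per cow-lactation with the
  whole-lactation milk yield, breed, calf-gender sequence, days in milk and
  herd-year contemporary group;
* **pedigree data** (``s2`` schema) — animal / sire / dam identifier triples,
  unknown parents coded ``0`` by default;
* **test-day data** (``s3`` schema) — one row per cow holding her calving date
  and daily milk yields measured on herd-test dates, the dates being the
  column headings (``YYYY-MM-DD``).

Files are plain text, delimited by tab, comma or runs of whitespace (detected
automatically).  All readers validate eagerly and raise
:class:`ValidationError` naming the offending line.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "BREEDS",
    "LactationRecord",
    "PedigreeEntry",
    "TestDaySeries",
    "ValidationError",
    "read_lactation_data",
    "write_lactation_data",
    "read_pedigree",
    "write_pedigree",
    "read_testday_series",
    "write_testday_series",
    "write_results_table",
]

#: Canonical breed labels and the codes accepted on input.
BREEDS = {
    "HF": "HolsteinFriesian",
    "HOLSTEINFRIESIAN": "HolsteinFriesian",
    "HOLSTEIN_FRIESIAN": "HolsteinFriesian",
    "J": "Jersey",
    "JERSEY": "Jersey",
}

UNKNOWN_PARENT = "0"

_S1_HEADER = [
    "animal_id",
    "lactation_number",
    "milk_yield",
    "breed",
    "gender_sequence",
    "days_in_milk",
    "herd_year",
]
_S2_HEADER = ["animal_id", "sire_id", "dam_id"]

_SEQ_RE = re.compile(r"^[MF]+$")


class ValidationError(ValueError):
    """Raised when an input file violates the schema; names the line."""


@dataclass(frozen=True)
class LactationRecord:
    """One cow-lactation: the response and factors of the yield models."""

    animal_id: str
    lactation_number: int
    milk_yield: float
    breed: str
    gender_sequence: str
    days_in_milk: int
    herd_year: str

    def __post_init__(self) -> None:
        if self.lactation_number not in (1, 2, 3):
            raise ValidationError(
                f"lactation_number must be 1-3, got {self.lactation_number!r} "
                f"for animal {self.animal_id}"
            )
        if self.milk_yield < 0:
            raise ValidationError(
                f"negative milk yield {self.milk_yield} for animal {self.animal_id}"
            )
        if not _SEQ_RE.match(self.gender_sequence):
            raise ValidationError(
                f"gender sequence {self.gender_sequence!r} for animal "
                f"{self.animal_id} contains characters outside {{M,F}}"
            )
        if self.days_in_milk <= 0:
            raise ValidationError(
                f"days_in_milk must be positive, got {self.days_in_milk} "
                f"for animal {self.animal_id}"
            )


@dataclass(frozen=True)
class PedigreeEntry:
    """Animal/sire/dam triple; ``None`` parent means unknown."""

    animal_id: str
    sire_id: str | None = None
    dam_id: str | None = None


@dataclass
class TestDaySeries:
    """A cow's calving date and her dated herd-test daily yields."""

    animal_id: str
    calving_date: _dt.date
    tests: list[tuple[_dt.date, float]] = field(default_factory=list)

    def days_in_milk(self) -> list[int]:
        """Days from calving to each test, in test order."""
        return [(d - self.calving_date).days for d, _ in self.tests]

    def yields(self) -> list[float]:
        return [y for _, y in self.tests]


# ---------------------------------------------------------------------------
# low-level parsing helpers


def _split_line(line: str, delim: str | None) -> list[str]:
    if delim is None:
        return line.split()
    return [c.strip() for c in line.split(delim)]


def _detect_delimiter(first_line: str) -> str | None:
    """Tab wins over comma wins over generic whitespace."""
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return None


def _read_rows(path: str | Path) -> tuple[list[tuple[int, list[str]]], str | None]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[tuple[int, list[str]]] = []
    delim: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if delim is None and not rows:
                delim = _detect_delimiter(line)
            rows.append((lineno, _split_line(line.rstrip("\n"), delim)))
    return rows, delim


def _normalise_breed(code: str, lineno: int) -> str:
    key = code.strip().upper().replace("-", "_").replace(" ", "_")
    key_compact = key.replace("_", "")
    if key in BREEDS:
        return BREEDS[key]
    if key_compact in BREEDS:
        return BREEDS[key_compact]
    raise ValidationError(f"line {lineno}: unknown breed code {code!r}")


# ---------------------------------------------------------------------------
# lactation (s1) files


def read_lactation_data(
    path: str | Path, parity_window: int = 3
) -> list[LactationRecord]:
    """Read an s1-schema file into :class:`LactationRecord` objects.

    Parameters
    ----------
    path:
        Delimited text file with the seven s1 columns, with or without a
        header row.
    parity_window:
        Expected length of the calf-gender sequence (3 for lactation-1/2
        analyses, 4 when fourth-parity gender is carried).  Records whose
        sequence length differs are rejected.
    """
    if parity_window not in (3, 4):
        raise ValueError("parity_window must be 3 or 4")
    rows, _ = _read_rows(path)
    if not rows:
        return []
    if [c.lower() for c in rows[0][1]] == _S1_HEADER:
        rows = rows[1:]
    records: list[LactationRecord] = []
    seen: set[tuple[str, int]] = set()
    for lineno, cells in rows:
        if len(cells) != len(_S1_HEADER):
            raise ValidationError(
                f"line {lineno}: expected {len(_S1_HEADER)} columns, got {len(cells)}"
            )
        animal, lact_s, yield_s, breed_s, seq, dim_s, hy = cells
        try:
            lact = int(lact_s)
            milk = float(yield_s)
            dim = int(dim_s)
        except ValueError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from None
        seq = seq.strip().upper()
        if len(seq) != parity_window:
            raise ValidationError(
                f"line {lineno}: gender sequence {seq!r} has length {len(seq)}, "
                f"expected {parity_window}"
            )
        key = (animal, lact)
        if key in seen:
            raise ValidationError(
                f"line {lineno}: duplicate record for animal {animal} lactation {lact}"
            )
        seen.add(key)
        try:
            records.append(
                LactationRecord(
                    animal_id=animal,
                    lactation_number=lact,
                    milk_yield=milk,
                    breed=_normalise_breed(breed_s, lineno),
                    gender_sequence=seq,
                    days_in_milk=dim,
                    herd_year=hy,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from None
    return records


def write_lactation_data(
    records: Iterable[LactationRecord], path: str | Path
) -> None:
    """Write records as a tab-separated s1 file with a header row."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_S1_HEADER) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.animal_id,
                        str(r.lactation_number),
                        repr(r.milk_yield),
                        r.breed,
                        r.gender_sequence,
                        str(r.days_in_milk),
                        r.herd_year,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# pedigree (s2) files


def read_pedigree(
    path: str | Path, unknown: str = UNKNOWN_PARENT
) -> list[PedigreeEntry]:
    """Read an s2-schema pedigree file.

    ``unknown`` is the sentinel used for missing parents (``"0"`` by
    convention).  Cycles are detected here so downstream relationship code can
    assume an acyclic pedigree.
    """
    rows, _ = _read_rows(path)
    if not rows:
        return []
    if [c.lower() for c in rows[0][1]] == _S2_HEADER:
        rows = rows[1:]
    entries: list[PedigreeEntry] = []
    seen: set[str] = set()
    for lineno, cells in rows:
        if len(cells) != 3:
            raise ValidationError(
                f"line {lineno}: expected 3 columns, got {len(cells)}"
            )
        animal, sire, dam = cells
        if animal == unknown:
            raise ValidationError(f"line {lineno}: animal id equals unknown sentinel")
        if animal in seen:
            raise ValidationError(f"line {lineno}: duplicate pedigree entry {animal}")
        seen.add(animal)
        entries.append(
            PedigreeEntry(
                animal_id=animal,
                sire_id=None if sire == unknown else sire,
                dam_id=None if dam == unknown else dam,
            )
        )
    _check_acyclic(entries)
    return entries


def _check_acyclic(entries: Sequence[PedigreeEntry]) -> None:
    parents = {
        e.animal_id: [p for p in (e.sire_id, e.dam_id) if p is not None]
        for e in entries
    }
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {a: WHITE for a in parents}
    for start in parents:
        if colour[start] != WHITE:
            continue
        # iterative DFS towards ancestors
        stack: list[tuple[str, int]] = [(start, 0)]
        path: list[str] = []
        while stack:
            node, i = stack.pop()
            if i == 0:
                colour[node] = GREY
                path.append(node)
            plist = parents.get(node, [])
            if i < len(plist):
                stack.append((node, i + 1))
                nxt = plist[i]
                if nxt not in parents:
                    continue
                if colour[nxt] == GREY:
                    cycle = path[path.index(nxt):] + [nxt]
                    raise ValidationError(
                        "pedigree cycle detected: " + " -> ".join(cycle)
                    )
                if colour[nxt] == WHITE:
                    stack.append((nxt, 0))
            else:
                colour[node] = BLACK
                path.pop()


def write_pedigree(
    entries: Iterable[PedigreeEntry], path: str | Path, unknown: str = UNKNOWN_PARENT
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_S2_HEADER) + "\n")
        for e in entries:
            fh.write(
                f"{e.animal_id}\t{e.sire_id or unknown}\t{e.dam_id or unknown}\n"
            )


# ---------------------------------------------------------------------------
# test-day (s3) files


def _parse_date(token: str, lineno: int | str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(token)
    except ValueError:
        raise ValidationError(f"line {lineno}: bad date {token!r}") from None


def read_testday_series(path: str | Path) -> list[TestDaySeries]:
    """Read an s3-schema test-day file.

    The header row is ``animal_id calving_date <date> <date> ...`` with each
    subsequent column heading a herd-test date.  Empty cells or ``NA`` mean the
    cow was not tested (e.g. not yet calved, or already dried off) on that
    date; such tests are simply omitted from her series.
    """
    rows, _ = _read_rows(path)
    if not rows:
        return []
    header = rows[0][1]
    if len(header) < 3 or header[0].lower() != "animal_id":
        raise ValidationError("s3 file must start with an animal_id/calving_date header")
    test_dates = [_parse_date(tok, "header") for tok in header[2:]]
    if any(b <= a for a, b in zip(test_dates, test_dates[1:])):
        raise ValidationError("test-date columns must be strictly increasing")
    out: list[TestDaySeries] = []
    for lineno, cells in rows[1:]:
        if len(cells) != len(header):
            raise ValidationError(
                f"line {lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        animal = cells[0]
        calving = _parse_date(cells[1], lineno)
        tests: list[tuple[_dt.date, float]] = []
        for date, cell in zip(test_dates, cells[2:]):
            if cell in ("", "NA", ".", "na"):
                continue
            try:
                y = float(cell)
            except ValueError:
                raise ValidationError(
                    f"line {lineno}: bad yield {cell!r} for {animal} on {date}"
                ) from None
            if date <= calving:
                raise ValidationError(
                    f"line {lineno}: test on {date} not after calving "
                    f"({calving}) for animal {animal}"
                )
            tests.append((date, y))
        out.append(TestDaySeries(animal_id=animal, calving_date=calving, tests=tests))
    return out


def write_testday_series(
    series: Sequence[TestDaySeries], path: str | Path
) -> None:
    """Write series as a tab-separated s3 file (union of all test dates)."""
    all_dates = sorted({d for s in series for d, _ in s.tests})
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "\t".join(["animal_id", "calving_date"] + [d.isoformat() for d in all_dates])
            + "\n"
        )
        for s in series:
            by_date = {d: y for d, y in s.tests}
            cells = [s.animal_id, s.calving_date.isoformat()] + [
                repr(by_date[d]) if d in by_date else "NA" for d in all_dates
            ]
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# result tables


def write_results_table(rows: Iterable[dict], path: str | Path) -> None:
    """Write a tidy estimates table (term, level, estimate, se, t, p ...).

    Column order follows the first row; all rows must share its keys.
    """
    rows = list(rows)
    path = Path(path)
    with open(path, "w") as fh:
        if not rows:
            fh.write("")
            return
        cols = list(rows[0].keys())
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")
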