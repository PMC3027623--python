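"""Discrete morphological character matrices: data model and NEXUS/TNT I/O.

The matrix is the object every scoring operation works on: an ordered list of
taxa, an ordered list of character definitions (unordered/Fitch or
ordered/Wagner, with weights and active flags), and a rectangular grid of
cell state-sets.  Cells distinguish observed singleton states, missing data
(``?``), inapplicable/gap (``-``, scored like missing), and ambiguous
multi-state observations (polymorphic ``(..)`` / uncertain ``{..}`` — scored
identically, the tag is only bookkeeping).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "Taxon",
    "CharacterDef",
    "CellState",
    "CharacterMatrix",
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "matrix_summary",
    "DEFAULT_SYMBOLS",
]

DEFAULT_SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"

UNORDERED = "unordered"
ORDERED = "ordered"

OBSERVED = "observed"
MISSING = "missing"
GAP = "gap"
UNCERTAIN = "uncertain"
POLYMORPHIC = "polymorphic"

#: tags whose state set is the full character alphabet (free assignment)
_FULL_TAGS = (MISSING, GAP)
#: tags carrying an explicit multi-state observation
_AMBIG_TAGS = (UNCERTAIN, POLYMORPHIC)


class MatrixParseError(ValueError):
    """Raised when a matrix file violates its declared dialect."""


@dataclass(frozen=True)
class Taxon:
    name: str
    active: bool = True

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("taxon name must be non-empty")


@dataclass
class CharacterDef:
    """One column: 0-based ``index``, ``kind`` in {unordered, ordered}.

    ``n_states`` is the size of the observed state alphabet (missing cells
    range over it).  ``weight`` is 1 under equal weighting.
    """

    index: int
    kind: str = UNORDERED
    n_states: int = 2
    weight: float = 1.0
    active: bool = True

    def __post_init__(self) -> None:
        if self.kind not in (UNORDERED, ORDERED):
            raise ValueError(f"unknown character kind {self.kind!r}")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")


@dataclass(frozen=True)
class CellState:
    """A state set plus a provenance tag."""

    states: frozenset
    tag: str = OBSERVED

    def __post_init__(self) -> None:
        if self.tag == OBSERVED and len(self.states) != 1:
            raise ValueError("observed cell must hold exactly one state")
        if self.tag in _AMBIG_TAGS and len(self.states) < 2:
            raise ValueError("ambiguous cell must hold >= 2 states")
        if not self.states:
            raise ValueError("cell state set must be non-empty")

    @property
    def is_full_ambiguity(self) -> bool:
        return self.tag in _FULL_TAGS

    def mask(self) -> int:
        m = 0
        for s in self.states:
            m |= 1 << s
        return m

    def scoring_equal(self, other: "CellState") -> bool:
        """Equality up to the polymorphic/uncertain distinction."""
        if self.states != other.states:
            return False
        a, b = self.tag, other.tag
        if a == b:
            return True
        return a in _AMBIG_TAGS and b in _AMBIG_TAGS


def _cell(states: Iterable[int], tag: str) -> CellState:
    return CellState(frozenset(states), tag)


class CharacterMatrix:
    """Rectangular taxa x characters grid of :class:`CellState`."""

    def __init__(
        self,
        taxa: Sequence[Taxon],
        characters: Sequence[CharacterDef],
        cells: Sequence[Sequence[CellState]],
        symbols: str = DEFAULT_SYMBOLS,
    ):
        self.taxa = list(taxa)
        self.characters = list(characters)
        self.cells = [list(row) for row in cells]
        self.symbols = symbols
        self.validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_rows(
        cls,
        taxon_names: Sequence[str],
        rows: Sequence[str],
        ordered: Iterable[int] = (),
        symbols: str = DEFAULT_SYMBOLS,
    ) -> "CharacterMatrix":
        """Build a matrix from per-taxon cell strings like ``"0 1 (01) ?"``.

        Cells may be run together (``"01?"``) or whitespace separated; both
        ``(..)``/``{..}``/``[..]`` ambiguity spellings are accepted.
        """
        raw = [_scan_cells(r, symbols, bracket_poly=True) for r in rows]
        widths = {len(r) for r in raw}
        if len(widths) != 1:
            raise MatrixParseError("ragged rows in from_rows input")
        return _assemble(list(taxon_names), raw, set(ordered), symbols)

    # -- basic queries --------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    @property
    def taxon_names(self) -> list:
        return [t.name for t in self.taxa]

    def taxon_index(self, name: str) -> int:
        for i, t in enumerate(self.taxa):
            if t.name == name:
                return i
        raise KeyError(name)

    def cell(self, taxon: int, char: int) -> CellState:
        return self.cells[taxon][char]

    def active_taxa(self) -> list:
        return [i for i, t in enumerate(self.taxa) if t.active]

    def active_characters(self) -> list:
        return [j for j, c in enumerate(self.characters) if c.active]

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        names = self.taxon_names
        if len(set(names)) != len(names):
            raise ValueError("taxon names must be unique")
        if not self.characters:
            raise ValueError("matrix must have at least one character")
        if len(self.cells) != self.n_taxa:
            raise ValueError("cell grid row count != taxon count")
        for i, row in enumerate(self.cells):
            if len(row) != self.n_characters:
                raise ValueError(
                    f"cell grid not rectangular at taxon {names[i]!r}"
                )
        for j, c in enumerate(self.characters):
            alphabet = frozenset(range(c.n_states))
            for i, row in enumerate(self.cells):
                cell = row[j]
                if not cell.states <= alphabet:
                    raise ValueError(
                        f"state out of range for character {j} "
                        f"(taxon {names[i]!r})"
                    )
                if cell.is_full_ambiguity and cell.states != alphabet:
                    raise ValueError(
                        f"missing/gap cell must span the full alphabet "
                        f"(taxon {names[i]!r}, character {j})"
                    )

    # -- equality -------------------------------------------------------------

    def equals(self, other: "CharacterMatrix", strict_ambiguity: bool = True) -> bool:
        if self.taxon_names != other.taxon_names:
            return False
        if [(c.kind, c.n_states, c.active) for c in self.characters] != [
            (c.kind, c.n_states, c.active) for c in other.characters
        ]:
            return False
        for ra, rb in zip(self.cells, other.cells):
            for a, b in zip(ra, rb):
                if strict_ambiguity:
                    if a != b:
                        return False
                elif not a.scoring_equal(b):
                    return False
        return True

    def __eq__(self, other) -> bool:  # strict cell-for-cell equality
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return self.equals(other, strict_ambiguity=True)

    def __repr__(self) -> str:
        return f"<CharacterMatrix {self.n_taxa} taxa x {self.n_characters} characters>"


# ---------------------------------------------------------------------------
# cell-token scanning
# ---------------------------------------------------------------------------

_CLOSER = {"(": ")", "{": "}", "[": "]"}
_TAG_FOR_OPENER = {"(": POLYMORPHIC, "{": UNCERTAIN, "[": POLYMORPHIC}


def _scan_cells(text: str, symbols: str, bracket_poly: bool, offset: int = 0,
                full_text: str = None):
    """Scan a run of cell tokens.

    Returns a list of ``(kind, payload)`` where kind is 'obs', 'missing',
    'gap', or an ambiguity tag and payload is a state list.  When
    ``full_text`` is given, symbol errors report 1-based line numbers
    relative to it (``offset`` = position of ``text`` within it).
    """
    sym_index = {ch: i for i, ch in enumerate(symbols)}
    out = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "?":
            out.append((MISSING, []))
            i += 1
        elif ch == "-":
            out.append((GAP, []))
            i += 1
        elif ch in "({" or (bracket_poly and ch == "["):
            closer = _CLOSER[ch]
            j = text.find(closer, i + 1)
            if j < 0:
                raise MatrixParseError(f"unterminated {ch!r} state group")
            states = []
            for c in text[i + 1:j]:
                if c.isspace():
                    continue
                if c not in sym_index:
                    raise _symbol_error(c, full_text, offset + i)
                states.append(sym_index[c])
            if len(states) < 2:
                raise MatrixParseError("state group must list >= 2 states")
            out.append((_TAG_FOR_OPENER[ch], states))
            i = j + 1
        else:
            if ch not in sym_index:
                raise _symbol_error(ch, full_text, offset + i)
            out.append((OBSERVED, [sym_index[ch]]))
            i += 1
    return out


def _symbol_error(ch, full_text, pos) -> MatrixParseError:
    if full_text is not None:
        line = full_text.count("\n", 0, pos) + 1
        return MatrixParseError(f"unknown state symbol {ch!r} at line {line}")
    return MatrixParseError(f"unknown state symbol {ch!r}")


def _assemble(names, raw_rows, ordered_idx, symbols,
              weights=None, inactive_idx=()) -> CharacterMatrix:
    """Resolve raw cell tokens into a validated matrix.

    Alphabet size per character = (max observed state) + 1, minimum 2 so a
    fully-missing column still has a free binary assignment.
    """
    nchar = len(raw_rows[0]) if raw_rows else 0
    n_states = [1] * nchar
    for row in raw_rows:
        for j, (_tag, states) in enumerate(row):
            for s in states:
                n_states[j] = max(n_states[j], s + 1)
    n_states = [max(k, 2) for k in n_states]

    characters = []
    for j in range(nchar):
        characters.append(
            CharacterDef(
                index=j,
                kind=ORDERED if j in ordered_idx else UNORDERED,
                n_states=n_states[j],
                weight=1.0 if weights is None else weights[j],
                active=j not in set(inactive_idx),
            )
        )
    cells = []
    for row in raw_rows:
        out = []
        for j, (tag, states) in enumerate(row):
            if tag in _FULL_TAGS:
                out.append(_cell(range(n_states[j]), tag))
            else:
                out.append(_cell(states, tag))
        cells.append(out)
    return CharacterMatrix([Taxon(n) for n in names], characters, cells, symbols)


# ---------------------------------------------------------------------------
# NEXUS dialect
# ---------------------------------------------------------------------------

def _strip_nexus_comments(text: str) -> str:
    """Blank out ``[...]`` comments (nesting-aware), preserving offsets."""
    out = list(text)
    depth = 0
    for i, ch in enumerate(text):
        if ch == "[":
            depth += 1
        if depth > 0 and ch != "\n":
            out[i] = " "
        if ch == "]" and depth > 0:
            depth -= 1
    return "".join(out)


_RANGE_RE = re.compile(r"(\d+)\s*-\s*(\d+)|(\d+)")


def _parse_index_list(text: str, base: int) -> list:
    """Parse ``5 7-9``-style 1-based (NEXUS) index lists to 0-based."""
    idx = []
    for m in _RANGE_RE.finditer(text):
        if m.group(3) is not None:
            idx.append(int(m.group(3)) - base)
        else:
            idx.extend(range(int(m.group(1)) - base, int(m.group(2)) - base + 1))
    return idx


def _read_nexus(text: str) -> CharacterMatrix:
    stripped = _strip_nexus_comments(text)
    if not stripped.lstrip().lower().startswith("#nexus"):
        raise MatrixParseError("NEXUS file must start with #NEXUS")

    blocks = {}
    for m in re.finditer(r"begin\s+(\w+)\s*;(.*?)\bend\s*;", stripped,
                         re.IGNORECASE | re.DOTALL):
        blocks.setdefault(m.group(1).lower(), []).append((m.start(2), m.group(2)))

    data_blocks = blocks.get("data", []) + blocks.get("characters", [])
    if not data_blocks:
        raise MatrixParseError("no DATA or CHARACTERS block found")
    block_offset, body = data_blocks[0]

    dim = re.search(r"dimensions([^;]*);", body, re.IGNORECASE)
    if not dim:
        raise MatrixParseError("missing DIMENSIONS command")
    ntax_m = re.search(r"ntax\s*=\s*(\d+)", dim.group(1), re.IGNORECASE)
    nchar_m = re.search(r"nchar\s*=\s*(\d+)", dim.group(1), re.IGNORECASE)
    if not ntax_m or not nchar_m:
        raise MatrixParseError("DIMENSIONS must declare NTAX and NCHAR")
    ntax, nchar = int(ntax_m.group(1)), int(nchar_m.group(1))

    symbols = DEFAULT_SYMBOLS
    fmt = re.search(r"format([^;]*);", body, re.IGNORECASE)
    if fmt:
        sym_m = re.search(r'symbols\s*=\s*"([^"]*)"', fmt.group(1), re.IGNORECASE)
        if sym_m:
            declared = "".join(sym_m.group(1).split())
            if declared:
                symbols = declared

    mat = re.search(r"matrix\b(.*?);", body, re.IGNORECASE | re.DOTALL)
    if not mat:
        raise MatrixParseError("missing MATRIX command")
    mat_offset = block_offset + mat.start(1)
    names, raw_rows = _scan_matrix_rows(
        mat.group(1), nchar, ntax, symbols, bracket_poly=False,
        offset=mat_offset, full_text=stripped,
    )

    ordered_idx: set = set()
    for _off, abody in blocks.get("assumptions", []):
        for ts in re.finditer(r"typeset[^;=]*=\s*([^;]*);", abody, re.IGNORECASE):
            for part in ts.group(1).split(","):
                if ":" not in part:
                    continue
                kind, lst = part.split(":", 1)
                kind = kind.strip().lower()
                ids = _parse_index_list(lst, base=1)
                if kind.startswith("ord"):
                    ordered_idx.update(ids)
                elif kind.startswith("unord"):
                    ordered_idx.difference_update(ids)

    return _assemble(names, raw_rows, ordered_idx, symbols)


def _scan_matrix_rows(body, nchar, ntax, symbols, bracket_poly, offset, full_text):
    """Read taxon-name + nchar cells, repeated; tolerant of line wrapping."""
    names, rows = [], []
    i, n = 0, len(body)
    while True:
        while i < n and body[i].isspace():
            i += 1
        if i >= n:
            break
        # taxon name: quoted or bare token
        if body[i] == "'":
            j = body.find("'", i + 1)
            if j < 0:
                raise MatrixParseError("unterminated quoted taxon name")
            name = body[i + 1:j]
            i = j + 1
        else:
            j = i
            while j < n and not body[j].isspace():
                j += 1
            name = body[i:j]
            i = j
        cells = []
        while len(cells) < nchar:
            while i < n and body[i].isspace():
                i += 1
            if i >= n:
                raise MatrixParseError(
                    f"row for taxon {name!r} ends after {len(cells)} of "
                    f"{nchar} characters"
                )
            j = i
            while j < n and not body[j].isspace():
                j += 1
            cells.extend(
                _scan_cells(body[i:j], symbols, bracket_poly,
                            offset=offset + i, full_text=full_text)
            )
            i = j
        if len(cells) > nchar:
            raise MatrixParseError(
                f"row for taxon {name!r} has {len(cells)} cells, "
                f"expected {nchar}"
            )
        names.append(name)
        rows.append(cells)
    if len(names) != ntax:
        raise MatrixParseError(
            f"matrix declares {ntax} taxa but {len(names)} rows were read"
            + (f" (last row: {names[-1]!r})" if names else "")
        )
    return names, rows


def _write_nexus(m: CharacterMatrix) -> str:
    used = max((c.n_states for c in m.characters), default=2)
    symbols = m.symbols[:max(used, 2)]
    name_w = max(len(_quote_name(t.name)) for t in m.taxa)
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_characters};",
        f'    FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;',
        "    MATRIX",
    ]
    for t, row in zip(m.taxa, m.cells):
        cells = "".join(_format_cell(c, m.symbols, tnt=False) for c in row)
        lines.append(f"    {_quote_name(t.name):<{name_w}}  {cells}")
    lines.append("    ;")
    lines.append("END;")
    ordered = [c.index for c in m.characters if c.kind == ORDERED]
    if ordered:
        spans = _format_index_list(ordered, base=1)
        lines += [
            "BEGIN ASSUMPTIONS;",
            f"    TYPESET * default = ord: {spans};",
            "END;",
        ]
    return "\n".join(lines) + "\n"


def _quote_name(name: str) -> str:
    if re.fullmatch(r"[\w.]+", name):
        return name
    return "'" + name.replace("'", "''") + "'"


def _format_cell(c: CellState, symbols: str, tnt: bool) -> str:
    if c.tag == MISSING:
        return "?"
    if c.tag == GAP:
        return "-"
    body = "".join(symbols[s] for s in sorted(c.states))
    if c.tag == OBSERVED:
        return body
    if tnt:
        return "[" + body + "]"
    return ("(" + body + ")") if c.tag == POLYMORPHIC else ("{" + body + "}")


def _format_index_list(idx, base: int) -> str:
    idx = sorted(idx)
    spans = []
    start = prev = idx[0]
    for i in idx[1:] + [None]:
        if i is not None and i == prev + 1:
            prev = i
            continue
        spans.append(
            str(start + base) if start == prev
            else f"{start + base}-{prev + base}"
        )
        if i is not None:
            start = prev = i
    return " ".join(spans)


# ---------------------------------------------------------------------------
# TNT dialect
# ---------------------------------------------------------------------------

def _read_tnt(text: str) -> CharacterMatrix:
    m = re.search(r"xread\b", text, re.IGNORECASE)
    if not m:
        raise MatrixParseError("no xread command found")
    i = m.end()
    n = len(text)
    # optional quoted title
    while i < n and text[i].isspace():
        i += 1
    if i < n and text[i] == "'":
        j = text.find("'", i + 1)
        if j < 0:
            raise MatrixParseError("unterminated xread title")
        i = j + 1
    nums = []
    while len(nums) < 2:
        while i < n and text[i].isspace():
            i += 1
        j = i
        while j < n and text[j].isdigit():
            j += 1
        if j == i:
            raise MatrixParseError("xread must declare nchar and ntax")
        nums.append(int(text[i:j]))
        i = j
    nchar, ntax = nums  # TNT order: characters first
    end = text.find(";", i)
    if end < 0:
        raise MatrixParseError("xread block not terminated by ';'")
    names, raw_rows = _scan_matrix_rows(
        text[i:end], nchar, ntax, DEFAULT_SYMBOLS, bracket_poly=True,
        offset=i, full_text=text,
    )

    ordered_idx: set = set()
    inactive: set = set()
    for cc in re.finditer(r"\bcc(?:ode)?\s+([^;]*);", text, re.IGNORECASE):
        _apply_ccode(cc.group(1), nchar, ordered_idx, inactive)
    return _assemble(names, raw_rows, ordered_idx, DEFAULT_SYMBOLS,
                     inactive_idx=inactive)


_CC_TOKEN = re.compile(r"[+\-\[\]]|(\d+)(?:\.(\d+))?")


def _apply_ccode(body: str, nchar: int, ordered_idx: set, inactive: set) -> None:
    """TNT ccode: ``+`` ordered, ``-`` unordered, ``[``/``]`` active toggles;
    indices 0-based, ``a.b`` ranges."""
    mode_ordered = None
    mode_active = None
    for m in _CC_TOKEN.finditer(body):
        tok = m.group(0)
        if tok == "+":
            mode_ordered = True
        elif tok == "-":
            mode_ordered = False
        elif tok == "[":
            mode_active = True
        elif tok == "]":
            mode_active = False
        else:
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            for j in range(lo, min(hi, nchar - 1) + 1):
                if mode_ordered is True:
                    ordered_idx.add(j)
                elif mode_ordered is False:
                    ordered_idx.discard(j)
                if mode_active is True:
                    inactive.discard(j)
                elif mode_active is False:
                    inactive.add(j)


def _write_tnt(m: CharacterMatrix) -> str:
    name_w = max(len(t.name.replace(" ", "_")) for t in m.taxa)
    lines = [
        "xread",
        f"{m.n_characters} {m.n_taxa}",
    ]
    for t, row in zip(m.taxa, m.cells):
        cells = "".join(_format_cell(c, m.symbols, tnt=True) for c in row)
        lines.append(f"{t.name.replace(' ', '_'):<{name_w}}  {cells}")
    lines.append(";")
    ordered = [c.index for c in m.characters if c.kind == ORDERED]
    cc_parts = []
    if ordered:
        cc_parts.append("+ " + _format_tnt_ranges(ordered))
    inactive = [c.index for c in m.characters if not c.active]
    if inactive:
        cc_parts.append("] " + _format_tnt_ranges(inactive))
    if cc_parts:
        lines.append("ccode " + " ".join(cc_parts) + ";")
    lines.append("proc /;")
    return "\n".join(lines) + "\n"


def _format_tnt_ranges(idx) -> str:
    idx = sorted(idx)
    spans = []
    start = prev = idx[0]
    for i in idx[1:] + [None]:
        if i is not None and i == prev + 1:
            prev = i
            continue
        spans.append(str(start) if start == prev else f"{start}.{prev}")
        if i is not None:
            start = prev = i
    return " ".join(spans)


# ---------------------------------------------------------------------------
# public I/O entry points
# ---------------------------------------------------------------------------

def read_matrix(source, dialect: str = "auto") -> CharacterMatrix:
    """Parse a character matrix from a string, text stream, or path.

    ``dialect`` is ``"nexus"``, ``"tnt"``, or ``"auto"`` (sniffed from the
    leading ``#NEXUS`` header vs an ``xread`` command).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text and not text.lstrip().lower().startswith(("#nexus", "xread")):
            with open(text) as fh:
                text = fh.read()
    if dialect == "auto":
        if text.lstrip().lower().startswith("#nexus"):
            dialect = "nexus"
        elif re.search(r"\bxread\b", text, re.IGNORECASE):
            dialect = "tnt"
        else:
            raise MatrixParseError("cannot sniff dialect (no #NEXUS or xread)")
    if dialect == "nexus":
        return _read_nexus(text)
    if dialect == "tnt":
        return _read_tnt(text)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_matrix(matrix: CharacterMatrix, dialect: str = "nexus") -> str:
    """Serialize a matrix; ``read_matrix(write_matrix(m))`` reproduces ``m``
    cell-for-cell (TNT spells both ambiguity tags as ``[..]``)."""
    matrix.validate()
    if dialect == "nexus":
        return _write_nexus(matrix)
    if dialect == "tnt":
        return _write_tnt(matrix)
    raise ValueError(f"unknown dialect {dialect!r}")


def matrix_summary(matrix: CharacterMatrix) -> dict:
    """Counts and percentages a reader checks first after a parse."""
    n_cells = matrix.n_taxa * matrix.n_characters
    n_missing = sum(
        1 for row in matrix.cells for c in row if c.tag in _FULL_TAGS
    )
    n_poly = sum(
        1 for row in matrix.cells for c in row if c.tag in _AMBIG_TAGS
    )
    kinds = {UNORDERED: 0, ORDERED: 0}
    for c in matrix.characters:
        kinds[c.kind] += 1
    return {
        "n_taxa": matrix.n_taxa,
        "n_characters": matrix.n_characters,
        "pct_missing": 100.0 * n_missing / n_cells if n_cells else 0.0,
        "pct_polymorphic": 100.0 * n_poly / n_cells if n_cells else 0.0,
        "n_unordered": kinds[UNORDERED],
        "n_ordered": kinds[ORDERED],
        "n_inactive_characters": sum(1 for c in matrix.characters if not c.active),
    }
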