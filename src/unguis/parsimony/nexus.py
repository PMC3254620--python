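"""NEXUS reading and writing for morphological character matrices.

Supports the subset of NEXUS used for discrete morphological data: a
DATA or CHARACTERS block (DIMENSIONS, FORMAT with SYMBOLS/MISSING/GAP,
MATRIX with ``(01)`` / ``{01}`` ambiguity codings and ``?`` missing cells),
an ASSUMPTIONS block with TYPESET ``ord``/``unord`` assignments, and an
OUTGROUP command (accepted in an ASSUMPTIONS, SETS or PAUP block).  Taxon
names may be quoted or use underscores for spaces.  ``parse_nexus`` and
``write_nexus`` round-trip losslessly on alphabet-normalized matrices
(each character's alphabet = 0..max observed state; see
``CharacterMatrix.normalized``, which never changes lengths or fit
statistics); parse errors carry 1-based line numbers.
"""

from __future__ import annotations

import re

from ..errors import NexusParseError
from .matrix import Cell, Character, CharacterMatrix

_DEFAULT_SYMBOLS = "0123456789"


def _strip_comments(text: str) -> str:
    """Remove [...] comments, preserving newlines so line numbers survive."""
    out = []
    depth = 0
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]" and depth:
            depth -= 1
        elif depth == 0:
            out.append(ch)
        elif ch == "\n":
            out.append(ch)
    return "".join(out)


def _commands(text: str):
    """Yield (command_text, start_line) split on ';' outside quotes."""
    buf: list[str] = []
    start_line = 1
    line = 1
    in_quote = False
    for ch in text:
        if ch == "\n":
            line += 1
        if ch == "'":
            in_quote = not in_quote
        if ch == ";" and not in_quote:
            cmd = "".join(buf).strip()
            if cmd:
                yield cmd, start_line
            buf = []
            start_line = line
        else:
            if not buf and not ch.isspace():
                start_line = line
            buf.append(ch)
    tail = "".join(buf).strip()
    if tail and tail != "#NEXUS":
        yield tail, start_line


def _parse_name(token: str) -> str:
    token = token.strip()
    if token.startswith("'") and token.endswith("'"):
        return token[1:-1].replace("''", "'")
    return token.replace("_", " ")


def _parse_ranges(spec: str, nchar: int, line: int) -> list[int]:
    """'1-24 26 28-30' -> 1-based character ids; '.' means nchar."""
    ids: list[int] = []
    for part in spec.replace(",", " ").split():
        if "-" in part and not part.startswith("-"):
            a, b = part.split("-", 1)
            lo = int(a)
            hi = nchar if b.strip() == "." else int(b)
            ids.extend(range(lo, hi + 1))
        else:
            ids.append(nchar if part == "." else int(part))
    for i in ids:
        if not 1 <= i <= nchar:
            raise NexusParseError(f"character id {i} out of range 1..{nchar}", line)
    return ids


def _parse_matrix_rows(body: str, start_line: int, ntax: int, nchar: int,
                       symbols: str, missing: str, gap: str):
    """Parse MATRIX rows -> (taxa, cells).  Interleaved format supported."""
    sym_to_state = {s: i for i, s in enumerate(symbols)}
    taxa: list[str] = []
    rows: dict[str, list[Cell]] = {}
    line_no = start_line
    for raw in body.splitlines():
        line_no += 1
        stripped = raw.strip()
        if not stripped:
            continue
        m = re.match(r"\s*('(?:[^']|'')+'|\S+)\s+(.*)$", raw)
        if not m:
            raise NexusParseError("cannot parse matrix row", line_no)
        name = _parse_name(m.group(1))
        if name not in rows:
            taxa.append(name)
            rows[name] = []
        cells = rows[name]
        seq = m.group(2)
        i = 0
        while i < len(seq):
            ch = seq[i]
            if ch.isspace():
                i += 1
                continue
            if ch in "({":
                closer = ")" if ch == "(" else "}"
                j = seq.find(closer, i)
                if j < 0:
                    raise NexusParseError("unterminated ambiguity group", line_no)
                states = frozenset(
                    sym_to_state[c] for c in seq[i + 1:j] if c in sym_to_state
                )
                if len(states) < 2:
                    raise NexusParseError(
                        f"ambiguity group {seq[i:j + 1]!r} needs >= 2 states", line_no
                    )
                cells.append(states)
                i = j + 1
            elif ch == missing or ch == gap:
                cells.append(None)
                i += 1
            elif ch in sym_to_state:
                cells.append(frozenset([sym_to_state[ch]]))
                i += 1
            else:
                raise NexusParseError(f"undeclared symbol {ch!r}", line_no)
    if len(taxa) != ntax:
        raise NexusParseError(
            f"MATRIX has {len(taxa)} taxa, DIMENSIONS declared {ntax}", start_line
        )
    for name in taxa:
        if len(rows[name]) != nchar:
            raise NexusParseError(
                f"taxon {name!r} has {len(rows[name])} cells, expected {nchar}",
                start_line,
            )
    return taxa, [rows[name] for name in taxa]


def parse_nexus(text: str) -> CharacterMatrix:
    """Parse a NEXUS DATA/CHARACTERS (+ ASSUMPTIONS) document."""
    clean = _strip_comments(text)
    if "#NEXUS" not in clean.split("\n", 1)[0].upper():
        raise NexusParseError("missing #NEXUS header", 1)
    ntax = nchar = None
    symbols = _DEFAULT_SYMBOLS
    missing, gap = "?", "-"
    taxa: list[str] = []
    cells: list[list[Cell]] = []
    ordered_ids: set[int] = set()
    unordered_ids: set[int] = set()
    outgroup = ""
    labels: dict[int, str] = {}
    saw_matrix = False
    for cmd, line in _commands(clean):
        head = cmd.split(None, 1)[0].upper()
        rest = cmd.split(None, 1)[1] if " " in cmd or "\n" in cmd else ""
        if head == "DIMENSIONS":
            m = re.search(r"NTAX\s*=\s*(\d+)", cmd, re.I)
            ntax = int(m.group(1)) if m else ntax
            m = re.search(r"NCHAR\s*=\s*(\d+)", cmd, re.I)
            nchar = int(m.group(1)) if m else nchar
        elif head == "FORMAT":
            m = re.search(r"SYMBOLS\s*=\s*\"([^\"]*)\"", cmd, re.I)
            if m:
                symbols = m.group(1).replace(" ", "")
            m = re.search(r"MISSING\s*=\s*(\S)", cmd, re.I)
            if m:
                missing = m.group(1)
            m = re.search(r"GAP\s*=\s*(\S)", cmd, re.I)
            if m:
                gap = m.group(1)
        elif head == "CHARLABELS":
            for i, tok in enumerate(rest.split(), start=1):
                labels[i] = _parse_name(tok)
        elif head == "MATRIX":
            if ntax is None or nchar is None:
                raise NexusParseError("MATRIX before DIMENSIONS", line)
            first_nl = cmd.find("\n")
            if first_nl < 0:
                raise NexusParseError("empty MATRIX", line)
            taxa, cells = _parse_matrix_rows(
                cmd[first_nl + 1:], line, ntax, nchar, symbols, missing, gap
            )
            saw_matrix = True
        elif head == "TYPESET":
            if nchar is None:
                raise NexusParseError("TYPESET before DIMENSIONS", line)
            body = cmd.split("=", 1)
            if len(body) != 2:
                raise NexusParseError("malformed TYPESET", line)
            for clause in body[1].split(","):
                if ":" not in clause:
                    continue
                kind, spec = clause.split(":", 1)
                ids = _parse_ranges(spec, nchar, line)
                kind = kind.strip().lower()
                if kind in ("ord", "wagner"):
                    ordered_ids.update(ids)
                    unordered_ids.difference_update(ids)
                elif kind in ("unord", "fitch"):
                    unordered_ids.update(ids)
                    ordered_ids.difference_update(ids)
        elif head == "OUTGROUP":
            outgroup = _parse_name(rest.strip())
    if not saw_matrix:
        raise NexusParseError("no MATRIX command found")
    characters = []
    for cid in range(1, nchar + 1):
        observed = set()
        for row in cells:
            c = row[cid - 1]
            if c is not None:
                observed |= set(c)
        # alphabet: contiguous 0..max observed state (at least binary)
        top = max(observed) if observed else 1
        states = tuple(range(0, max(top, 1) + 1))
        ordered = cid in ordered_ids or (cid not in unordered_ids and False)
        if cid in ordered_ids:
            ordered = True
        elif cid in unordered_ids:
            ordered = False
        else:
            ordered = False  # NEXUS default type is unordered
        characters.append(
            Character(id=cid, label=labels.get(cid, ""), states=states, ordered=ordered)
        )
    if outgroup and outgroup not in taxa:
        raise NexusParseError(f"outgroup {outgroup!r} not among matrix taxa")
    return CharacterMatrix(
        taxa=tuple(taxa), characters=characters, cells=cells, outgroup=outgroup
    )


def _format_name(name: str) -> str:
    if re.search(r"[\s(){}\[\];,'=]", name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _format_cell(c: Cell) -> str:
    if c is None:
        return "?"
    if len(c) == 1:
        return _DEFAULT_SYMBOLS[next(iter(c))]
    return "(" + "".join(_DEFAULT_SYMBOLS[s] for s in sorted(c)) + ")"


def _format_ids(ids: list[int]) -> str:
    """Compact 1-based id list: [1,2,3,5] -> '1-3 5'."""
    ids = sorted(ids)
    parts = []
    i = 0
    while i < len(ids):
        j = i
        while j + 1 < len(ids) and ids[j + 1] == ids[j] + 1:
            j += 1
        parts.append(str(ids[i]) if i == j else f"{ids[i]}-{ids[j]}")
        i = j + 1
    return " ".join(parts)


def write_nexus(matrix: CharacterMatrix) -> str:
    """Serialise a matrix; ``parse_nexus(write_nexus(m)) == m``."""
    max_state = max(max(c.states) for c in matrix.characters)
    symbols = " ".join(_DEFAULT_SYMBOLS[: max_state + 1])
    name_w = max(len(_format_name(t)) for t in matrix.taxa) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={matrix.ntax} NCHAR={matrix.nchar};",
        f'    FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;',
    ]
    if all(c.label for c in matrix.characters):
        labs = " ".join(_format_name(c.label) for c in matrix.characters)
        lines.append(f"    CHARLABELS {labs};")
    lines.append("    MATRIX")
    for name, row in zip(matrix.taxa, matrix.cells):
        body = "".join(_format_cell(c) for c in row)
        lines.append(f"        {_format_name(name):<{name_w}}{body}")
    lines.append("    ;")
    lines.append("END;")
    ordered = [c.id for c in matrix.characters if c.ordered]
    unordered = [c.id for c in matrix.characters if not c.ordered]
    lines.append("BEGIN ASSUMPTIONS;")
    clauses = []
    if ordered:
        clauses.append(f"ord: {_format_ids(ordered)}")
    if unordered:
        clauses.append(f"unord: {_format_ids(unordered)}")
    lines.append(f"    TYPESET * default = {', '.join(clauses)};")
    if matrix.outgroup:
        lines.append(f"    OUTGROUP {_format_name(matrix.outgroup)};")
    lines.append("END;")
    return "\n".join(lines) + "\n"
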