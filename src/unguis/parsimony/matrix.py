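"""Discrete morphological character matrices with ordered states.

Cells are either a single state, an ambiguity/polymorphism set of two or
more states, or missing.  Each character carries its own small integer state
alphabet and an ``ordered`` flag: ordered (Wagner) characters cost ``|i - j|``
per change, unordered (Fitch) characters cost 1 for any change.  A matrix
designates exactly one outgroup taxon, used to root trees for display.

A :class:`MatrixEdit` is a declarative, auditable revision of a matrix
(recoding a character's state scheme, changing individual cells, appending
characters or taxa) so that published corrections to an existing matrix can
be shipped as data and replayed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from ..errors import MatrixEditError

#: A cell: frozenset of states (singleton = resolved; >=2 = ambiguity or
#: polymorphism) or None for missing ("?").
Cell = frozenset | None

MISSING: Cell = None


@dataclass(frozen=True)
class Character:
    """One column: id (1-based), label, state alphabet, ordered flag."""

    id: int
    label: str = ""
    states: tuple[int, ...] = (0, 1)
    ordered: bool = True

    def __post_init__(self):
        if len(self.states) < 2:
            raise ValueError(f"character {self.id}: needs >= 2 states")
        if any(s < 0 for s in self.states):
            raise ValueError(f"character {self.id}: states must be non-negative")


def cell(*states: int) -> Cell:
    """Convenience constructor: ``cell()`` is missing, ``cell(0, 1)`` ambiguity."""
    return frozenset(states) if states else MISSING


@dataclass
class CharacterMatrix:
    """Taxa x characters matrix of discrete morphological states."""

    taxa: tuple[str, ...]
    characters: list[Character]
    cells: list[list[Cell]]  # rows follow ``taxa``, columns follow ``characters``
    outgroup: str = ""

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        if len(self.cells) != len(self.taxa):
            raise ValueError("row count does not match taxon count")
        for row in self.cells:
            if len(row) != len(self.characters):
                raise ValueError("column count does not match character count")
        if self.outgroup and self.outgroup not in self.taxa:
            raise ValueError(f"outgroup {self.outgroup!r} is not among the taxa")
        self.validate_states()

    # -- basic access ------------------------------------------------------
    @property
    def ntax(self) -> int:
        return len(self.taxa)

    @property
    def nchar(self) -> int:
        return len(self.characters)

    def taxon_index(self, name: str) -> int:
        try:
            return self.taxa.index(name)
        except ValueError:
            raise KeyError(f"unknown taxon {name!r}") from None

    def char_index(self, char_id: int) -> int:
        for j, c in enumerate(self.characters):
            if c.id == char_id:
                return j
        raise KeyError(f"unknown character id {char_id}")

    def column(self, char_id: int) -> list[Cell]:
        j = self.char_index(char_id)
        return [row[j] for row in self.cells]

    def get(self, taxon: str, char_id: int) -> Cell:
        return self.cells[self.taxon_index(taxon)][self.char_index(char_id)]

    def validate_states(self) -> None:
        for i, row in enumerate(self.cells):
            for j, c in enumerate(row):
                if c is None:
                    continue
                alphabet = set(self.characters[j].states)
                if not c or not set(c) <= alphabet:
                    raise ValueError(
                        f"taxon {self.taxa[i]!r}, character {self.characters[j].id}: "
                        f"cell {sorted(c)} outside alphabet {sorted(alphabet)}"
                    )

    def normalized(self) -> "CharacterMatrix":
        """Copy with each alphabet trimmed to ``0..max observed state``.

        NEXUS declares one global symbol list, so per-character alphabets
        are recovered from the observed states on parsing; a matrix equals
        its parse-write round trip exactly when it is in this form.
        Trimming never changes tree lengths or fit statistics: states
        beyond the observed range are never optimal ancestral assignments.
        """
        out = self.copy()
        for j, char in enumerate(out.characters):
            observed = set()
            for row in out.cells:
                if row[j] is not None:
                    observed |= set(row[j])
            top = max(observed) if observed else 1
            out.characters[j] = replace(char, states=tuple(range(max(top, 1) + 1)))
        return out

    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(
            taxa=self.taxa,
            characters=list(self.characters),
            cells=[list(row) for row in self.cells],
            outgroup=self.outgroup,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CharacterMatrix)
            and self.taxa == other.taxa
            and self.characters == other.characters
            and self.cells == other.cells
            and self.outgroup == other.outgroup
        )


@dataclass(frozen=True)
class MatrixEdit:
    """One auditable revision of a character matrix.

    operation is one of:

    ``recode-character``
        Replace a character's state alphabet and/or ordered flag; existing
        cells may be remapped through ``state_map`` (old state -> new state).
    ``change-cell``
        Set the cell of (``taxon``, ``character``) to ``value`` (a state
        int, an iterable of states, or None for missing).
    ``add-character``
        Append a new :class:`Character`; ``values`` maps taxon -> cell
        (unlisted taxa become missing).
    ``add-taxon``
        Append a taxon; ``values`` maps character id -> cell.
    ``set-ordering``
        Flip a character's ordered flag.
    """

    operation: str
    character: int | None = None
    taxon: str | None = None
    value: object = None
    new_character: Character | None = None
    values: dict | None = None
    states: tuple[int, ...] | None = None
    ordered: bool | None = None
    state_map: dict | None = None
    note: str = ""


def _as_cell(value) -> Cell:
    if value is None:
        return MISSING
    if isinstance(value, (int,)):
        return frozenset([value])
    return frozenset(int(v) for v in value)


def apply_edits(
    matrix: CharacterMatrix, edits: list[MatrixEdit]
) -> tuple[CharacterMatrix, list[str]]:
    """Apply edits in order; returns the new matrix and an audit log."""
    m = matrix.copy()
    log: list[str] = []
    for e in edits:
        try:
            if e.operation == "change-cell":
                i, j = m.taxon_index(e.taxon), m.char_index(e.character)
                old = m.cells[i][j]
                m.cells[i][j] = _as_cell(e.value)
                log.append(
                    f"change-cell char {e.character} {e.taxon}: "
                    f"{_fmt(old)} -> {_fmt(m.cells[i][j])}  [{e.note}]"
                )
            elif e.operation == "recode-character":
                j = m.char_index(e.character)
                c = m.characters[j]
                new_states = e.states if e.states is not None else c.states
                new_ordered = e.ordered if e.ordered is not None else c.ordered
                m.characters[j] = replace(c, states=tuple(new_states), ordered=new_ordered)
                if e.state_map:
                    for row in m.cells:
                        if row[j] is not None:
                            row[j] = frozenset(e.state_map.get(s, s) for s in row[j])
                log.append(
                    f"recode-character {e.character}: states={tuple(new_states)} "
                    f"ordered={new_ordered}  [{e.note}]"
                )
            elif e.operation == "add-character":
                if e.new_character is None:
                    raise MatrixEditError("add-character needs new_character")
                if any(c.id == e.new_character.id for c in m.characters):
                    raise MatrixEditError(
                        f"character id {e.new_character.id} already present"
                    )
                m.characters.append(e.new_character)
                vals = e.values or {}
                for name in vals:
                    m.taxon_index(name)  # raises KeyError for unknown taxa
                for i, name in enumerate(m.taxa):
                    m.cells[i].append(_as_cell(vals.get(name)))
                log.append(
                    f"add-character {e.new_character.id} ({e.new_character.label})"
                    f"  [{e.note}]"
                )
            elif e.operation == "add-taxon":
                if e.taxon in m.taxa:
                    raise MatrixEditError(f"taxon {e.taxon!r} already present")
                vals = e.values or {}
                row = [_as_cell(vals.get(c.id)) for c in m.characters]
                m.taxa = m.taxa + (e.taxon,)
                m.cells.append(row)
                log.append(f"add-taxon {e.taxon}  [{e.note}]")
            elif e.operation == "set-ordering":
                j = m.char_index(e.character)
                m.characters[j] = replace(m.characters[j], ordered=bool(e.ordered))
                log.append(f"set-ordering {e.character}: ordered={e.ordered}  [{e.note}]")
            else:
                raise MatrixEditError(f"unknown operation {e.operation!r}")
        except KeyError as exc:
            raise MatrixEditError(str(exc)) from exc
    m.validate_states()
    # re-run the dataclass consistency checks
    return CharacterMatrix(m.taxa, m.characters, m.cells, m.outgroup), log


def _fmt(c: Cell) -> str:
    if c is None:
        return "?"
    return "/".join(str(s) for s in sorted(c))
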