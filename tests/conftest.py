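import numpy as np
import pytest

from unguis.parsimony.matrix import Character, CharacterMatrix
from unguis.records import PhalanxRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(columns, ordered=None, taxa=None, outgroup_first=True):
    """Small matrix from state-string columns, e.g. ['0012', '01?2'].

    '?' is missing; '(ab)' is not supported here — pass frozensets via
    ``cells`` directly for ambiguity.
    """
    ntax = len(columns[0])
    taxa = taxa or tuple(chr(ord("A") + i) for i in range(ntax))
    chars = []
    cells = [[] for _ in range(ntax)]
    for j, col in enumerate(columns):
        states = sorted({int(ch) for ch in col if ch != "?"} | {0, 1})
        top = max(states)
        ordflag = True if ordered is None else ordered[j]
        chars.append(
            Character(id=j + 1, states=tuple(range(top + 1)), ordered=ordflag)
        )
        for i, ch in enumerate(col):
            cells[i].append(None if ch == "?" else frozenset([int(ch)]))
    return CharacterMatrix(
        taxa=tuple(taxa), characters=chars, cells=cells,
        outgroup=taxa[0] if outgroup_first else "",
    )


def phalanx_record(specimen_id="spec", scale=1.0, group="unassigned", **over):
    """A valid phalanx record with nail-like default proportions."""
    vals = dict(BH=2.3, BW=3.2, TPL=6.5, SH14=1.75, SW14=1.76,
                SH34=1.40, SW34=1.76, VFL=5.3, FSA=77.0)
    vals.update(over)
    for k in ("BH", "BW", "TPL", "SH14", "SW14", "SH34", "SW34", "VFL"):
        vals[k] *= scale
    return PhalanxRecord(specimen_id=specimen_id, unguis_group=group, **vals)
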