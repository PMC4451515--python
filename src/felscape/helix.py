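"""Nearest-neighbor (Turner-rule) stability of an RNA helix.

The free energy of a contiguous stem is assembled from tabulated dG37
stacking terms, with two conventions:

* ``mode="duplex"`` -- an isolated duplex: initiation + stacks + terminal
  AU/GU end penalties (the standard duplex formation free energy);
* ``mode="stem"`` -- the stacking contribution alone, the natural score for
  a stem embedded inside a larger fold (no initiation, no end penalties).

The bundled parameter table carries the Watson-Crick dG37 stacks shared by
the 1999 and 2004 Turner rule sets; a different table file can be supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import ConfigError, FelscapeError

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}
AU_LIKE_ENDS = {("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}


@dataclass
class HelixSpec:
    """A contiguous RNA stem inside a (1-based) sequence.

    ``pairs`` run 5'->3' on the first strand: consecutive pairs must be
    (i + 1, j - 1), and every pair must be Watson-Crick or GU wobble.
    """

    sequence: str
    pairs: list[tuple[int, int]]
    numbering_start: int = 1

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("T", "U")
        self.pairs = [tuple(int(x) for x in p) for p in self.pairs]
        n = len(self.sequence)
        for i, j in self.pairs:
            if not (0 <= i - self.numbering_start < n
                    and 0 <= j - self.numbering_start < n):
                raise ConfigError(f"pair {(i, j)} outside the sequence")
        for (i1, j1), (i2, j2) in zip(self.pairs[:-1], self.pairs[1:]):
            if (i2, j2) != (i1 + 1, j1 - 1):
                raise ConfigError(
                    f"stem not contiguous between pairs {(i1, j1)} and {(i2, j2)}"
                )
        for k, (i, j) in enumerate(self.pairs):
            bases = (self.base(i), self.base(j))
            if bases not in WC_PAIRS | WOBBLE_PAIRS:
                raise ConfigError(
                    f"position {i}:{j} ({bases[0]}-{bases[1]}) is not a "
                    f"Watson-Crick or GU wobble pair"
                )

    def base(self, index: int) -> str:
        return self.sequence[index - self.numbering_start]

    def reversed(self) -> "HelixSpec":
        """The same duplex read from the other strand's 5' end."""
        pairs = [(j, i) for (i, j) in reversed(self.pairs)]
        spec = object.__new__(HelixSpec)
        spec.sequence = self.sequence
        spec.pairs = pairs
        spec.numbering_start = self.numbering_start
        return spec


def _canonical_stack(top: str, bottom: str) -> str:
    """Rotation-invariant key: 5'XY/3'ZW is the same stack as 5'WZ/3'YX."""
    a = f"{top}/{bottom}"
    b = f"{bottom[::-1]}/{top[::-1]}"
    return min(a, b)


def load_parameter_table(source: str | Path = "turner2004") -> dict:
    """Load a nearest-neighbor table: stacks, initiation, end penalties."""
    if isinstance(source, str) and not source.endswith(".tsv"):
        ref = resources.files("felscape.data") / f"{source}_dg37.tsv"
        text = ref.read_text()
        name = source
    else:
        text = Path(source).read_text()
        name = str(source)
    stacks: dict[str, float] = {}
    init = 0.0
    terminal_au = 0.0
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("kind\t"):
            continue
        kind, key, value = line.split("\t")
        if kind == "stack":
            top, bottom = key.split("/")
            stacks[_canonical_stack(top, bottom)] = float(value)
        elif kind == "init":
            init = float(value)
        elif kind == "penalty" and key == "terminal_au":
            terminal_au = float(value)
    if not stacks:
        raise FelscapeError(f"parameter table {name!r} has no stack entries")
    return {"name": name, "stacks": stacks, "init": init,
            "terminal_au": terminal_au}


def helix_stability(
    helix: HelixSpec,
    table: dict | str | Path = "turner2004",
    mode: str = "duplex",
) -> float:
    """dG37 of the stem in kcal/mol (deterministic table lookups).

    Raises a ConfigError for non-pairable bases (via HelixSpec) and a
    FelscapeError naming the stack when a table entry is missing.
    """
    if not isinstance(table, dict):
        table = load_parameter_table(table)
    if len(helix.pairs) < 2:
        raise ConfigError("a stem needs >= 2 base pairs")
    if mode not in ("duplex", "stem"):
        raise ConfigError(f"unknown mode {mode!r}")

    total = 0.0
    for (i1, j1), (i2, j2) in zip(helix.pairs[:-1], helix.pairs[1:]):
        top = helix.base(i1) + helix.base(i2)
        bottom = helix.base(j1) + helix.base(j2)
        key = _canonical_stack(top, bottom)
        if key not in table["stacks"]:
            raise FelscapeError(
                f"no table entry for stack 5'{top}3'/3'{bottom}5' "
                f"in {table['name']!r}"
            )
        total += table["stacks"][key]

    if mode == "duplex":
        total += table["init"]
        for i, j in (helix.pairs[0], helix.pairs[-1]):
            if (helix.base(i), helix.base(j)) in AU_LIKE_ENDS:
                total += table["terminal_au"]
    return total


def load_reference_pseudoknot() -> dict:
    """The bundled synthetic reconstruction of the T2 gene 32 pseudoknot.

    Returns the sequence and the H1/H2 HelixSpec objects.  The stems were
    rebuilt from published nucleotide identities (see the data file header);
    they are a stand-in for the undistributed experimental coordinates.
    """
    ref = resources.files("felscape.data") / "pseudoknot_2tpk_synthetic.json"
    payload = json.loads(ref.read_text())
    seq = payload["sequence"]
    start = payload.get("numbering_start", 1)
    return {
        "sequence": seq,
        "helices": {
            name: HelixSpec(seq, pairs, numbering_start=start)
            for name, pairs in payload["helices"].items()
        },
    }
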