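"""N-glycan composition parsing, classification, and sequon motif checks.

Glycan compositions are expressed as monosaccharide count strings of the
form ``N#H#F#S#`` — counts of HexNAc (N), hexose (H), fucose (F) and
sialic acid / NeuAc (S).  Compositions are classified into five
mutually exclusive structural groups commonly used in glycoproteomics:

* ``mannose`` — high-mannose glycans: the chitobiose core (two HexNAc)
  plus five or more mannoses, no fucose or sialic acid,
* ``sialylated`` — at least one NeuAc, no fucose,
* ``fucosylated`` — at least one fucose, no NeuAc,
* ``fucosylated_sialylated`` — both terminal decorations present,
* ``complex_hybrid`` — everything else (branched complex or hybrid
  glycans without terminal fucose/NeuAc, and paucimannose structures).

Terminal decorations take precedence over backbone typing: a branched
complex glycan bearing sialic acid (e.g. N4H5F0S2) is typed
``sialylated``, not ``complex_hybrid``.

N-glycosylation occurs at asparagine within the sequon N-X-S/T/C where
X is any residue except proline; :func:`classify_sequon` reads that
motif off a peptide (or protein) sequence.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

__all__ = [
    "GlycanComposition",
    "GlycanParseError",
    "GLYCAN_TYPES",
    "SEQUON_MOTIFS",
    "parse_composition",
    "classify_glycan",
    "classify_sequon",
]

#: The five-class partition of glycan compositions, in display order.
GLYCAN_TYPES = (
    "mannose",
    "sialylated",
    "fucosylated",
    "complex_hybrid",
    "fucosylated_sialylated",
)

#: Sequon motif labels. ``invalid`` marks X==P or a non-S/T/C +2 residue.
SEQUON_MOTIFS = ("NXT", "NXS", "NXC", "invalid")


class GlycanParseError(ValueError):
    """Raised when a composition string does not match the N#H#F#S# grammar."""


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide counts of an N-glycan.

    Attributes
    ----------
    hexnac, hex, fuc, neuac : int
        Non-negative counts of HexNAc, hexose, fucose and NeuAc.
    """

    hexnac: int
    hex: int
    fuc: int
    neuac: int

    def __post_init__(self) -> None:
        for name in ("hexnac", "hex", "fuc", "neuac"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def raw(self) -> str:
        """Canonical string form, uppercase in N, H, F, S order."""
        return f"N{self.hexnac}H{self.hex}F{self.fuc}S{self.neuac}"

    def __str__(self) -> str:
        return self.raw


# One letter code -> field; accepts the tokens in any order, each exactly once.
_TOKEN_RE = re.compile(r"([NHFS])(\d+)", re.IGNORECASE)
_FIELD_BY_CODE = {"N": "hexnac", "H": "hex", "F": "fuc", "S": "neuac"}


def parse_composition(s: str, strict: bool = False) -> GlycanComposition:
    """Parse a composition string like ``"N4H5F0S2"``.

    Letter/count tokens may appear in any order and any case; the
    canonical form (``raw``) is always uppercase ``N…H…F…S…``.  All four
    monosaccharides must be present (write explicit zeros).

    Parameters
    ----------
    strict
        When true, warn about compositions that are implausible as
        N-glycans (fewer than two HexNAc, which cannot form the
        chitobiose core).

    Raises
    ------
    GlycanParseError
        If the string is malformed or a monosaccharide field is missing
        or duplicated.
    """
    if not isinstance(s, str):
        raise GlycanParseError(f"composition must be a string, got {type(s).__name__}")
    text = s.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if m.start() != pos:
            bad = text[pos : m.start()]
            raise GlycanParseError(f"unexpected token {bad!r} in composition {s!r}")
        code = m.group(1).upper()
        field = _FIELD_BY_CODE[code]
        if field in counts:
            raise GlycanParseError(f"duplicated field {code!r} in composition {s!r}")
        counts[field] = int(m.group(2))
        pos = m.end()
    if pos != len(text):
        raise GlycanParseError(f"unexpected token {text[pos:]!r} in composition {s!r}")
    missing = [c for c, f in _FIELD_BY_CODE.items() if f not in counts]
    if missing:
        raise GlycanParseError(
            f"composition {s!r} is missing field(s) {', '.join(missing)}"
        )
    comp = GlycanComposition(**counts)
    if strict and comp.hexnac < 2:
        warnings.warn(
            f"composition {comp.raw} has fewer than 2 HexNAc and is not a "
            "plausible N-glycan",
            stacklevel=2,
        )
    return comp


def classify_glycan(c: GlycanComposition | str, mannose_min_hex: int = 5) -> str:
    """Assign a composition to one of the five glycan classes.

    Terminal features decide first: any fucose and any NeuAc together
    give ``fucosylated_sialylated``; one of the two alone gives
    ``fucosylated`` or ``sialylated``.  Undecorated compositions with
    exactly two HexNAc and at least ``mannose_min_hex`` hexoses are
    ``mannose`` (high-mannose, Man5 and larger by default); everything
    else is ``complex_hybrid``.
    """
    if isinstance(c, str):
        c = parse_composition(c)
    if c.fuc > 0 and c.neuac > 0:
        return "fucosylated_sialylated"
    if c.neuac > 0:
        return "sialylated"
    if c.fuc > 0:
        return "fucosylated"
    if c.hexnac == 2 and c.hex >= mannose_min_hex:
        return "mannose"
    return "complex_hybrid"


def classify_sequon(
    peptide: str,
    site_index: int,
    context: str | None = None,
) -> str:
    """Classify the N-glycosylation sequon at ``peptide[site_index]``.

    The sequon is N-X-S/T/C with X != proline, read from the site
    residue and the two following ones.  When the +2 residue falls
    outside the peptide (C-terminal site of a tryptic peptide), the
    missing residues can be supplied via ``context``: the downstream
    protein sequence starting at the residue after the peptide.  If the
    motif cannot be resolved, the label is ``invalid``.

    Raises
    ------
    ValueError
        If the site residue is not asparagine.
    """
    if not (0 <= site_index < len(peptide)):
        raise ValueError(f"site_index {site_index} outside peptide of length {len(peptide)}")
    if peptide[site_index].upper() != "N":
        raise ValueError(
            f"residue at site_index {site_index} is {peptide[site_index]!r}, expected 'N'"
        )
    extended = peptide.upper() + (context or "").upper()
    if site_index + 2 >= len(extended):
        return "invalid"
    x = extended[site_index + 1]
    third = extended[site_index + 2]
    if x == "P" or third not in "STC":
        return "invalid"
    return {"T": "NXT", "S": "NXS", "C": "NXC"}[third]
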