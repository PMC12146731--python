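"""Electronic-continuum-correction edits to molecular-topology text files.

The ECC treats electronic polarization as a mean-field dielectric by scaling
the partial charges of ions and of the charge-bearing terminal atoms of
charged residue side chains by a factor f_ECC (0.87 here).  Two companion
edits accompany the scaling: the calcium Lennard-Jones sigma is enlarged to
keep the Ca-water-oxygen distance at its experimental 0.242 nm, and
pair-specific override (NBFIX-style) records for Ca/Na with oxygens are
removed, since they are an alternative route to the same correction and
would double-count it.

The supported grammar is a restricted GROMACS-style topology: ``[ section ]``
headers, whitespace-separated records, ``;`` comments.  Unedited lines are
preserved byte-for-byte; edited lines are rewritten token-by-token so that
only the changed field differs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "TopologyDocument",
    "ScalingRule",
    "DEFAULT_TERMINAL_ATOMS",
    "scale_charges",
    "patch_ca_sigma",
    "strip_nbfix",
]

#: Charge-bearing terminal atoms per charged residue (editable convention:
#: carboxylate group for Asp/Glu, ammonium for Lys, guanidinium for Arg,
#: imidazolium nitrogens/hydrogens for protonated His).
DEFAULT_TERMINAL_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("CB", "HB1", "HB2", "CG", "OD1", "OD2"),
    "GLU": ("CG", "HG1", "HG2", "CD", "OE1", "OE2"),
    "LYS": ("CE", "HE1", "HE2", "NZ", "HZ1", "HZ2", "HZ3"),
    "ARG": ("CD", "HD1", "HD2", "NE", "HE", "CZ",
            "NH1", "HH11", "HH12", "NH2", "HH21", "HH22"),
    "HSP": ("CD2", "HD2", "CE1", "HE1", "ND1", "HD1", "NE2", "HE2"),
}

_SECTION_RE = re.compile(r"^\s*\[\s*(\S+)\s*\]\s*(;.*)?$")


@dataclass
class _Line:
    text: str
    section: str | None


@dataclass
class TopologyDocument:
    """A topology file held line-by-line with section annotations.

    Only lines explicitly edited are rewritten; everything else, including
    comments and unknown sections, round-trips byte-identically.
    """

    lines: list[_Line] = field(default_factory=list)

    @classmethod
    def parse(cls, text: str) -> "TopologyDocument":
        doc = cls()
        section = None
        for raw in text.splitlines(keepends=False):
            m = _SECTION_RE.match(raw)
            if m:
                section = m.group(1).lower()
            doc.lines.append(_Line(raw, section))
        doc._trailing_newline = text.endswith("\n") or not text
        return doc

    @classmethod
    def read(cls, path) -> "TopologyDocument":
        with open(path) as fh:
            return cls.parse(fh.read())

    def serialize(self) -> str:
        out = "\n".join(ln.text for ln in self.lines)
        if getattr(self, "_trailing_newline", True):
            out += "\n"
        return out

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.serialize())

    def copy(self) -> "TopologyDocument":
        doc = TopologyDocument([_Line(ln.text, ln.section) for ln in self.lines])
        doc._trailing_newline = getattr(self, "_trailing_newline", True)
        return doc

    # -- record access -----------------------------------------------------

    def _data_lines(self, section: str):
        for i, ln in enumerate(self.lines):
            if ln.section != section:
                continue
            stripped = ln.text.split(";", 1)[0].strip()
            if not stripped or _SECTION_RE.match(ln.text):
                continue
            yield i, stripped.split()

    def atom_records(self):
        """(line index, fields) for [ atoms ] records.

        GROMACS layout: nr type resnr residue atom cgnr charge [mass ...].
        """
        yield from self._data_lines("atoms")

    def total_charge(self) -> float:
        return sum(float(f[6]) for _, f in self.atom_records() if len(f) > 6)


@dataclass(frozen=True)
class ScalingRule:
    """What to scale: ion species plus charged-residue terminal atoms."""

    f_ecc: float
    ion_species: tuple[str, ...] = ("CA", "CAL", "NA", "SOD", "CLA", "CL", "BA")
    terminal_atoms: dict = field(
        default_factory=lambda: dict(DEFAULT_TERMINAL_ATOMS)
    )

    def __post_init__(self) -> None:
        if not 0 < self.f_ecc <= 1:
            raise ValueError("f_ecc must be in (0, 1]")
        object.__setattr__(
            self, "ion_species", tuple(s.upper() for s in self.ion_species)
        )

    def selects(self, residue: str, atom: str) -> bool:
        # ions are matched by residue name only: protein alpha carbons are
        # also named "CA" and must never be caught by the calcium selection
        residue = residue.upper()
        atom = atom.upper()
        if residue in self.ion_species:
            return True
        return atom in tuple(
            a.upper() for a in self.terminal_atoms.get(residue, ())
        )


def _replace_token(text: str, token_index: int, new_token: str) -> str:
    """Replace the n-th whitespace-separated token, preserving spacing."""
    parts = re.split(r"(\s+)", text)
    tok = -1
    for i, p in enumerate(parts):
        if p and not p.isspace():
            tok += 1
            if tok == token_index:
                parts[i] = new_token
                return "".join(parts)
    raise IndexError(f"line has no token {token_index}: {text!r}")


def _format_charge(value: float) -> str:
    s = f"{value:.6f}".rstrip("0")
    return s + "0" if s.endswith(".") else s


def scale_charges(
    doc: TopologyDocument, rule: ScalingRule
) -> tuple[TopologyDocument, list[tuple[str, float, float]]]:
    """Multiply the charges of selected atoms by f_ECC.

    Returns a new document plus an audit list of (atom name, old charge,
    new charge).  Raises if the selection matches nothing, which would
    otherwise be a silent no-op.
    """
    out = doc.copy()
    audit: list[tuple[str, float, float]] = []
    for i, f in out.atom_records():
        if len(f) < 7:
            continue
        residue, atom = f[3], f[4]
        if not rule.selects(residue, atom):
            continue
        old = float(f[6])
        new = old * rule.f_ecc
        # charge is token 6 of the record, which may not start at column 0 --
        # count tokens over the pre-comment part of the line
        line = out.lines[i]
        code, sep, comment = line.text.partition(";")
        line.text = _replace_token(code, 6, _format_charge(new)) + sep + comment
        audit.append((atom, old, new))
    if not audit:
        raise ValueError("scaling rule selected no atoms (refusing silent no-op)")
    return out, audit


def patch_ca_sigma(
    doc: TopologyDocument,
    new_sigma_nm: float = 0.27,
    ca_names: tuple[str, ...] = ("CA", "CAL"),
) -> tuple[TopologyDocument, list[tuple[str, float, float]]]:
    """Replace the calcium Lennard-Jones sigma in [ atomtypes ].

    GROMACS atomtypes layout: name [at.num] mass charge ptype sigma epsilon;
    sigma is the second-to-last numeric field.  Epsilon is untouched.
    Returns (document, audit of (name, old sigma, new sigma)).
    """
    out = doc.copy()
    audit: list[tuple[str, float, float]] = []
    for i, f in out._data_lines("atomtypes"):
        if f[0].upper() not in tuple(n.upper() for n in ca_names):
            continue
        sigma_tok = len(f) - 2
        old = float(f[sigma_tok])
        line = out.lines[i]
        code, sep, comment = line.text.partition(";")
        line.text = _replace_token(code, sigma_tok, repr(new_sigma_nm)) + sep + comment
        audit.append((f[0], old, new_sigma_nm))
    if not audit:
        raise LookupError(f"no atomtypes record found for {ca_names}")
    return out, audit


def strip_nbfix(
    doc: TopologyDocument, species: tuple[str, ...] = ("CA", "CAL", "NA", "SOD")
) -> tuple[TopologyDocument, int]:
    """Delete pair-override records involving the listed species.

    Pair overrides live in [ nonbond_params ] (the GROMACS rendering of
    NBFIX).  Records whose either atom type matches a listed species are
    removed; everything else, including overrides between other species,
    stays.  Returns (document, number of removals); zero removals is legal.
    """
    wanted = tuple(s.upper() for s in species)
    out = doc.copy()
    drop = []
    for i, f in out._data_lines("nonbond_params"):
        if len(f) >= 2 and (f[0].upper() in wanted or f[1].upper() in wanted):
            drop.append(i)
    for i in reversed(drop):
        del out.lines[i]
    return out, len(drop)
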