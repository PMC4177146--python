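"""XYZ read/write and preliminary MDL MOL (V2000) reading.

XYZ parsing is deliberately forgiving: any run of blanks or tabs separates
fields, CRLF line endings and trailing blank lines are accepted, and column
alignment is irrelevant.  XYZ carries no connectivity, so the returned
molecule has an empty bond set; callers normally follow a load with
:func:`molforge.perception.perceive_bonds`.

MOL reading is a preliminary subset: counts line, atom block and bond block
only.  Bond order is read but discarded — bonds are plain connectivity.
"""

from __future__ import annotations

from .elements import default_table
from .errors import BadIndexError, MalformedCountError, ParseError
from .molecule import Atom, Molecule

__all__ = ["read_xyz", "write_xyz", "read_mol"]


def read_xyz(text: str) -> Molecule:
    """Parse XYZ-format content into a Molecule (no bonds).

    Line 1 is the atom count, line 2 a free-text title, then one
    ``symbol x y z`` line per atom.  The declared count is validated
    against the atom lines actually present.
    """
    if not text.strip():
        raise ParseError("empty XYZ input")
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")
    try:
        count = int(lines[0].strip())
    except (ValueError, IndexError):
        raise ParseError(f"first line is not an atom count: {lines[0]!r}")
    if count < 0:
        raise ParseError("negative atom count")
    title = lines[1].strip() if len(lines) > 1 else ""

    table = default_table()
    atoms: list[Atom] = []
    for lineno, raw in enumerate(lines[2:], start=3):
        if not raw.strip():
            continue  # trailing/interior blank lines are tolerated
        fields = raw.split()
        if len(fields) < 4:
            raise ParseError(f"line {lineno}: expected 'symbol x y z', got {raw!r}")
        sym = table.lookup(fields[0]).symbol  # raises UnknownElementError
        try:
            xyz = [float(f) for f in fields[1:4]]
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric coordinate in {raw!r}")
        atoms.append(Atom(sym, xyz))
    if len(atoms) != count:
        raise MalformedCountError(
            f"header declares {count} atoms but {len(atoms)} atom lines parsed"
        )
    return Molecule(atoms=atoms, title=title)


def write_xyz(molecule: Molecule) -> str:
    """Serialize to canonical XYZ (coordinates to 6 decimal places)."""
    lines = [str(len(molecule)), molecule.title]
    for atom in molecule.atoms:
        x, y, z = atom.position
        lines.append(f"{atom.symbol} {x:.6f} {y:.6f} {z:.6f}")
    return "\n".join(lines) + "\n"


def read_mol(text: str) -> Molecule:
    """Parse a V2000 MOL connection table (atoms + bonds only).

    File indices are 1-based and converted to internal 0-based.  Property
    blocks, charges and stereo flags are ignored.
    """
    if not text.strip():
        raise ParseError("empty MOL input")
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")
    if len(lines) < 4:
        raise ParseError("MOL file shorter than header + counts line")
    title = lines[0].strip()
    counts = lines[3]
    # counts line: fixed columns aaabbb..., but tolerate whitespace splitting
    try:
        natoms = int(counts[0:3])
        nbonds = int(counts[3:6])
    except ValueError:
        fields = counts.split()
        try:
            natoms, nbonds = int(fields[0]), int(fields[1])
        except (ValueError, IndexError):
            raise ParseError(f"malformed counts line: {counts!r}")

    table = default_table()
    atoms: list[Atom] = []
    for lineno in range(4, 4 + natoms):
        if lineno >= len(lines):
            raise MalformedCountError("atom block shorter than declared count")
        fields = lines[lineno].split()
        if len(fields) < 4:
            raise ParseError(f"line {lineno + 1}: malformed atom line")
        xyz = [float(f) for f in fields[0:3]]
        sym = table.lookup(fields[3]).symbol
        atoms.append(Atom(sym, xyz))

    mol = Molecule(atoms=atoms, title=title)
    for lineno in range(4 + natoms, 4 + natoms + nbonds):
        if lineno >= len(lines):
            raise MalformedCountError("bond block shorter than declared count")
        line = lines[lineno]
        try:
            i = int(line[0:3])
            j = int(line[3:6])
        except ValueError:
            fields = line.split()
            try:
                i, j = int(fields[0]), int(fields[1])
            except (ValueError, IndexError):
                raise ParseError(f"line {lineno + 1}: malformed bond line")
        if not (1 <= i <= natoms and 1 <= j <= natoms):
            raise BadIndexError(
                f"bond ({i}, {j}) references a nonexistent atom in a {natoms}-atom file"
            )
        mol.add_bond(i - 1, j - 1)  # bond order in columns 7-9 is discarded
    return mol
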