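"""Structures, trajectories, atom selection and restraint specification.

Coordinates are carried in Å throughout.  PDB (fixed-column, including
multi-model files used as the trajectory dialect) and GRO are read through
:mod:`biotite`; a light validation pass runs first so that malformed records
are reported with their line number.  United-atom structures are accepted
as-is — no hydrogens are constructed.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)


class StructureParseError(ValueError):
    """Raised when a structure or trajectory file cannot be parsed."""


class SelectionSyntaxError(ValueError):
    """Raised for malformed selection expressions; carries the position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


#: HOLE-style van der Waals radii in Å, keyed by element, plus atom-name
#: prefix overrides.  Unknown atoms fall back to ``default``.
DEFAULT_VDW_RADII: dict = {
    "element": {"C": 1.85, "N": 1.75, "O": 1.65, "S": 2.00, "H": 1.00, "P": 2.10},
    "name_prefix": {},
    "default": 2.00,
}


# ---------------------------------------------------------------------------
# containers


@dataclass
class AtomSet:
    """An ordered collection of atoms for one structure or frame.

    Columnar storage: every field is a length-N array.  ``vdw_radius`` is NaN
    until :func:`assign_vdw_radii` has run.
    """

    serial: np.ndarray
    name: np.ndarray
    resname: np.ndarray
    resid: np.ndarray
    chain: np.ndarray
    element: np.ndarray
    coords: np.ndarray
    vdw_radius: np.ndarray = None  # type: ignore[assignment]
    box: np.ndarray | None = None
    provenance: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if len(self.coords) == 0:
            raise ValueError("AtomSet may not be empty")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.vdw_radius is None:
            self.vdw_radius = np.full(len(self.coords), np.nan)
        for attr in ("serial", "resid"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=int))
        for attr in ("name", "resname", "chain", "element"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype="U6"))
        if len(np.unique(self.serial)) != len(self.serial):
            raise ValueError("atom serials must be unique within a model")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def has_radii(self) -> bool:
        return bool(np.all(np.isfinite(self.vdw_radius)))

    def subset(self, indices: np.ndarray) -> "AtomSet":
        """Order-preserving subset by integer or boolean index array."""
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.nonzero(indices)[0]
        if len(indices) == 0:
            raise ValueError("selection is empty")
        return AtomSet(
            serial=self.serial[indices],
            name=self.name[indices],
            resname=self.resname[indices],
            resid=self.resid[indices],
            chain=self.chain[indices],
            element=self.element[indices],
            coords=self.coords[indices],
            vdw_radius=self.vdw_radius[indices],
            box=self.box,
            provenance=self.provenance,
        )

    def select(self, expression: str, allow_empty: bool = False) -> "AtomSet":
        return select_atoms(self, expression, allow_empty=allow_empty)

    def with_coords(self, coords: np.ndarray) -> "AtomSet":
        new = replace(self)
        new.coords = np.asarray(coords, dtype=float)
        if new.coords.shape != self.coords.shape:
            raise ValueError("replacement coordinates must match atom count")
        return new


@dataclass
class Trajectory:
    """Topology plus a stack of coordinate frames with times in ns."""

    topology: AtomSet
    frames: np.ndarray  # (n_frames, n_atoms, 3) in Å
    times: np.ndarray  # ns, strictly increasing
    timestep: float  # ns

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.topology):
            raise ValueError("every frame must match the topology's atom count")
        if len(self.times) != len(self.frames):
            raise ValueError("one time per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Sampled span in ns (n_frames × timestep)."""
        return self.n_frames * self.timestep

    def frame(self, i: int) -> AtomSet:
        return self.topology.with_coords(self.frames[i])


@dataclass
class RestraintSpec:
    """Elastic-network restraints: Cα pairs within a distance band.

    ``pairs`` holds (index_i, index_j, reference_distance_Å) with i < j,
    sorted ascending; indices refer to the Cα-filtered atom set.
    """

    pairs: list
    force_constant: float  # kJ mol⁻¹ nm⁻²
    low: float
    high: float

    def __post_init__(self):
        for i, j, d in self.pairs:
            if i == j:
                raise ValueError("self-pairs are not allowed")
            if not (self.low <= d <= self.high):
                raise ValueError(f"pair ({i},{j}) distance {d:.3f} outside band")


# ---------------------------------------------------------------------------
# PDB / GRO reading


_COORD_SLICES = [(30, 38), (38, 46), (46, 54)]


def _validate_pdb(lines: Sequence[str], path: str) -> list[int]:
    """Check ATOM/HETATM coordinate fields; return atom counts per model.

    Multi-model files must have identical atom counts per model; a mismatch
    is reported with the offending model (frame) index.
    """
    counts: list[int] = []
    current = 0
    in_model = False
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            if len(line.rstrip("\n")) < 54:
                raise StructureParseError(
                    f"{path}:{lineno}: truncated {rec} record (needs coordinate columns)"
                )
            for lo, hi in _COORD_SLICES:
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise StructureParseError(
                        f"{path}:{lineno}: malformed coordinate field {line[lo:hi]!r}"
                    ) from None
            current += 1
        elif rec == "MODEL":
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            counts.append(current)
            current = 0
    if not counts and current > 0:
        counts.append(current)
    elif in_model and current > 0:  # trailing model without ENDMDL
        counts.append(current)
    for i, c in enumerate(counts):
        if c != counts[0]:
            raise StructureParseError(
                f"{path}: frame {i} has {c} atoms, expected {counts[0]}"
            )
    return counts


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "NA", "MG", "BR", "FE", "ZN", "CA"):
        # two-letter ions only when the name is exactly the ion
        if stripped.upper() in ("CL", "NA", "MG", "BR", "FE", "ZN"):
            return stripped.capitalize()
    return stripped[0].upper()


def _atomset_from_biotite(arr, box, provenance: str) -> AtomSet:
    n = arr.array_length()
    serial = (
        arr.get_annotation("atom_id")
        if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, n + 1)
    )
    element = np.asarray(arr.element, dtype="U6")
    blank = np.array([e.strip() == "" for e in element])
    if blank.any():
        names = np.asarray(arr.atom_name)
        element = element.copy()
        for i in np.nonzero(blank)[0]:
            element[i] = _guess_element(names[i])
    return AtomSet(
        serial=np.asarray(serial),
        name=np.asarray(arr.atom_name),
        resname=np.asarray(arr.res_name),
        resid=np.asarray(arr.res_id),
        chain=np.asarray(arr.chain_id),
        element=element,
        coords=np.asarray(arr.coord, dtype=float),
        box=box,
        provenance=provenance,
    )


def _box_lengths(arr) -> np.ndarray | None:
    box = getattr(arr, "box", None)
    if box is None:
        return None
    box = np.asarray(box, dtype=float)
    if box.ndim == 3:  # stack: first frame
        box = box[0]
    return np.diag(box).copy()


def _read_file(path: str | Path):
    """Return a biotite AtomArray or AtomArrayStack for a PDB or GRO file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    suffix = path.suffix.lower()
    if suffix == ".gro":
        from biotite.structure.io.gro import GROFile

        gro = GROFile.read(str(path))
        arr = gro.get_structure()
        # GRO carries nm; biotite converts to Å already
        return arr
    lines = text.splitlines()
    _validate_pdb(lines, str(path))
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    try:
        arr = pdb.get_structure(extra_fields=["atom_id"])
    except Exception as exc:  # pragma: no cover - biotite-side failures
        raise StructureParseError(f"{path}: {exc}") from exc
    return arr


def read_structure(path: str | Path, model: int | str = 1):
    """Read a structure file (PDB or GRO) into an :class:`AtomSet`.

    ``model`` is 1-based; ``"all"`` returns a list of AtomSets, one per
    model.  Single-model files ignore ``model=1``.
    """
    arr = _read_file(path)
    box = _box_lengths(arr)
    provenance = str(path)
    is_stack = arr.coord.ndim == 3
    if model == "all":
        if not is_stack:
            return [_atomset_from_biotite(arr, box, f"{provenance}#model=1")]
        return [
            _atomset_from_biotite(arr[i], box, f"{provenance}#model={i + 1}")
            for i in range(arr.stack_depth())
        ]
    model = int(model)
    if not is_stack:
        if model != 1:
            raise StructureParseError(f"{path}: model {model} requested but file has 1 model")
        return _atomset_from_biotite(arr, box, f"{provenance}#model=1")
    if not (1 <= model <= arr.stack_depth()):
        raise StructureParseError(
            f"{path}: model {model} requested but file has {arr.stack_depth()} models"
        )
    return _atomset_from_biotite(arr[model - 1], box, f"{provenance}#model={model}")


def read_trajectory(
    path: str | Path, topology: AtomSet | None = None, timestep: float = 1.0
) -> Trajectory:
    """Read a multi-model PDB as a trajectory with times 0, dt, 2dt, … ns.

    If ``topology`` is given, every frame must match its atom count; the
    first model otherwise serves as topology.
    """
    models = read_structure(path, model="all")
    if topology is None:
        topology = models[0]
    for i, m in enumerate(models):
        if len(m) != len(topology):
            raise StructureParseError(
                f"{path}: frame {i} has {len(m)} atoms, expected {len(topology)}"
            )
    frames = np.stack([m.coords for m in models])
    times = np.arange(len(models)) * float(timestep)
    return Trajectory(topology=topology, frames=frames, times=times, timestep=float(timestep))


# ---------------------------------------------------------------------------
# PDB writing (fixtures round-trip through the same dialect the reader eats)


def _to_biotite(atoms: AtomSet):
    import biotite.structure as struc

    arr = struc.AtomArray(len(atoms))
    arr.coord = atoms.coords.astype(np.float32)
    arr.chain_id = atoms.chain
    arr.res_id = atoms.resid
    arr.res_name = atoms.resname
    arr.atom_name = atoms.name
    arr.element = atoms.element
    arr.set_annotation("atom_id", atoms.serial)
    if atoms.box is not None:
        arr.box = np.diag(atoms.box).astype(np.float32)
    return arr


def write_structure(atoms: AtomSet, path: str | Path) -> None:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(_to_biotite(atoms))
    pdb.write(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write as multi-model PDB (MODEL/ENDMDL), the mandatory dialect."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    arrays = []
    for i in range(traj.n_frames):
        a = _to_biotite(traj.topology)
        a.coord = traj.frames[i].astype(np.float32)
        arrays.append(a)
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# selection expressions


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")
_FIELDS = ("name", "resname", "resid", "chain", "element")
_KEYWORDS = set(_FIELDS) | {"and", "or", "not", "(", ")"}


class _Parser:
    """Recursive-descent parser for the selection grammar.

    expr    := term ("or" term)*
    term    := factor ("and" factor)*
    factor  := "not" factor | "(" expr ")" | field value+
    value   := literal | integer range "a:b" / "a-b" (resid only)
    """

    def __init__(self, expression: str, atoms: AtomSet):
        self.expression = expression
        self.atoms = atoms
        self.tokens = [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(expression)]
        self.pos = 0
        if not self.tokens:
            raise SelectionSyntaxError("empty selection expression", 0)

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.expression))

    def _next(self):
        tok = self._peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self._expr()
        tok, at = self._peek()
        if tok is not None:
            raise SelectionSyntaxError(f"unexpected token {tok!r}", at)
        return mask

    def _expr(self) -> np.ndarray:
        mask = self._term()
        while self._peek()[0] == "or":
            self._next()
            mask = mask | self._term()
        return mask

    def _term(self) -> np.ndarray:
        mask = self._factor()
        while self._peek()[0] == "and":
            self._next()
            mask = mask & self._factor()
        return mask

    def _factor(self) -> np.ndarray:
        tok, at = self._peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression", at)
        if tok == "not":
            self._next()
            return ~self._factor()
        if tok == "(":
            self._next()
            mask = self._expr()
            tok2, at2 = self._next()
            if tok2 != ")":
                raise SelectionSyntaxError("expected ')'", at2)
            return mask
        if tok in _FIELDS:
            return self._primary()
        raise SelectionSyntaxError(f"expected a field keyword, got {tok!r}", at)

    def _primary(self) -> np.ndarray:
        fld, at = self._next()
        values = []
        while True:
            tok, _ = self._peek()
            if tok is None or tok in _KEYWORDS:
                break
            values.append(self._next()[0])
        if not values:
            raise SelectionSyntaxError(f"field {fld!r} needs at least one value", at)
        if fld == "resid":
            mask = np.zeros(len(self.atoms), dtype=bool)
            for v in values:
                m = re.fullmatch(r"(-?\d+)[:–-](-?\d+)", v)
                if m:
                    lo, hi = int(m.group(1)), int(m.group(2))
                    mask |= (self.atoms.resid >= lo) & (self.atoms.resid <= hi)
                else:
                    try:
                        mask |= self.atoms.resid == int(v)
                    except ValueError:
                        raise SelectionSyntaxError(f"bad resid value {v!r}", at) from None
            return mask
        column = getattr(self.atoms, fld)
        if fld == "element":
            return np.isin(np.char.upper(column), [v.upper() for v in values])
        return np.isin(column, values)


def selection_mask(atoms: AtomSet, expression: str) -> np.ndarray:
    """Boolean mask for a selection expression (see :class:`_Parser`)."""
    return _Parser(expression, atoms).parse()


def select_atoms(atoms: AtomSet, expression: str, allow_empty: bool = False) -> AtomSet:
    """Subset ``atoms`` by a selection expression, preserving order.

    Grammar: ``name``/``resname``/``resid``/``chain``/``element`` each
    followed by one or more values (resid accepts ``a:b`` ranges), combined
    with ``and``/``or``/``not`` and parentheses.
    """
    mask = selection_mask(atoms, expression)
    if not mask.any() and not allow_empty:
        raise ValueError(f"selection {expression!r} matched no atoms")
    return atoms.subset(mask)


# ---------------------------------------------------------------------------
# vdW radii and restraints


def assign_vdw_radii(atoms: AtomSet, radius_set: dict | None = None) -> AtomSet:
    """Return a copy with every atom's vdW radius assigned.

    Lookup order: atom-name prefix override, then element, then the table's
    default (with a logged warning per unmatched element).
    """
    table = radius_set or DEFAULT_VDW_RADII
    by_element = {k.upper(): v for k, v in table.get("element", {}).items()}
    by_prefix = {k.upper(): v for k, v in table.get("name_prefix", {}).items()}
    default = float(table.get("default", 2.0))
    radii = np.empty(len(atoms))
    warned: set[str] = set()
    for i in range(len(atoms)):
        name = atoms.name[i].upper()
        hit = None
        for prefix, r in by_prefix.items():
            if name.startswith(prefix):
                hit = r
                break
        if hit is None:
            hit = by_element.get(atoms.element[i].upper())
        if hit is None:
            hit = default
            key = atoms.element[i]
            if key not in warned:
                warned.add(key)
                msg = f"no vdW radius for element {key!r}; using default {default} Å"
                logger.warning(msg)
                warnings.warn(msg, stacklevel=2)
        radii[i] = hit
    out = atoms.subset(np.arange(len(atoms)))
    out.vdw_radius = radii
    return out


def gnm_restraint_pairs(
    atoms: AtomSet,
    low: float = 7.0,
    high: float = 9.0,
    force_constant: float = 1000.0,
) -> RestraintSpec:
    """Gaussian-network restraint pairs between Cα atoms.

    All unordered Cα pairs whose separation lies in [low, high] Å, each with
    its reference distance and a shared force constant (default
    1000 kJ mol⁻¹ nm⁻², the standard elastic-network strength).  Pair indices
    refer to the Cα-filtered order and are emitted ascending.
    """
    if low >= high:
        raise ValueError("low must be < high")
    ca_mask = atoms.name == "CA"
    if ca_mask.sum() < 2:
        raise ValueError("need at least 2 Cα atoms for a network")
    ca = atoms.subset(ca_mask)
    from scipy.spatial import cKDTree

    tree = cKDTree(ca.coords)
    candidates = tree.query_pairs(r=high, output_type="ndarray")
    pairs = []
    for i, j in candidates:
        d = float(np.linalg.norm(ca.coords[i] - ca.coords[j]))
        if low <= d <= high:
            pairs.append((int(min(i, j)), int(max(i, j)), d))
    pairs.sort()
    return RestraintSpec(pairs=pairs, force_constant=force_constant, low=low, high=high)
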