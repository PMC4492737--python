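"""Reading structures and trajectories into coordinate ensembles.

All coordinates are handled in Angstrom internally (MDAnalysis converts
nm-based formats such as XTC on read). The rest of the package only ever
sees :class:`Ensemble` / :class:`StructureFrame`, so the file format is
irrelevant downstream — the clustering metric is superposition-free and no
alignment or imaging is performed here.

Atom selection is residue-level: one named atom per residue (Cα by
default), optionally restricted to explicit chain/residue ranges. Altloc
duplicates are resolved to a single atom (highest occupancy, tie broken in
favour of altloc 'A'). Residues lacking the selected atom are dropped with
a warning, unless the user explicitly asked for them via ``residue_include``
— then it is an error, since the intent was explicit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import InputError, SelectionError

logger = logging.getLogger(__name__)

__all__ = [
    "Label",
    "AtomSelection",
    "StructureFrame",
    "Ensemble",
    "parse_residue_ranges",
    "read_structure",
    "read_trajectory",
    "write_multimodel_pdb",
    "write_trajectory",
]


class Label(NamedTuple):
    """Identity of one selected atom: residue-level key plus residue name."""

    chain: str
    resnum: int
    icode: str
    resname: str

    @property
    def key(self) -> tuple:
        """Identity key; resname is annotation only."""
        return (self.chain, self.resnum, self.icode)

    def __str__(self) -> str:
        return f"{self.chain}{self.resnum}{self.icode}".strip()


def parse_residue_ranges(spec: str) -> list[tuple[str, int, int]]:
    """Parse ``"A:5-10,B:1-100,A:12"`` into (chain, lo, hi) triples."""
    ranges = []
    for part in spec.split(","):
        part = part.strip()
        if not part:
            continue
        try:
            chain, rng = part.split(":")
            if "-" in rng.lstrip("-"):
                lo, hi = rng.rsplit("-", 1)
                lo, hi = int(lo), int(hi)
            else:
                lo = hi = int(rng)
        except ValueError as exc:
            raise SelectionError(f"cannot parse residue range {part!r}") from exc
        if hi < lo:
            raise SelectionError(f"empty residue range {part!r}")
        ranges.append((chain.strip(), lo, hi))
    if not ranges:
        raise SelectionError(f"no residue ranges in {spec!r}")
    return ranges


@dataclass(frozen=True)
class AtomSelection:
    """One named atom per residue, optionally restricted to residue ranges.

    Parameters
    ----------
    atom_name:
        PDB atom name to keep per residue. Default ``"CA"``.
    residue_include:
        Optional list of ``(chain, lo, hi)`` inclusive ranges. ``None``
        keeps every residue possessing the atom.
    """

    atom_name: str = "CA"
    residue_include: tuple[tuple[str, int, int], ...] | None = None

    def __post_init__(self):
        if self.residue_include is not None:
            object.__setattr__(
                self, "residue_include", tuple(tuple(r) for r in self.residue_include)
            )

    def includes(self, chain: str, resnum: int) -> bool:
        if self.residue_include is None:
            return True
        return any(
            chain == c and lo <= resnum <= hi for c, lo, hi in self.residue_include
        )


@dataclass
class StructureFrame:
    """A single conformation over a fixed atom selection (Å)."""

    coords: np.ndarray  # (N, 3) float64
    labels: list[Label]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InputError(f"coords must be N×3, got {self.coords.shape}")
        if self.coords.shape[0] != len(self.labels):
            raise InputError("coords/labels length mismatch")
        if not np.isfinite(self.coords).all():
            raise InputError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Ensemble:
    """An ordered set of conformations over one fixed atom selection (Å)."""

    coords: np.ndarray  # (n_frames, N, 3) float64
    labels: list[Label]
    selection: AtomSelection = field(default_factory=AtomSelection)
    provenance: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InputError(f"coords must be F×N×3, got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise InputError("ensemble needs at least one frame")
        if self.coords.shape[1] != len(self.labels):
            raise InputError("coords/labels length mismatch")
        if not np.isfinite(self.coords).all():
            raise InputError("non-finite coordinates")
        keys = [lab.key for lab in self.labels]
        if len(set(keys)) != len(keys):
            raise InputError("duplicate (chain, resnum, icode) labels")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> StructureFrame:
        return StructureFrame(self.coords[i], self.labels)


def _select_atoms(universe, selection: AtomSelection):
    """Apply ``selection`` to a Universe; return (atom indices, labels).

    Altloc duplicates collapse to the highest-occupancy copy (tie → 'A');
    residues missing the atom are dropped with a warning or, when they
    fall inside an explicit ``residue_include``, raise SelectionError.
    """
    atoms = universe.atoms
    n = len(atoms)

    def attr(name, default):
        try:
            return getattr(atoms, name)
        except Exception:
            return np.array([default] * n)

    names = attr("names", "")
    chains = attr("chainIDs", "")
    if not any(str(c).strip() for c in chains):
        chains = attr("segids", "")
    resnums = attr("resids", 0)
    icodes = attr("icodes", "")
    resnames = attr("resnames", "UNK")
    occup = attr("occupancies", 1.0)
    altlocs = attr("altLocs", "")

    # group candidate atoms by residue key, in file order
    by_key: dict[tuple, list[int]] = {}
    order: list[tuple] = []
    residues_seen: set[tuple] = set()
    for i in range(n):
        chain = str(chains[i]).strip()
        key = (chain, int(resnums[i]), str(icodes[i]).strip())
        residues_seen.add(key)
        if str(names[i]).strip() != selection.atom_name:
            continue
        if not selection.includes(chain, int(resnums[i])):
            continue
        if key not in by_key:
            by_key[key] = []
            order.append(key)
        by_key[key].append(i)

    indices: list[int] = []
    labels: list[Label] = []
    for key in order:
        cand = by_key[key]
        if len(cand) > 1:
            # altloc duplicates: highest occupancy, tie → altloc 'A' (then
            # lexicographic) for determinism
            cand = sorted(
                cand, key=lambda i: (-float(occup[i]), str(altlocs[i]).strip() or "A")
            )
        i = cand[0]
        indices.append(i)
        labels.append(Label(key[0], key[1], key[2], str(resnames[i]).strip()))

    # residues present in the file, inside an explicit include, but lacking
    # the atom: the user asked for them, so error rather than drop
    if selection.residue_include is not None:
        for key in sorted(residues_seen):
            if selection.includes(key[0], key[1]) and key not in by_key:
                raise SelectionError(
                    f"residue {key[0]}:{key[1]}{key[2]} has no atom "
                    f"{selection.atom_name!r}"
                )
    else:
        dropped = sorted(k for k in residues_seen if k not in by_key)
        if dropped:
            logger.warning(
                "dropped %d residue(s) without atom %r: %s",
                len(dropped),
                selection.atom_name,
                ", ".join(f"{c}:{r}{ic}" for c, r, ic in dropped[:10])
                + ("..." if len(dropped) > 10 else ""),
            )

    if not indices:
        raise SelectionError(
            f"selection (atom {selection.atom_name!r}) matched no atoms"
        )
    return np.array(indices, dtype=int), labels


def _load_universe(topology, trajectory=None):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign reader chatter (elements, box...)
        try:
            if trajectory is None:
                return mda.Universe(str(topology))
            return mda.Universe(str(topology), str(trajectory))
        except (OSError, ValueError, EOFError) as exc:
            raise InputError(f"cannot read {trajectory or topology}: {exc}") from exc


def read_structure(path, selection: AtomSelection | None = None) -> StructureFrame:
    """Read a single structure (first model of a PDB) under ``selection``."""
    selection = selection or AtomSelection()
    u = _load_universe(path)
    idx, labels = _select_atoms(u, selection)
    coords = np.array(u.atoms.positions[idx], dtype=np.float64)
    return StructureFrame(coords, labels)


def read_trajectory(
    topology,
    trajectory=None,
    selection: AtomSelection | None = None,
    stride: int = 1,
) -> Ensemble:
    """Read a trajectory into an :class:`Ensemble`.

    ``trajectory`` may be omitted when ``topology`` itself is a multi-model
    PDB. Striding is 1-based starting at the first stored frame: stride 3
    over 10 frames keeps frames 1, 4, 7, 10.
    """
    selection = selection or AtomSelection()
    if stride < 1:
        raise InputError(f"stride must be ≥ 1, got {stride}")
    u = _load_universe(topology, trajectory)
    idx, labels = _select_atoms(u, selection)
    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory[::stride]:
            frames.append(np.array(u.atoms.positions[idx], dtype=np.float64))
    if not frames:
        raise InputError("no frames after striding")
    src = f"{topology}" + (f" + {trajectory}" if trajectory else "")
    ens = Ensemble(
        np.stack(frames),
        labels,
        selection=selection,
        provenance=f"read_trajectory({src}, stride={stride})",
    )
    logger.info(
        "read %d frame(s) × %d atom(s) from %s", ens.n_frames, ens.n_atoms, src
    )
    return ens


_PDB_ATOM = (
    "ATOM  {serial:>5} {name:<4}{altloc:1}{resname:>3} {chain:1}"
    "{resnum:>4}{icode:1}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bf:6.2f}"
    "          {element:>2}\n"
)


def _atom_line(serial, lab: Label, xyz, name="CA", bf=0.0) -> str:
    return _PDB_ATOM.format(
        serial=min(serial, 99999),
        name=f" {name:<3}",
        altloc="",
        resname=(lab.resname or "GLY")[:3],
        chain=(lab.chain or "A")[:1],
        resnum=lab.resnum,
        icode=lab.icode[:1] if lab.icode else "",
        x=xyz[0],
        y=xyz[1],
        z=xyz[2],
        occ=1.00,
        bf=bf,
        element="C",
    )


def write_multimodel_pdb(ensemble: Ensemble, path) -> None:
    """Write the ensemble as a multi-model Cα-trace PDB."""
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            fh.write(f"MODEL     {f + 1}\n")
            for a, lab in enumerate(ensemble.labels):
                fh.write(
                    _atom_line(
                        a + 1,
                        lab,
                        ensemble.coords[f, a],
                        name=ensemble.selection.atom_name,
                    )
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_trajectory(ensemble: Ensemble, path) -> None:
    """Write coordinates to a binary trajectory (format from extension)."""
    import MDAnalysis as mda

    u = mda.Universe.empty(ensemble.n_atoms, trajectory=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=ensemble.n_atoms) as w:
            for f in range(ensemble.n_frames):
                u.atoms.positions = ensemble.coords[f].astype(np.float32)
                w.write(u.atoms)
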