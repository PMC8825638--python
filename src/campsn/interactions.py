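"""Frame-wise interaction detection and persistence tables.

Residues are nodes; three non-covalent interaction classes are detected
geometrically in every frame of a conformational ensemble:

* ``hydrophobic``  — side-chain centers of mass of two hydrophobic residues
  within ``d_hydro``;
* ``salt_bridge``  — any pair of oppositely charged group atoms within
  ``d_salt``;
* ``hydrogen_bond`` — donor–acceptor distance ≤ ``d_hb`` and a donor-side
  angle ≥ ``theta_hb`` (measured at the hydrogen when protons are present,
  otherwise at the donor heavy atom between its covalent antecedent and the
  acceptor).

The persistence of a (pair, class) interaction is the percentage of frames
in which it is detected; persistence tables are the substrate for building
persistence-filtered protein structure networks.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "Residue",
    "ResidueTopology",
    "ConformationalEnsemble",
    "DetectionConfig",
    "PersistenceTable",
    "detect_frame_interactions",
    "compute_persistence",
    "persistence_from_stream",
    "HYDROPHOBIC_RESIDUES",
    "ACIDIC_RESIDUES",
    "BASIC_RESIDUES",
]

# ---------------------------------------------------------------------------
# Chemical classification tables
# ---------------------------------------------------------------------------

HYDROPHOBIC_RESIDUES = frozenset({"ILE", "LEU", "VAL", "PHE", "MET", "ALA"})
ACIDIC_RESIDUES = frozenset({"ASP", "GLU"})
BASIC_RESIDUES = frozenset({"LYS", "ARG", "HIS"})

#: side-chain atoms carrying the formal charge of ionisable residues
CHARGED_GROUP_ATOMS: Mapping[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}

#: H-bond donor heavy atoms per residue (backbone N is a donor for all)
SIDECHAIN_DONORS: Mapping[str, tuple[str, ...]] = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",),
}

#: H-bond acceptor heavy atoms per residue (backbone O accepts for all)
SIDECHAIN_ACCEPTORS: Mapping[str, tuple[str, ...]] = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
}

#: covalent antecedent of each donor heavy atom, used for the proton-free
#: angle fallback; unknown donors fall back to CB then CA.
DONOR_ANTECEDENT: Mapping[str, str] = {
    "N": "CA",
    "OG": "CB",
    "OG1": "CB",
    "OH": "CZ",
    "ND2": "CG",
    "NE2": "CD",
    "NZ": "CE",
    "NE": "CD",
    "NH1": "CZ",
    "NH2": "CZ",
    "ND1": "CG",
    "NE1": "CD1",
}

_BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA"})

_ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

INTERACTION_CLASSES = ("hydrophobic", "salt_bridge", "hydrogen_bond")


# ---------------------------------------------------------------------------
# Topology and ensemble containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Residue:
    """A residue: chain id, sequence index, three-letter name and its atoms."""

    chain: str
    resid: int
    name: str
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.atom_names) == 0:
            raise ValueError(f"residue {self.chain}:{self.resid} has no atoms")
        if len(self.atom_names) != len(self.elements):
            raise ValueError("atom_names and elements length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def label(self) -> str:
        """Node label ``chain:X<resid>`` with a one-letter residue code."""
        one = _THREE_TO_ONE.get(self.name, "X")
        return f"{self.chain}:{one}{self.resid}"


@dataclass
class ResidueTopology:
    """Residue/atom topology with reference coordinates in Å.

    ``coordinates`` has one row per atom, ordered residue by residue as in
    ``residues``. Classification (hydrophobic flag, charged-group atoms,
    donors/acceptors) is derived from the residue name tables above.
    """

    residues: list[Residue]
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = sum(r.n_atoms for r in self.residues)
        if self.coordinates.shape != (n, 3):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} != ({n}, 3)"
            )
        seen = set()
        for r in self.residues:
            key = (r.chain, r.resid)
            if key in seen:
                raise ValueError(f"duplicate residue {key}")
            seen.add(key)
        offsets = np.cumsum([0] + [r.n_atoms for r in self.residues])
        self._offsets = offsets

    @property
    def n_atoms(self) -> int:
        return int(self._offsets[-1])

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def atom_slice(self, i: int) -> slice:
        return slice(int(self._offsets[i]), int(self._offsets[i + 1]))

    def atom_index(self, i: int, atom_name: str) -> int | None:
        res = self.residues[i]
        try:
            return int(self._offsets[i]) + res.atom_names.index(atom_name)
        except ValueError:
            return None

    @property
    def ca_indices(self) -> np.ndarray:
        """Flat atom indices of the Cα atoms, one per residue."""
        idx = []
        for i, res in enumerate(self.residues):
            j = self.atom_index(i, "CA")
            if j is None:
                raise ValueError(f"residue {res.label} lacks a CA atom")
            idx.append(j)
        return np.asarray(idx, dtype=int)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.residues]

    def chains(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain not in out:
                out.append(r.chain)
        return out


@dataclass
class ConformationalEnsemble:
    """An ordered stack of frames over a fixed topology (coordinates in Å)."""

    topology: ResidueTopology
    frames: np.ndarray
    replica: str = "replica-0"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (
            self.topology.n_atoms,
            3,
        ):
            raise ValueError(
                "frames must have shape (n_frames, n_atoms, 3) matching topology"
            )
        if self.frames.shape[0] < 2:
            raise ValueError("an ensemble needs at least 2 frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def ca_coordinates(self) -> np.ndarray:
        """Cα coordinates, shape (n_frames, n_residues, 3)."""
        return self.frames[:, self.topology.ca_indices, :]

    # -- multi-model PDB I/O (biotite) --------------------------------------

    def to_pdb(self, path: str | Path) -> None:
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdbio

        top = self.topology
        arr = struc.AtomArray(top.n_atoms)
        chain_id, res_id, res_name, atom_name, element = [], [], [], [], []
        for res in top.residues:
            for name, elem in zip(res.atom_names, res.elements):
                chain_id.append(res.chain)
                res_id.append(res.resid)
                res_name.append(res.name)
                atom_name.append(name)
                element.append(elem)
        arr.chain_id = np.array(chain_id)
        arr.res_id = np.array(res_id)
        arr.res_name = np.array(res_name)
        arr.atom_name = np.array(atom_name)
        arr.element = np.array(element)
        arr.hetero = np.zeros(top.n_atoms, dtype=bool)
        stack = struc.stack([arr] * self.n_frames)
        stack.coord = self.frames.astype(np.float32)
        pdb = pdbio.PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))

    @classmethod
    def from_pdb(cls, path: str | Path, replica: str | None = None
                 ) -> "ConformationalEnsemble":
        import biotite.structure.io.pdb as pdbio

        pdb = pdbio.PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
        residues: list[Residue] = []
        names: list[str] = []
        elements: list[str] = []
        prev: tuple[str, int] | None = None
        arr0 = stack[0]
        for i in range(arr0.array_length()):
            key = (str(arr0.chain_id[i]), int(arr0.res_id[i]))
            if prev is not None and key != prev:
                residues.append(_flush_residue(prev, arr0, i, names, elements))
                names, elements = [], []
            names.append(str(arr0.atom_name[i]))
            elements.append(str(arr0.element[i]))
            prev = key
        if prev is not None:
            residues.append(
                _flush_residue(prev, arr0, arr0.array_length(), names, elements)
            )
        topo = ResidueTopology(residues, np.asarray(arr0.coord, dtype=float))
        return cls(
            topo,
            np.asarray(stack.coord, dtype=float),
            replica=replica or Path(path).stem,
        )


def _flush_residue(key, arr, end_idx, names, elements) -> Residue:
    # residue name comes from the first atom of the block
    start = end_idx - len(names)
    return Residue(
        chain=key[0],
        resid=key[1],
        name=str(arr.res_name[start]),
        atom_names=tuple(names),
        elements=tuple(elements),
    )


#: registry for optional topology+trajectory readers, keyed by format name.
#: A reader maps (topology_path, trajectory_path) -> ConformationalEnsemble.
TRAJECTORY_READERS: dict[str, callable] = {}


def read_ensemble(path: str | Path, *, fmt: str | None = None,
                  topology_path: str | Path | None = None,
                  replica: str | None = None) -> ConformationalEnsemble:
    """Read an ensemble: multi-model PDB natively, other formats via registry."""
    if fmt is None or fmt == "pdb":
        return ConformationalEnsemble.from_pdb(path, replica=replica)
    try:
        reader = TRAJECTORY_READERS[fmt]
    except KeyError:
        raise ValueError(f"no reader registered for format {fmt!r}") from None
    return reader(topology_path, path)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DetectionConfig:
    """Geometric cutoffs for interaction detection.

    Defaults follow standard protein-structure-network practice:
    5.0 Å between hydrophobic side-chain centers of mass, 4.5 Å between
    oppositely charged group atoms, 3.5 Å donor–acceptor with a 120° angle
    for hydrogen bonds. Sequence-adjacent residues (|Δindex| ≤ 1 in the same
    chain) are never connected.
    """

    d_hydro: float = 5.0
    d_salt: float = 4.5
    d_hb: float = 3.5
    theta_hb: float = 120.0

    def to_json(self, path: str | Path) -> None:
        import json

        Path(path).write_text(
            json.dumps(
                {
                    "d_hydro": self.d_hydro,
                    "d_salt": self.d_salt,
                    "d_hb": self.d_hb,
                    "theta_hb": self.theta_hb,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DetectionConfig":
        import json

        return cls(**json.loads(Path(path).read_text()))


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _sequence_adjacent(r1: Residue, r2: Residue) -> bool:
    return r1.chain == r2.chain and abs(r1.resid - r2.resid) <= 1


class _DetectionContext:
    """Pre-resolved atom indices for a topology (built once, reused per frame)."""

    def __init__(self, topology: ResidueTopology):
        self.topology = topology
        t = topology
        # hydrophobic residues: side-chain atom indices and masses
        self.hydro: list[tuple[int, np.ndarray, np.ndarray]] = []
        for i, res in enumerate(t.residues):
            if res.name not in HYDROPHOBIC_RESIDUES:
                continue
            sl = t.atom_slice(i)
            idx = [
                sl.start + j
                for j, nm in enumerate(res.atom_names)
                if nm not in _BACKBONE_ATOMS and res.elements[j] != "H"
            ]
            if not idx:
                continue
            masses = np.array(
                [_ELEMENT_MASS.get(t.residues[i].elements[j - sl.start], 12.0)
                 for j in idx]
            )
            self.hydro.append((i, np.array(idx), masses))
        # charged group atoms: (residue index, atom index, sign)
        self.charged: list[tuple[int, int, int]] = []
        for i, res in enumerate(t.residues):
            atoms = CHARGED_GROUP_ATOMS.get(res.name)
            if atoms is None:
                continue
            sign = -1 if res.name in ACIDIC_RESIDUES else +1
            for nm in atoms:
                j = t.atom_index(i, nm)
                if j is not None:
                    self.charged.append((i, j, sign))
        # donors: (residue, donor atom idx, hydrogen idx or None,
        #          antecedent idx or None)
        self.donors: list[tuple[int, int, int | None, int | None]] = []
        for i, res in enumerate(t.residues):
            donor_names = ["N"] + list(SIDECHAIN_DONORS.get(res.name, ()))
            for nm in donor_names:
                j = t.atom_index(i, nm)
                if j is None:
                    continue
                h_idx = self._find_hydrogen(i, nm)
                ante = self._find_antecedent(i, nm)
                self.donors.append((i, j, h_idx, ante))
        # acceptors: (residue, atom idx)
        self.acceptors: list[tuple[int, int]] = []
        for i, res in enumerate(t.residues):
            acc_names = ["O"] + list(SIDECHAIN_ACCEPTORS.get(res.name, ()))
            for nm in acc_names:
                j = t.atom_index(i, nm)
                if j is not None:
                    self.acceptors.append((i, j))

    def _find_hydrogen(self, i: int, donor_name: str) -> int | None:
        # hydrogens named like the donor: H for N, HG for OG, HZ1.. for NZ
        res = self.topology.residues[i]
        if donor_name == "N":
            return self.topology.atom_index(i, "H")
        stem = "H" + donor_name[1:]
        for j, nm in enumerate(res.atom_names):
            if res.elements[j] == "H" and nm.startswith(stem):
                return self.topology.atom_slice(i).start + j
        return None

    def _find_antecedent(self, i: int, donor_name: str) -> int | None:
        cand = DONOR_ANTECEDENT.get(donor_name)
        for nm in (cand, "CB", "CA"):
            if nm is None:
                continue
            j = self.topology.atom_index(i, nm)
            if j is not None:
                return j
        return None


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1 = a - vertex
    v2 = b - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_frame_interactions(
    topology: ResidueTopology,
    frame: np.ndarray,
    cutoffs: DetectionConfig | None = None,
    _context: "_DetectionContext | None" = None,
) -> set[tuple[tuple[str, str], str]]:
    """Detect all (pair, class) interactions present in a single frame.

    Returns a set of ``((label_a, label_b), class)`` with labels sorted within
    the pair; sequence-adjacent residues are excluded for every class.
    """
    cutoffs = cutoffs or DetectionConfig()
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (topology.n_atoms, 3):
        raise ValueError("frame does not match topology atom count")
    ctx = _context or _DetectionContext(topology)
    res = topology.residues
    found: set[tuple[tuple[str, str], str]] = set()

    # hydrophobic: side-chain COM distances
    if len(ctx.hydro) >= 2:
        coms = np.array(
            [np.average(frame[idx], axis=0, weights=m) for _, idx, m in ctx.hydro]
        )
        d = cdist(coms, coms)
        for a, b in itertools.combinations(range(len(ctx.hydro)), 2):
            i, j = ctx.hydro[a][0], ctx.hydro[b][0]
            if _sequence_adjacent(res[i], res[j]):
                continue
            if d[a, b] <= cutoffs.d_hydro:
                found.add((_pair_key(res[i].label, res[j].label), "hydrophobic"))

    # salt bridges: opposite charged-group atoms
    neg = [(i, j) for i, j, s in ctx.charged if s < 0]
    pos = [(i, j) for i, j, s in ctx.charged if s > 0]
    if neg and pos:
        dn = cdist(frame[[j for _, j in neg]], frame[[j for _, j in pos]])
        for a, b in zip(*np.nonzero(dn <= cutoffs.d_salt)):
            i, j = neg[a][0], pos[b][0]
            if i == j or _sequence_adjacent(res[i], res[j]):
                continue
            found.add((_pair_key(res[i].label, res[j].label), "salt_bridge"))

    # hydrogen bonds: donor-acceptor distance + angle constraint
    if ctx.donors and ctx.acceptors:
        d_idx = [d for _, d, _, _ in ctx.donors]
        a_idx = [a for _, a in ctx.acceptors]
        dd = cdist(frame[d_idx], frame[a_idx])
        for a, b in zip(*np.nonzero(dd <= cutoffs.d_hb)):
            i_res, d_atom, h_atom, ante = ctx.donors[a]
            j_res, acc_atom = ctx.acceptors[b]
            if i_res == j_res or _sequence_adjacent(res[i_res], res[j_res]):
                continue
            if h_atom is not None:
                ang = _angle_deg(frame[d_atom], frame[h_atom], frame[acc_atom])
            elif ante is not None:
                ang = _angle_deg(frame[ante], frame[d_atom], frame[acc_atom])
            else:
                ang = 180.0  # no geometry to test against: accept on distance
            if ang >= cutoffs.theta_hb:
                found.add(
                    (_pair_key(res[i_res].label, res[j_res].label),
                     "hydrogen_bond")
                )
    return found


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


@dataclass
class PersistenceTable:
    """Per (residue pair, interaction class) persistence in % of frames."""

    entries: dict[tuple[tuple[str, str], str], float]
    n_frames: int

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        canonical = {}
        for (pair, cls), pct in self.entries.items():
            if pair[0] == pair[1]:
                raise ValueError(f"self-pair {pair}")
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"persistence {pct} outside [0, 100]")
            if cls not in INTERACTION_CLASSES:
                raise ValueError(f"unknown interaction class {cls!r}")
            canonical[(_pair_key(*pair), cls)] = pct
        self.entries = canonical

    def persistence(self, pair: tuple[str, str], cls: str) -> float:
        """Persistence %, 0.0 when the pair was never observed."""
        return self.entries.get((_pair_key(*pair), cls), 0.0)

    def subset(self, cls: str) -> dict[tuple[str, str], float]:
        return {
            pair: pct for (pair, c), pct in self.entries.items() if c == cls
        }

    # -- CSV I/O ------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (pair, cls), pct in sorted(self.entries.items()):
            ca, ra = pair[0].split(":", 1)
            cb, rb = pair[1].split(":", 1)
            rows.append(
                {
                    "chain_a": ca,
                    "res_a": ra,
                    "chain_b": cb,
                    "res_b": rb,
                    "class": cls,
                    "persistence_pct": pct,
                    "n_frames": self.n_frames,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "chain_a", "res_a", "chain_b", "res_b",
                "class", "persistence_pct", "n_frames",
            ],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PersistenceTable":
        df = pd.read_csv(path)
        entries = {}
        n_frames = 1
        for _, row in df.iterrows():
            pair = _pair_key(
                f"{row['chain_a']}:{row['res_a']}",
                f"{row['chain_b']}:{row['res_b']}",
            )
            entries[(pair, row["class"])] = float(row["persistence_pct"])
            n_frames = int(row["n_frames"])
        return cls(entries, n_frames)

    @classmethod
    def weighted_merge(
        cls, tables: Sequence["PersistenceTable"]
    ) -> "PersistenceTable":
        """Frame-count-weighted mean of several tables (replica concatenation)."""
        if not tables:
            raise ValueError("no tables to merge")
        total = sum(t.n_frames for t in tables)
        keys = set().union(*(t.entries.keys() for t in tables))
        entries = {
            k: sum(t.entries.get(k, 0.0) * t.n_frames for t in tables) / total
            for k in keys
        }
        return cls(entries, total)


def compute_persistence(
    ensemble: ConformationalEnsemble | Sequence[ConformationalEnsemble],
    cutoffs: DetectionConfig | None = None,
) -> PersistenceTable:
    """Persistence over all frames of one ensemble or a list of replicas."""
    if isinstance(ensemble, ConformationalEnsemble):
        ensembles = [ensemble]
    else:
        ensembles = list(ensemble)
        if not ensembles:
            raise ValueError("empty ensemble list")
    cutoffs = cutoffs or DetectionConfig()
    counts: dict[tuple[tuple[str, str], str], int] = {}
    n_frames = 0
    for ens in ensembles:
        ctx = _DetectionContext(ens.topology)
        for frame in ens.frames:
            n_frames += 1
            for key in detect_frame_interactions(
                ens.topology, frame, cutoffs, _context=ctx
            ):
                counts[key] = counts.get(key, 0) + 1
    entries = {k: 100.0 * v / n_frames for k, v in counts.items()}
    return PersistenceTable(entries, n_frames)


def persistence_from_stream(
    stream: Iterable[set[tuple[tuple[str, str], str]]],
) -> PersistenceTable:
    """Persistence from a pre-detected per-frame contact stream."""
    counts: dict[tuple[tuple[str, str], str], int] = {}
    n_frames = 0
    for frame_set in stream:
        n_frames += 1
        for pair, cls in frame_set:
            key = (_pair_key(*pair), cls)
            counts[key] = counts.get(key, 0) + 1
    if n_frames == 0:
        raise ValueError("empty contact stream")
    entries = {k: 100.0 * v / n_frames for k, v in counts.items()}
    return PersistenceTable(entries, n_frames)
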