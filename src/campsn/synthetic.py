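"""Synthetic inputs with known ground truth.

Real inputs for this pipeline are microsecond-scale MD ensembles of a
calmodulin–peptide complex and SPR/ITC raw data. This module generates
desk-scale stand-ins whose generating parameters are returned alongside the
data, so every downstream estimator can be tested for parameter recovery:

* :func:`make_toy_complex` — a deterministic two-chain pseudo-helical
  topology whose residues cover all chemical classes the detector needs;
* :func:`sample_ensemble` — multi-replica Gaussian ensembles displaced along
  prescribed orthonormal collective modes (the planted "essential subspace")
  plus isotropic noise;
* :func:`sample_contact_stream` — frame-wise Bernoulli interaction streams
  with prescribed per-pair persistence;
* :func:`simulate_sensorgram` — noisy 1:1 Langmuir sensorgrams.

All generators are deterministic given their seed; replica r of an ensemble
uses ``seed + r``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .energetics import Sensorgram
from .interactions import (
    ConformationalEnsemble,
    Residue,
    ResidueTopology,
)

__all__ = [
    "EnsembleSpec",
    "ContactStreamSpec",
    "SensorgramSpec",
    "make_toy_complex",
    "sample_ensemble",
    "sample_contact_stream",
    "simulate_sensorgram",
]


# ---------------------------------------------------------------------------
# Toy complex
# ---------------------------------------------------------------------------

# atoms beyond the N/CA/C/O backbone, with elements; enough side-chain
# geometry for COM, charge-group and donor/acceptor detection
_SIDECHAINS: Mapping[str, tuple[tuple[str, str], ...]] = {
    "ALA": (("CB", "C"),),
    "LEU": (("CB", "C"), ("CG", "C"), ("CD1", "C"), ("CD2", "C")),
    "ILE": (("CB", "C"), ("CG1", "C"), ("CD1", "C")),
    "VAL": (("CB", "C"), ("CG1", "C"), ("CG2", "C")),
    "PHE": (("CB", "C"), ("CG", "C"), ("CZ", "C")),
    "MET": (("CB", "C"), ("CG", "C"), ("SD", "S"), ("CE", "C")),
    "ASP": (("CB", "C"), ("CG", "C"), ("OD1", "O"), ("OD2", "O")),
    "GLU": (("CB", "C"), ("CG", "C"), ("CD", "C"), ("OE1", "O"), ("OE2", "O")),
    "LYS": (("CB", "C"), ("CG", "C"), ("CE", "C"), ("NZ", "N")),
    "ARG": (("CB", "C"), ("CG", "C"), ("CD", "C"), ("NE", "N"),
            ("CZ", "C"), ("NH1", "N"), ("NH2", "N")),
    "SER": (("CB", "C"), ("OG", "O")),
    "ASN": (("CB", "C"), ("CG", "C"), ("OD1", "O"), ("ND2", "N")),
}

_HYDROPHOBIC_POOL = ("LEU", "ILE", "VAL", "PHE", "MET", "ALA")
_ACIDIC_POOL = ("ASP", "GLU")
_BASIC_POOL = ("LYS", "ARG")
_POLAR_POOL = ("SER", "ASN")
_FULL_POOL = _HYDROPHOBIC_POOL + _ACIDIC_POOL + _BASIC_POOL + _POLAR_POOL

# ideal α-helix geometry for the Cα trace
_HELIX_RADIUS = 2.3       # Å
_HELIX_RISE = 1.5         # Å per residue
_HELIX_TWIST = 100.0      # degrees per residue


def _helix_residue_atoms(
    name: str, index: int, origin: np.ndarray, invert: bool,
    rng: np.random.Generator,
) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Place backbone + side-chain atoms for one pseudo-helical residue."""
    theta = math.radians(_HELIX_TWIST * index)
    u = np.array([math.cos(theta), math.sin(theta), 0.0])  # radial
    v = np.array([-math.sin(theta), math.cos(theta), 0.0])  # tangential
    w = np.array([0.0, 0.0, 1.0])
    if invert:
        # extended strand with side chains pointing toward -x (the protein)
        u = np.array([-1.0, 0.0, 0.0])
        v = np.array([0.0, 1.0, 0.0])
        ca = origin + np.array(
            [0.0, 0.8 * ((-1) ** index), _HELIX_RISE * index]
        )
    else:
        ca = origin + _HELIX_RADIUS * u + np.array(
            [0.0, 0.0, _HELIX_RISE * index]
        )
    names = ["N", "CA", "C", "O"]
    elements = ["N", "C", "C", "O"]
    coords = [
        ca - 0.6 * u - 1.0 * v - 0.5 * w,
        ca,
        ca - 0.6 * u + 1.0 * v + 0.5 * w,
        ca - 1.8 * u + 1.2 * v + 0.6 * w,
    ]
    for j, (nm, el) in enumerate(_SIDECHAINS[name]):
        # extend outward along u with small deterministic jitter
        jitter = 0.25 * rng.standard_normal(3)
        coords.append(
            ca + (1.5 + 1.1 * j) * u + 0.35 * ((-1) ** j) * v
            + 0.3 * math.sin(1.0 + j) * w + jitter
        )
        names.append(nm)
        elements.append(el)
    return tuple(names), tuple(elements), np.array(coords)


def make_toy_complex(
    n_protein: int, n_peptide: int, seed: int
) -> ResidueTopology:
    """Two-chain toy complex: chain A pseudo-helix, chain B extended peptide.

    Residue names are drawn so that chain A always contains at least one
    hydrophobic, one acidic, one basic and one H-bond-capable polar residue.
    Deterministic for a given seed.
    """
    if n_protein < 4:
        raise ValueError("n_protein must be >= 4")
    if n_peptide < 1:
        raise ValueError("n_peptide must be >= 1")
    rng = np.random.default_rng(seed)
    names = [
        rng.choice(_HYDROPHOBIC_POOL),
        rng.choice(_ACIDIC_POOL),
        rng.choice(_BASIC_POOL),
        rng.choice(_POLAR_POOL),
    ] + list(rng.choice(_FULL_POOL, size=n_protein - 4))
    names = [str(n) for n in rng.permutation(names)]
    pep_names = [str(n) for n in rng.choice(_FULL_POOL, size=n_peptide)]

    residues: list[Residue] = []
    coords: list[np.ndarray] = []
    for i, name in enumerate(names):
        an, el, xyz = _helix_residue_atoms(
            name, i, np.zeros(3), invert=False, rng=rng
        )
        residues.append(Residue("A", i + 1, name, an, el))
        coords.append(xyz)
    pep_origin = np.array(
        [7.0, 0.0, 0.5 * _HELIX_RISE * max(n_protein - n_peptide, 0)]
    )
    for i, name in enumerate(pep_names):
        an, el, xyz = _helix_residue_atoms(
            name, i, pep_origin, invert=True, rng=rng
        )
        residues.append(Residue("B", i + 1, name, an, el))
        coords.append(xyz)
    return ResidueTopology(residues, np.vstack(coords))


# ---------------------------------------------------------------------------
# Ensembles with planted modes
# ---------------------------------------------------------------------------


@dataclass
class EnsembleSpec:
    """Gaussian ensemble along orthonormal collective Cα modes.

    ``mode_directions`` are unit 3N vectors over the Cα coordinates (N = all
    residues, protein + peptide); ``mode_variances`` are their Å² amplitude
    variances, non-increasing. Every atom of a residue follows its Cα mode
    displacement rigidly; isotropic Gaussian noise of ``isotropic_noise_sd``
    Å is then added independently per atom coordinate.
    """

    n_residues_protein: int
    n_residues_peptide: int
    n_frames: int
    n_replicas: int
    mode_directions: Sequence[np.ndarray]
    mode_variances: Sequence[float]
    isotropic_noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        self.mode_directions = [
            np.asarray(m, dtype=float) for m in self.mode_directions
        ]
        self.mode_variances = list(self.mode_variances)
        if len(self.mode_directions) != len(self.mode_variances):
            raise ValueError("one variance per mode direction required")
        if any(v < 0 for v in self.mode_variances):
            raise ValueError("mode variances must be non-negative")
        for a, b in zip(self.mode_variances, self.mode_variances[1:]):
            if b > a + 1e-12:
                raise ValueError("mode variances must be non-increasing")
        k = len(self.mode_directions)
        if k:
            M = np.stack(self.mode_directions)
            gram = M @ M.T
            if not np.allclose(gram, np.eye(k), atol=1e-8):
                raise ValueError("mode directions must be orthonormal")

    @property
    def n_residues(self) -> int:
        return self.n_residues_protein + self.n_residues_peptide

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_residues_protein": self.n_residues_protein,
            "n_residues_peptide": self.n_residues_peptide,
            "n_frames": self.n_frames,
            "n_replicas": self.n_replicas,
            "mode_directions": [m.tolist() for m in self.mode_directions],
            "mode_variances": self.mode_variances,
            "isotropic_noise_sd": self.isotropic_noise_sd,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "EnsembleSpec":
        return cls(**json.loads(Path(path).read_text()))


def rigid_body_subspace(reference_ca: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6×3N) of rigid translations and infinitesimal
    rotations about the reference Cα centroid."""
    ref = np.asarray(reference_ca, dtype=float)
    n = ref.shape[0]
    centered = ref - ref.mean(axis=0)
    basis = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        basis.append(t.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        basis.append(np.cross(e, centered).ravel())
    Q, _ = np.linalg.qr(np.stack(basis, axis=1))
    return Q.T


def random_orthonormal_modes(
    reference_ca: np.ndarray, n_modes: int, seed: int,
    remove_rigid: bool = True,
) -> list[np.ndarray]:
    """Random orthonormal internal 3N collective modes.

    Rigid-body translations and rotations (about the reference Cα
    configuration) are projected out by default, so the planted modes
    survive least-squares superposition and can be recovered by PCA.
    """
    ref = np.asarray(reference_ca, dtype=float)
    n_ca = ref.shape[0]
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((3 * n_ca, n_modes))
    if remove_rigid:
        R = rigid_body_subspace(ref)
        A -= R.T @ (R @ A)
    Q, _ = np.linalg.qr(A)
    return [Q[:, k].copy() for k in range(n_modes)]


def sample_ensemble(
    topology: ResidueTopology, spec: EnsembleSpec
) -> list[ConformationalEnsemble]:
    """One Gaussian ensemble per replica (replica r seeded with seed + r)."""
    n_ca = topology.n_residues
    for m in spec.mode_directions:
        if m.shape != (3 * n_ca,):
            raise ValueError(
                f"mode dimensionality {m.shape} != (3*{n_ca},)"
            )
    ref = topology.coordinates
    # per-atom residue membership for rigid broadcast of Cα displacements
    res_of_atom = np.concatenate(
        [np.full(r.n_atoms, i) for i, r in enumerate(topology.residues)]
    )
    out: list[ConformationalEnsemble] = []
    for r in range(spec.n_replicas):
        rng = np.random.default_rng(spec.seed + r)
        frames = np.repeat(ref[None, :, :], spec.n_frames, axis=0)
        for mode, var in zip(spec.mode_directions, spec.mode_variances):
            amp = rng.normal(0.0, math.sqrt(var), size=spec.n_frames)
            disp = mode.reshape(n_ca, 3)  # per-residue displacement direction
            frames += amp[:, None, None] * disp[res_of_atom][None, :, :]
        if spec.isotropic_noise_sd > 0:
            frames += rng.normal(
                0.0, spec.isotropic_noise_sd, size=frames.shape
            )
        out.append(
            ConformationalEnsemble(topology, frames, replica=f"replica-{r}")
        )
    return out


# ---------------------------------------------------------------------------
# Contact streams
# ---------------------------------------------------------------------------


@dataclass
class ContactStreamSpec:
    """Bernoulli ground truth: (pair, class) → per-frame presence probability."""

    pair_probabilities: Mapping[tuple[tuple[str, str], str], float]
    n_frames: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for (pair, _cls), p in self.pair_probabilities.items():
            if pair[0] == pair[1]:
                raise ValueError(f"pair {pair} must reference distinct residues")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


def sample_contact_stream(
    spec: ContactStreamSpec,
) -> list[set[tuple[tuple[str, str], str]]]:
    """Per-frame interaction sets; each entry is present i.i.d. with its p."""
    rng = np.random.default_rng(spec.seed)
    keys = sorted(spec.pair_probabilities.keys())
    probs = np.array([spec.pair_probabilities[k] for k in keys])
    draws = rng.random((spec.n_frames, len(keys))) < probs[None, :]
    return [
        {keys[j] for j in np.nonzero(draws[f])[0]}
        for f in range(spec.n_frames)
    ]


def contact_stream_to_frame(
    stream: Sequence[set[tuple[tuple[str, str], str]]],
):
    """Long-format DataFrame (frame, chain_a, res_a, chain_b, res_b, class)."""
    import pandas as pd

    rows = []
    for f, frame_set in enumerate(stream):
        for pair, cls in sorted(frame_set):
            ca, ra = pair[0].split(":", 1)
            cb, rb = pair[1].split(":", 1)
            rows.append((f, ca, ra, cb, rb, cls))
    return pd.DataFrame(
        rows,
        columns=["frame", "chain_a", "res_a", "chain_b", "res_b", "class"],
    )


# ---------------------------------------------------------------------------
# Sensorgrams
# ---------------------------------------------------------------------------


@dataclass
class SensorgramSpec:
    """1:1 Langmuir ground truth for a multi-concentration titration.

    Defaults mirror a slow-on/fast-off CaM–peptide interaction: injections
    from the hundreds-of-nM to low-µM range followed for 60 s of association
    and 300 s of dissociation.
    """

    kon: float = 15e3           # M⁻¹ s⁻¹
    koff: float = 7.1e-3        # s⁻¹
    rmax: float = 100.0         # RU
    concentrations: Sequence[float] = (
        0.25e-6, 0.5e-6, 1.0e-6, 1.5e-6, 2.0e-6, 3.0e-6,
    )
    t_assoc: float = 60.0       # s
    t_dissoc: float = 300.0     # s
    sampling_dt: float = 0.5    # s
    noise_sd: float = 0.5       # RU
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("kon", "koff", "rmax", "t_assoc", "t_dissoc",
                     "sampling_dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be strictly positive")

    @property
    def kd(self) -> float:
        return self.koff / self.kon

    def to_json(self, path: str | Path) -> None:
        payload = dict(self.__dict__)
        payload["concentrations"] = list(self.concentrations)
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SensorgramSpec":
        return cls(**json.loads(Path(path).read_text()))


def simulate_sensorgram(spec: SensorgramSpec) -> list[Sensorgram]:
    """Noisy 1:1 Langmuir traces, one per analyte concentration.

    Association: R(t) = Req·(1 − e^(−kobs·t)), kobs = kon·C + koff,
    Req = Rmax·C/(C + KD). Dissociation continues from the association end
    value with R(t) = R_end·e^(−koff·(t − t_assoc)).
    """
    rng = np.random.default_rng(spec.seed)
    time = np.arange(
        0.0, spec.t_assoc + spec.t_dissoc + 0.5 * spec.sampling_dt,
        spec.sampling_dt,
    )
    out: list[Sensorgram] = []
    for conc in spec.concentrations:
        kobs = spec.kon * conc + spec.koff
        req = spec.rmax * conc / (conc + spec.kd)
        assoc = time < spec.t_assoc
        r = np.empty_like(time)
        r[assoc] = req * (1.0 - np.exp(-kobs * time[assoc]))
        r_end = req * (1.0 - math.exp(-kobs * spec.t_assoc))
        r[~assoc] = r_end * np.exp(-spec.koff * (time[~assoc] - spec.t_assoc))
        if spec.noise_sd > 0:
            r = r + rng.normal(0.0, spec.noise_sd, size=r.shape)
        out.append(
            Sensorgram(
                time=time,
                response=r,
                concentration=conc,
                assoc_start=0.0,
                assoc_end=spec.t_assoc,
                dissoc_end=time[-1],
            )
        )
    return out
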