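"""Fragment and ligand featurization.

Five descriptor encodings are supported for the catalyst fragments:

* one-hot — a purely categorical baseline;
* electrotopological-state (E-state) indices — Kier–Hall intrinsic states
  perturbed by graph-distance-weighted differences;
* Coulomb-matrix eigenvalues — a rotation/translation/permutation-invariant
  geometric encoding;
* ingested Mordred tables — precomputed externally, never computed here;
* ingested quantum-chemistry (DFT) summary tables — scalar molecular
  properties plus per-atom/per-mode arrays reduced to min/max/mean.

Fragment vectors are concatenated (arene block first, then linker block)
into whole-ligand vectors, and feature matrices are preprocessed by
z-scoring and Pearson decorrelation before surrogate fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .catalyst_space import MolecularGraph
from .errors import (
    EncodingMismatchError,
    SchemaError,
    ValidationError,
)

ANGSTROM_PER_BOHR = 0.529177210903

#: Bondi van der Waals radii (Angstrom) for elements common in ligands.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85,
    "I": 1.98, "Al": 1.84,
}

ATOMIC_NUMBERS = {
    "H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Al": 13, "Si": 14,
    "P": 15, "S": 16, "Cl": 17, "Br": 35, "I": 53,
}

ENCODINGS = ("one-hot", "estate", "coulomb", "mordred-ingest", "dft-ingest")


@dataclass(frozen=True)
class DescriptorVector:
    """A named, provenance-tagged feature vector for a fragment or ligand."""

    names: tuple[str, ...]
    values: np.ndarray
    encoding: str

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValidationError("names and values must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("descriptor names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("descriptor values must be finite")
        if self.encoding not in ENCODINGS:
            raise ValidationError(f"unknown encoding {self.encoding!r}")

    def __len__(self) -> int:
        return len(self.names)


def one_hot_encode(
    fragment_id: str, vocabulary: Sequence[str]
) -> DescriptorVector:
    """Binary indicator vector over an ordered fragment vocabulary."""
    if fragment_id not in vocabulary:
        raise ValidationError(f"fragment id {fragment_id!r} not in vocabulary")
    values = np.zeros(len(vocabulary))
    values[list(vocabulary).index(fragment_id)] = 1.0
    return DescriptorVector(
        names=tuple(f"is_{v}" for v in vocabulary),
        values=values,
        encoding="one-hot",
    )


def estate_indices(graph: MolecularGraph) -> np.ndarray:
    """Electrotopological-state index S_i per heavy atom.

    Intrinsic state I_i = ((2/L_i)^2 * dv_i + 1) / d_i with L the principal
    quantum number, dv the (hydrogen-suppressed) valence-electron count and
    d the heavy-atom degree; the field effect of atom j on atom i is
    (I_i - I_j) / r_ij^2 with r_ij = graph distance + 1.  Because the
    pairwise perturbations are antisymmetric, sum(S) == sum(I).
    """
    n = len(graph.atoms)
    degrees = np.array([graph.degree(i) for i in range(n)], dtype=float)
    if np.any(degrees == 0) and n > 1:
        raise ValidationError("isolated atom: intrinsic state undefined")
    intrinsic = np.empty(n)
    for i, atom in enumerate(graph.atoms):
        delta = degrees[i] if degrees[i] > 0 else 1.0  # lone atom: S = I
        dv = atom.valence_electrons
        L = atom.principal_quantum_number
        intrinsic[i] = ((2.0 / L) ** 2 * dv + 1.0) / delta
    if n == 1:
        return intrinsic.copy()

    rows = [a for a, b in graph.bonds] + [b for a, b in graph.bonds]
    cols = [b for a, b in graph.bonds] + [a for a, b in graph.bonds]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    dist = shortest_path(adj, method="D", unweighted=True)
    if np.any(np.isinf(dist)):
        raise ValidationError("molecular graph must be connected")

    s = intrinsic.copy()
    r = dist + 1.0
    np.fill_diagonal(r, np.inf)
    s += ((intrinsic[:, None] - intrinsic[None, :]) / r**2).sum(axis=1)
    return s


def coulomb_matrix(
    atomic_numbers: Sequence[int],
    coords: np.ndarray,
    units: str = "angstrom",
) -> np.ndarray:
    """Coulomb matrix M_ii = 0.5 Z_i^2.4, M_ij = Z_i Z_j / |R_i - R_j|.

    Distances are taken in atomic units (bohr); pass ``units="bohr"`` if
    the coordinates are already atomic.
    """
    z = np.asarray(atomic_numbers, dtype=float)
    pos = np.asarray(coords, dtype=float).reshape(len(z), 3)
    if units == "angstrom":
        pos = pos / ANGSTROM_PER_BOHR
    elif units != "bohr":
        raise ValidationError(f"unknown units {units!r}")
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    off_diagonal = ~np.eye(len(z), dtype=bool)
    if np.any(dist[off_diagonal] == 0.0):
        raise ValidationError("coincident atoms give a singular distance")
    with np.errstate(divide="ignore"):
        m = np.where(dist > 0, np.outer(z, z) / np.where(dist > 0, dist, 1.0), 0.0)
    np.fill_diagonal(m, 0.5 * z**2.4)
    return m


def coulomb_eigenvalues(
    atomic_numbers: Sequence[int],
    coords: np.ndarray,
    pad_to: int | None = None,
    units: str = "angstrom",
) -> np.ndarray:
    """Descending, zero-padded eigenvalue spectrum of the Coulomb matrix.

    The spectrum is invariant to rigid rotation/translation and to atom
    permutation, which makes it a fixed-length geometric fingerprint.
    """
    n = len(atomic_numbers)
    if n < 1:
        raise ValidationError("need at least one atom")
    if pad_to is None:
        pad_to = n
    if pad_to < n:
        raise ValidationError(f"pad_to={pad_to} smaller than atom count {n}")
    eig = np.linalg.eigvalsh(coulomb_matrix(atomic_numbers, coords, units))
    eig = np.sort(eig)[::-1]
    return np.concatenate([eig, np.zeros(pad_to - n)])


def read_xyz(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read an XYZ file; returns (element symbols, coords in Angstrom)."""
    from rdkit import Chem

    mol = Chem.MolFromXYZFile(str(path))
    if mol is None:
        raise SchemaError(f"{path}: not a readable XYZ file")
    elements = [atom.GetSymbol() for atom in mol.GetAtoms()]
    coords = mol.GetConformer().GetPositions()
    return elements, np.asarray(coords, dtype=float)


def buried_volume(
    elements: Sequence[str],
    coords: np.ndarray,
    center: Sequence[float] | None = None,
    sphere_radius: float = 3.5,
    grid_spacing: float = 0.05,
    radii: Mapping[str, float] | None = None,
) -> float:
    """Percent buried volume (%V_bur) of a probe sphere, by grid integration.

    The fraction of a probe sphere (radius ``sphere_radius`` Angstrom,
    centered on the metal-binding site or, by default, the atom centroid)
    overlapped by the atoms' van der Waals spheres (Bondi radii, hydrogens
    included, no scaling). Evaluated on a regular cubic grid; halving the
    spacing moves the result by well under half a percentage point.
    """
    if sphere_radius <= 0:
        raise ValidationError("sphere_radius must be positive")
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(coords) == 0:
        return 0.0
    if len(coords) != len(elements):
        raise ValidationError("elements and coords length mismatch")
    table = dict(BONDI_RADII)
    if radii:
        table.update(radii)
    try:
        atom_radii = np.array([table[el] for el in elements])
    except KeyError as exc:
        raise ValidationError(f"no van der Waals radius for element {exc}") from exc
    c = (
        coords.mean(axis=0)
        if center is None
        else np.asarray(center, dtype=float)
    )

    ax = np.arange(-sphere_radius, sphere_radius + grid_spacing / 2, grid_spacing)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    inside = (pts**2).sum(axis=1) <= sphere_radius**2
    pts = pts[inside] + c
    buried = np.zeros(len(pts), dtype=bool)
    for pos, r in zip(coords, atom_radii):
        # skip atoms that cannot reach the probe sphere
        if np.linalg.norm(pos - c) > sphere_radius + r:
            continue
        buried |= ((pts - pos) ** 2).sum(axis=1) <= r**2
    return 100.0 * buried.mean()


def aggregate_atomic(values: Sequence[float], stat: str) -> float:
    """Reduce a per-atom or per-mode array to one of min/max/mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot aggregate an empty value list")
    if stat == "min":
        return float(arr.min())
    if stat == "max":
        return float(arr.max())
    if stat == "mean":
        return float(arr.mean())
    raise ValidationError(f"unknown statistic {stat!r}")


def derive_electronic(e_homo: float, e_lumo: float) -> tuple[float, float]:
    """Mulliken electronegativity and chemical hardness from frontier orbitals.

    EN = -(E_HOMO + E_LUMO)/2; hardness = (E_LUMO - E_HOMO)/2 >= 0.
    """
    if e_lumo < e_homo:
        raise ValidationError("E_LUMO must be >= E_HOMO")
    return -(e_homo + e_lumo) / 2.0, (e_lumo - e_homo) / 2.0


#: Scalar fields expected in an ingested quantum-chemistry summary table.
DFT_SCALAR_FIELDS = (
    "n_atoms",
    "charge",
    "spin_multiplicity",
    "dipole",
    "e_homo",
    "e_lumo",
)

#: Array fields reduced to min/max/mean features.
DFT_ARRAY_FIELDS = ("vbur", "mulliken", "apt_charge", "freq")


def ingest_dft_table(
    table: Mapping[str, object],
    scalar_fields: Sequence[str] = DFT_SCALAR_FIELDS,
    array_fields: Sequence[str] = DFT_ARRAY_FIELDS,
) -> DescriptorVector:
    """Flatten a per-fragment quantum-chemistry summary into a vector.

    Scalars pass through; electronegativity and hardness are derived from
    the frontier orbital energies; per-atom/per-mode arrays are reduced to
    min/max/mean with systematic names. Name order is deterministic.
    """
    names: list[str] = []
    values: list[float] = []
    for fld in scalar_fields:
        if fld not in table:
            raise SchemaError(f"missing field {fld!r} in descriptor table")
        val = float(table[fld])  # type: ignore[arg-type]
        if not np.isfinite(val):
            raise ValidationError(f"field {fld!r} is not finite")
        names.append(fld)
        values.append(val)
    if "e_homo" in scalar_fields and "e_lumo" in scalar_fields:
        en, hardness = derive_electronic(
            float(table["e_homo"]), float(table["e_lumo"])  # type: ignore[arg-type]
        )
        names += ["en", "hardness"]
        values += [en, hardness]
    for fld in array_fields:
        if fld not in table:
            raise SchemaError(f"missing field {fld!r} in descriptor table")
        arr = np.asarray(table[fld], dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"array field {fld!r} contains non-finite values")
        for stat in ("min", "max", "mean"):
            names.append(f"{fld}_{stat}")
            values.append(aggregate_atomic(arr, stat))
    return DescriptorVector(
        names=tuple(names), values=np.array(values), encoding="dft-ingest"
    )


def concatenate_fragments(
    a_vec: DescriptorVector, bc_vec: DescriptorVector
) -> DescriptorVector:
    """Whole-ligand vector: arene block first, linker block second.

    Names are prefixed with the fragment of origin so that attribution can
    trace each feature back to the arene or the linker.
    """
    if a_vec.encoding != bc_vec.encoding:
        raise EncodingMismatchError(
            f"cannot concatenate encodings {a_vec.encoding!r} and "
            f"{bc_vec.encoding!r}"
        )
    return DescriptorVector(
        names=tuple(f"A:{n}" for n in a_vec.names)
        + tuple(f"BC:{n}" for n in bc_vec.names),
        values=np.concatenate([a_vec.values, bc_vec.values]),
        encoding=a_vec.encoding,
    )


def ligand_feature_frame(
    ligands: Sequence, a_table: pd.DataFrame, bc_table: pd.DataFrame
) -> pd.DataFrame:
    """Concatenated per-ligand features from per-fragment descriptor tables.

    Both tables are indexed by fragment id; columns become ``A:<name>`` and
    ``BC:<name>`` blocks, rows are keyed by ligand id.
    """
    rows = {}
    for lg in ligands:
        if lg.a_id not in a_table.index:
            raise SchemaError(f"no descriptors for arene {lg.a_id!r}")
        if lg.bc_id not in bc_table.index:
            raise SchemaError(f"no descriptors for linker {lg.bc_id!r}")
        a = a_table.loc[lg.a_id]
        bc = bc_table.loc[lg.bc_id]
        rows[lg.id] = pd.concat(
            [a.add_prefix("A:"), bc.add_prefix("BC:")]
        )
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class Preprocessor:
    """Fitted normalize-and-decorrelate transform for feature matrices.

    Stores the training-set column statistics and the kept/dropped column
    ledger so that new candidate rows are transformed with *training*
    statistics, never their own.
    """

    kept: list[str]
    dropped_constant: list[str]
    dropped_correlated: list[tuple[str, str, float]]  # (dropped, kept, r)
    means: dict[str, float]
    scales: dict[str, float]
    corr_threshold: float

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.kept if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing feature columns: {missing}")
        out = frame[self.kept].astype(float).copy()
        for col in self.kept:
            out[col] = (out[col] - self.means[col]) / self.scales[col]
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "kept": self.kept,
                "dropped_constant": self.dropped_constant,
                "dropped_correlated": [
                    list(t) for t in self.dropped_correlated
                ],
                "means": self.means,
                "scales": self.scales,
                "corr_threshold": self.corr_threshold,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "Preprocessor":
        d = json.loads(text)
        return cls(
            kept=d["kept"],
            dropped_constant=d["dropped_constant"],
            dropped_correlated=[tuple(t) for t in d["dropped_correlated"]],
            means=d["means"],
            scales=d["scales"],
            corr_threshold=d["corr_threshold"],
        )


@dataclass
class FeatureMatrix:
    """A preprocessed feature matrix plus the transform that produced it."""

    frame: pd.DataFrame
    preprocessor: Preprocessor | None = None

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


def preprocess(
    frame: pd.DataFrame, corr_threshold: float = 0.95
) -> FeatureMatrix:
    """Standardize and decorrelate a raw feature matrix.

    Zero-variance columns are dropped; the rest are z-scored (population
    statistics); then, scanning column pairs in load order, the later
    member of any pair with \\|Pearson r\\| above the threshold is dropped.
    The returned transform replays training statistics on new rows.
    """
    if len(frame) < 2:
        raise ValidationError("need at least 2 rows to standardize features")
    frame = frame.astype(float)
    means = frame.mean(axis=0)
    scales = frame.std(axis=0, ddof=0)
    constant = [c for c in frame.columns if scales[c] == 0.0 or not np.isfinite(scales[c])]
    cols = [c for c in frame.columns if c not in constant]
    z = (frame[cols] - means[cols]) / scales[cols]

    dropped_corr: list[tuple[str, str, float]] = []
    corr = z.corr().to_numpy() if cols else np.empty((0, 0))
    removed: set[str] = set()
    for i, ci in enumerate(cols):
        if ci in removed:
            continue
        for j in range(i + 1, len(cols)):
            cj = cols[j]
            if cj in removed:
                continue
            r = corr[i, j]
            if abs(r) > corr_threshold:
                removed.add(cj)
                dropped_corr.append((cj, ci, float(r)))
    kept = [c for c in cols if c not in removed]

    pre = Preprocessor(
        kept=kept,
        dropped_constant=constant,
        dropped_correlated=dropped_corr,
        means={c: float(means[c]) for c in kept},
        scales={c: float(scales[c]) for c in kept},
        corr_threshold=corr_threshold,
    )
    return FeatureMatrix(frame=pre.transform(frame), preprocessor=pre)
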