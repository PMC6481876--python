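"""Structure parsing, dataset filters, and descriptor (.inv) file I/O.

Structures (PDB/mmCIF) are read with gemmi; waters and hydrogens are
dropped.  Dataset filters follow the representative-set construction used
for the shape maps: chains shorter than 40 residues are removed, as are
chains whose C-alpha atoms fall apart into more than one single-linkage
cluster at a 9 Angstrom cutoff (a spatial gap).  Sequence-identity culling
is consumed as a precomputed keep-list, never computed here.

Descriptors are stored in a small text format (".inv"): optional '#'
comment lines, a count line, then one invariant per line.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import gemmi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .zernike import ZernikeDescriptor, invariant_count, nl_index_map

__all__ = [
    "AtomSet",
    "read_structure",
    "spatial_gap_clusters",
    "chain_passes_filters",
    "read_annotations",
    "write_inv",
    "read_inv",
    "MIN_CHAIN_LENGTH",
    "GAP_CUTOFF",
]

ANNOTATION_COLUMNS = ("id", "n_domains", "length", "oligomeric_state",
                      "symmetry")

MIN_CHAIN_LENGTH = 40   # residues; shorter chains are filtered out
GAP_CUTOFF = 9.0        # Angstrom; C-alpha single-linkage clustering cutoff
_INV_DECIMALS = 6


@dataclass
class AtomSet:
    """Labeled atomic point cloud (coordinates in Angstrom)."""

    coordinates: np.ndarray
    elements: np.ndarray
    radii: np.ndarray
    chain_ids: np.ndarray
    residue_indices: np.ndarray
    residue_names: np.ndarray
    ca_mask: np.ndarray | None = None  # True where the atom is a C-alpha

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if len(self.coordinates) == 0:
            raise ValueError("atom set must contain at least one atom")
        if np.any(np.asarray(self.radii, dtype=float) <= 0):
            raise ValueError("van der Waals radii must be positive")

    def __len__(self) -> int:
        return len(self.coordinates)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c))
        return list(seen)

    def select_chain(self, chain_id: str) -> "AtomSet":
        mask = self.chain_ids == chain_id
        if not mask.any():
            raise ValueError(f"no atoms in chain {chain_id!r}")
        return AtomSet(
            coordinates=self.coordinates[mask],
            elements=self.elements[mask],
            radii=self.radii[mask],
            chain_ids=self.chain_ids[mask],
            residue_indices=self.residue_indices[mask],
            residue_names=self.residue_names[mask],
            ca_mask=None if self.ca_mask is None else self.ca_mask[mask],
        )


def _collect_atoms(model: gemmi.Model) -> AtomSet:
    coords, elements, radii, chains, res_idx, res_names = [], [], [], [], [], []
    ca_flags = []
    for chain in model:
        for residue in chain:
            if residue.is_water():
                continue
            for atom in residue:
                if atom.element == gemmi.Element("H") or atom.element == gemmi.Element("D"):
                    continue
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                elements.append(atom.element.name)
                radii.append(float(atom.element.vdw_r))
                chains.append(chain.name)
                res_idx.append(residue.seqid.num)
                res_names.append(residue.name)
                ca_flags.append(atom.name == "CA" and atom.element == gemmi.Element("C"))
    if not coords:
        raise ValueError("no non-hydrogen, non-water atoms in selection")
    return AtomSet(
        coordinates=np.array(coords),
        elements=np.array(elements),
        radii=np.array(radii),
        chain_ids=np.array(chains),
        residue_indices=np.array(res_idx),
        residue_names=np.array(res_names),
        ca_mask=np.array(ca_flags, dtype=bool),
    )


def read_structure(path, model: int = 1, assembly: bool = False) -> AtomSet:
    """Read a PDB or mmCIF file into an AtomSet.

    ``model`` is the 1-based model number; with ``assembly=True`` the first
    biological assembly annotated in the file is expanded (chain copies get
    distinct ids), mirroring the use of first biological units for complex
    analysis.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}")
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"structure file {path} contains no models")
    if model < 1 or model > len(st):
        raise ValueError(f"model {model} out of range (file has {len(st)} models)")
    gmodel = st[model - 1]
    if assembly:
        if len(st.assemblies) == 0:
            raise ValueError(f"{path} declares no biological assembly")
        gmodel = gemmi.make_assembly(
            st.assemblies[0], gmodel, gemmi.HowToNameCopiedChain.AddNumber)
    return _collect_atoms(gmodel)


def _ca_coords(atoms: AtomSet) -> np.ndarray:
    if atoms.ca_mask is None:
        # pseudo-atom sets carry no C-alpha labels: use every atom as marker
        return atoms.coordinates
    return atoms.coordinates[atoms.ca_mask]


def spatial_gap_clusters(atoms: AtomSet, cutoff: float = GAP_CUTOFF) -> int:
    """Number of single-linkage clusters of C-alpha atoms at ``cutoff``.

    Two C-alphas closer than ``cutoff`` are linked; the cluster count is the
    number of connected components.  More than one cluster means the chain
    has a spatial gap.
    """
    ca = _ca_coords(atoms)
    if len(ca) == 0:
        raise ValueError("no C-alpha atoms for gap clustering")
    if not np.isfinite(cutoff):
        return 1
    pairs = cKDTree(ca).query_pairs(cutoff, output_type="ndarray")
    # strictly-closer-than linkage: drop pairs at exactly the cutoff
    if len(pairs):
        d = np.linalg.norm(ca[pairs[:, 0]] - ca[pairs[:, 1]], axis=1)
        pairs = pairs[d < cutoff]
    n = len(ca)
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    count, _ = connected_components(adj, directed=False)
    return int(count)


def chain_passes_filters(atoms: AtomSet, min_len: int = MIN_CHAIN_LENGTH,
                         gap_cutoff: float = GAP_CUTOFF) -> bool:
    """Representative-set filter for a single chain.

    True iff the chain has at least ``min_len`` residues with a C-alpha atom
    and its C-alphas form a single spatial cluster at ``gap_cutoff``.
    """
    if len(atoms.chains) != 1:
        raise ValueError("chain filter expects a single-chain atom set")
    mask = atoms.ca_mask if atoms.ca_mask is not None else np.ones(len(atoms), dtype=bool)
    n_residues = len(set(zip(atoms.chain_ids[mask].tolist(),
                             atoms.residue_indices[mask].tolist())))
    if n_residues < min_len:
        return False
    return spatial_gap_clusters(atoms, cutoff=gap_cutoff) == 1


def read_annotations(path):
    """Read a per-structure annotation table (CSV) used for map coloring.

    Expected columns: id, n_domains, length, oligomeric_state, symmetry.
    Annotations are external inputs (domain counts, oligomeric states and
    symmetry assignments come from curated resources); they are consumed,
    never computed.  Returns a DataFrame indexed by id.
    """
    import pandas as pd

    table = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"annotation table {path} lacks columns: {missing}")
    return table.set_index("id")


def write_inv(desc: ZernikeDescriptor, path) -> None:
    """Write a descriptor as text: '#' comments, count line, one value/line."""
    path = Path(path)
    lines = [f"# 3D Zernike descriptor, order {desc.n_max}",
             str(len(desc.values))]
    lines += [f"{v:.{_INV_DECIMALS}f}" for v in desc.values]
    path.write_text("\n".join(lines) + "\n")


def read_inv(path) -> ZernikeDescriptor:
    """Read an .inv descriptor file written by :func:`write_inv`."""
    path = Path(path)
    order = None
    data: list[float] = []
    count = None
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "order" in line:
                try:
                    order = int(line.rsplit(None, 1)[-1])
                except ValueError:
                    pass
            continue
        try:
            value = float(line)
        except ValueError:
            raise ValueError(f"non-numeric line in {path}: {line!r}")
        if count is None:
            count = int(value)
            if count != value or count <= 0:
                raise ValueError(f"invalid count line in {path}: {line!r}")
        else:
            data.append(value)
    if count is None:
        raise ValueError(f"{path} has no count line")
    if len(data) != count:
        raise ValueError(
            f"{path}: count line says {count} values but found {len(data)}")
    if order is None:
        order = next((n for n in range(0, 101) if invariant_count(n) == count), None)
        if order is None:
            raise ValueError(f"{path}: cannot infer order from {count} values")
    if invariant_count(order) != count:
        raise ValueError(f"{path}: {count} values inconsistent with order {order}")
    return ZernikeDescriptor(n_max=order, values=np.array(data),
                             index_map=nl_index_map(order))
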