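"""Structure-derived descriptor schemes for protein-ligand complexes.

Three schemes are implemented:

``rf_v1``
    The 36 intermolecular atom-pair distance counts of the original
    RF-Score: for each ordered pair of a ligand element in
    {C, N, O, F, P, S, Cl, Br, I} and a protein element in {C, N, O, S},
    the number of protein-ligand atom pairs whose centres lie within a
    cutoff (default 12 angstroms).  Counts are integers and invariant to
    rigid motion and atom reordering by construction.

``vina6``
    Six empirical terms in the AutoDock Vina family, evaluated on the
    surface distance d = r - R_i - R_j (centre distance minus van der
    Waals radii) for every heavy-atom pair within 8 angstroms, plus the
    ligand rotatable-bond count:

    - gauss1      = exp(-(d / 0.5)^2)
    - gauss2      = exp(-((d - 3) / 2)^2)
    - repulsion   = d^2 for d < 0, else 0
    - hydrophobic = linear ramp 1 -> 0 for d in [0.5, 1.5], C-C pairs only
    - hbond       = linear ramp 1 -> 0 for d in [-0.7, 0], N/O-N/O pairs
    - nrot        = rotatable-bond count of the ligand

``xscore4``
    A four-term surrogate of the X-Score energy terms: an 8-4
    Lennard-Jones-like van der Waals sum, a distance-count hydrogen-bond
    term, a distance-count hydrophobic-contact term, and the ligand
    rotatable-bond count.  It reproduces the *shape* of an empirical
    classical scoring function, not any published parametrisation.

``rf_v3`` is the concatenation rf_v1 + vina6 (42 features).

All pair terms are computed with a vectorised double loop that is exactly
equivalent (same arithmetic, same closed <= boundary) to the brute-force
reference evaluation.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .structio import MolecularStructure, count_rotatable_bonds

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorVector",
    "DescriptorTable",
    "LIGAND_ELEMENTS",
    "PROTEIN_ELEMENTS",
    "VDW_RADII",
    "DEFAULT_RADIUS",
    "RF_V1_CUTOFF",
    "SCHEME_FEATURES",
    "rf_v1_counts",
    "vina_terms",
    "rf_v3_descriptors",
    "xscore_like_terms",
    "load_descriptor_table",
    "write_descriptor_table",
]

#: ligand element set of the rf_v1 pair counts (uppercase symbols)
LIGAND_ELEMENTS = ("C", "N", "O", "F", "P", "S", "CL", "BR", "I")
#: protein element set of the rf_v1 pair counts
PROTEIN_ELEMENTS = ("C", "N", "O", "S")
#: default centre-distance cutoff for rf_v1 counts, angstroms
RF_V1_CUTOFF = 12.0
#: centre-distance evaluation cutoff for the empirical pair terms, angstroms
PAIR_TERM_CUTOFF = 8.0

#: van der Waals radii (angstroms) used for surface distances
VDW_RADII = {
    "C": 1.9, "N": 1.8, "O": 1.7, "S": 2.0, "P": 2.1,
    "F": 1.5, "CL": 1.8, "BR": 2.0, "I": 2.2,
}
DEFAULT_RADIUS = 1.8

RF_V1_FEATURES = tuple(f"{le}_{pe}" for le in LIGAND_ELEMENTS for pe in PROTEIN_ELEMENTS)
VINA_FEATURES = ("gauss1", "gauss2", "repulsion", "hydrophobic", "hbond", "nrot")
XSCORE_FEATURES = ("vdw", "hbond", "hydrophobic", "rotor")

SCHEME_FEATURES: dict[str, tuple[str, ...]] = {
    "rf_v1": RF_V1_FEATURES,
    "vina6": VINA_FEATURES,
    "rf_v3": RF_V1_FEATURES + VINA_FEATURES,
    "xscore4": XSCORE_FEATURES,
}


@dataclass(frozen=True)
class DescriptorVector:
    """Named, ordered feature values computed under one scheme."""

    scheme: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")
        expected = SCHEME_FEATURES.get(self.scheme)
        if expected is not None and self.names != expected:
            raise ValueError(f"feature names do not match scheme {self.scheme!r}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def _pair_geometry(protein: MolecularStructure, ligand: MolecularStructure):
    """Squared centre distances (n_protein x n_ligand) and element arrays."""
    pc = protein.coords_array()
    lc = ligand.coords_array()
    diff = pc[:, None, :] - lc[None, :, :]
    d2 = (diff ** 2).sum(axis=-1)
    return d2, np.array(protein.elements), np.array(ligand.elements)


def rf_v1_counts(
    protein: MolecularStructure,
    ligand: MolecularStructure,
    cutoff: float = RF_V1_CUTOFF,
) -> DescriptorVector:
    """The 36 intermolecular atom-pair counts within ``cutoff`` angstroms.

    Pairs are counted when the centre distance is <= cutoff (closed
    boundary).  Atoms whose element lies outside the ligand or protein
    element set contribute nothing.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if not len(protein) or not len(ligand):
        raise ValueError("both structures must be nonempty")
    d2, pel, lel = _pair_geometry(protein, ligand)
    within = d2 <= cutoff * cutoff
    lig_idx = {el: k for k, el in enumerate(LIGAND_ELEMENTS)}
    pro_idx = {el: k for k, el in enumerate(PROTEIN_ELEMENTS)}
    counts = np.zeros((len(LIGAND_ELEMENTS), len(PROTEIN_ELEMENTS)), dtype=int)
    for p in range(len(pel)):
        pk = pro_idx.get(pel[p])
        if pk is None:
            continue
        for l in range(len(lel)):
            lk = lig_idx.get(lel[l])
            if lk is None:
                continue
            if within[p, l]:
                counts[lk, pk] += 1
    return DescriptorVector("rf_v1", RF_V1_FEATURES, counts.ravel().astype(float))


def _radii_for(elements: np.ndarray) -> np.ndarray:
    radii = np.empty(len(elements))
    for k, el in enumerate(elements):
        r = VDW_RADII.get(el)
        if r is None:
            logger.warning("no van der Waals radius for element %s; using %.1f", el, DEFAULT_RADIUS)
            r = DEFAULT_RADIUS
        radii[k] = r
    return radii


def vina_terms(protein: MolecularStructure, ligand: MolecularStructure) -> DescriptorVector:
    """Six Vina-family empirical terms (five pair sums plus nrot).

    Pair terms run over every protein-ligand heavy-atom pair with centre
    distance <= 8 angstroms, on the surface distance d = r - R_i - R_j.
    """
    if mol_missing_bonds(ligand):
        raise ValueError("ligand has no bond list; nrot is undefined")
    d2, pel, lel = _pair_geometry(protein, ligand)
    r = np.sqrt(d2)
    mask = r <= PAIR_TERM_CUTOFF
    pr = _radii_for(pel)
    lr = _radii_for(lel)
    d = r - pr[:, None] - lr[None, :]

    gauss1 = np.where(mask, np.exp(-((d / 0.5) ** 2)), 0.0).sum()
    gauss2 = np.where(mask, np.exp(-(((d - 3.0) / 2.0) ** 2)), 0.0).sum()
    repulsion = np.where(mask & (d < 0), d * d, 0.0).sum()

    carbon = (pel == "C")[:, None] & (lel == "C")[None, :]
    hydro = np.clip((1.5 - d) / 1.0, 0.0, 1.0)
    hydrophobic = np.where(mask & carbon, hydro, 0.0).sum()

    polar = np.isin(pel, ("N", "O"))[:, None] & np.isin(lel, ("N", "O"))[None, :]
    hb = np.clip(-d / 0.7, 0.0, 1.0)
    hbond = np.where(mask & polar, hb, 0.0).sum()

    nrot = float(count_rotatable_bonds(ligand))
    values = np.array([gauss1, gauss2, repulsion, hydrophobic, hbond, nrot])
    return DescriptorVector("vina6", VINA_FEATURES, values)


def rf_v3_descriptors(
    protein: MolecularStructure,
    ligand: MolecularStructure,
    cutoff: float = RF_V1_CUTOFF,
) -> DescriptorVector:
    """Concatenation of the 36 pair counts and the 6 empirical terms."""
    counts = rf_v1_counts(protein, ligand, cutoff)
    vina = vina_terms(protein, ligand)
    return DescriptorVector(
        "rf_v3",
        RF_V1_FEATURES + VINA_FEATURES,
        np.concatenate([counts.values, vina.values]),
    )


def xscore_like_terms(protein: MolecularStructure, ligand: MolecularStructure) -> DescriptorVector:
    """Four-term classical-scoring surrogate (vdw, hbond, hydrophobic, rotor).

    vdw sums, over pairs within 8 angstroms, the 8-4 potential
    ``(d0/r)^8 - 2 (d0/r)^4`` with d0 the sum of the two van der Waals
    radii, clamping each pair's contribution to [-1, 10] to avoid
    singularities at near-zero separations.  hbond counts N/O-N/O pairs
    within 3.5 angstroms; hydrophobic counts C-C pairs within 4.5
    angstroms; rotor is the ligand rotatable-bond count.
    """
    if mol_missing_bonds(ligand):
        raise ValueError("ligand has no bond list; rotor is undefined")
    d2, pel, lel = _pair_geometry(protein, ligand)
    r = np.sqrt(d2)
    mask = r <= PAIR_TERM_CUTOFF
    d0 = _radii_for(pel)[:, None] + _radii_for(lel)[None, :]
    with np.errstate(divide="ignore", over="ignore"):
        ratio4 = (d0 / np.where(r > 0, r, np.inf)) ** 4
        pair_vdw = np.clip(ratio4 * ratio4 - 2.0 * ratio4, -1.0, 10.0)
    vdw = np.where(mask, pair_vdw, 0.0).sum()

    polar = np.isin(pel, ("N", "O"))[:, None] & np.isin(lel, ("N", "O"))[None, :]
    hbond = float((polar & (r <= 3.5)).sum())
    carbon = (pel == "C")[:, None] & (lel == "C")[None, :]
    hydrophobic = float((carbon & (r <= 4.5)).sum())
    rotor = float(count_rotatable_bonds(ligand))
    return DescriptorVector("xscore4", XSCORE_FEATURES, np.array([vdw, hbond, hydrophobic, rotor]))


def mol_missing_bonds(mol: MolecularStructure) -> bool:
    return mol.bonds is None


def compute_descriptors(
    protein: MolecularStructure,
    ligand: MolecularStructure,
    scheme: str,
    cutoff: float = RF_V1_CUTOFF,
) -> DescriptorVector:
    """Dispatch to the named scheme."""
    if scheme == "rf_v1":
        return rf_v1_counts(protein, ligand, cutoff)
    if scheme == "vina6":
        return vina_terms(protein, ligand)
    if scheme == "rf_v3":
        return rf_v3_descriptors(protein, ligand, cutoff)
    if scheme == "xscore4":
        return xscore_like_terms(protein, ligand)
    raise ValueError(f"unknown descriptor scheme {scheme!r}")


class DescriptorTable:
    """A set of complexes' descriptor vectors under one scheme.

    Backed by a pandas DataFrame indexed by complex id, with one column
    per feature and an optional ``affinity`` column in pKd units.
    """

    def __init__(self, frame: pd.DataFrame, scheme: str):
        expected = SCHEME_FEATURES.get(scheme)
        feature_cols = [c for c in frame.columns if c != "affinity"]
        if expected is not None and tuple(feature_cols) != expected:
            raise ValueError(f"columns do not match scheme {scheme!r}")
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()][0]
            raise ValueError(f"duplicate complex id {dup!r}")
        if frame.isna().any().any():
            raise ValueError("missing values in descriptor table")
        self.frame = frame
        self.scheme = scheme
        self.feature_names = tuple(feature_cols)

    @classmethod
    def from_vectors(
        cls,
        ids: Sequence[str],
        vectors: Sequence[DescriptorVector],
        affinities: Mapping[str, float] | None = None,
    ) -> "DescriptorTable":
        if not vectors:
            raise ValueError("no descriptor vectors given")
        scheme = vectors[0].scheme
        if any(v.scheme != scheme for v in vectors):
            raise ValueError("mixed schemes in one table")
        frame = pd.DataFrame(
            np.vstack([v.values for v in vectors]),
            index=pd.Index(ids, name="id"),
            columns=list(vectors[0].names),
        )
        if affinities is not None:
            frame["affinity"] = [affinities[i] for i in ids]
        return cls(frame, scheme)

    @property
    def ids(self) -> list:
        return list(self.frame.index)

    @property
    def has_affinity(self) -> bool:
        return "affinity" in self.frame.columns

    def features(self) -> pd.DataFrame:
        return self.frame[list(self.feature_names)]

    def affinities(self) -> pd.Series:
        if not self.has_affinity:
            raise ValueError("table has no affinity column")
        return self.frame["affinity"]

    def subset(self, ids: Iterable) -> "DescriptorTable":
        return DescriptorTable(self.frame.loc[list(ids)], self.scheme)

    def __len__(self) -> int:
        return len(self.frame)


def load_descriptor_table(stream, scheme: str = "external") -> DescriptorTable:
    """Read a descriptor CSV (``id,<features...>[,affinity]``).

    Rejects duplicate ids (error names the id) and non-numeric or missing
    cells (error names row id and column).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    frame = pd.read_csv(stream, dtype=str)
    if "id" not in frame.columns:
        raise ValueError("descriptor CSV must have an 'id' column")
    frame = frame.set_index("id")
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicate complex id {dup!r}")
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() | frame[col].isna()
        if bad.any():
            row = frame.index[bad][0]
            raise ValueError(f"non-numeric or missing value at row {row!r}, column {col!r}")
        frame[col] = converted
    return DescriptorTable(frame, scheme)


def write_descriptor_table(table: DescriptorTable, stream) -> None:
    """Write the descriptor CSV dialect.

    Integer-valued count features are emitted as integers, real-valued
    terms with 6 significant digits; affinities keep full precision.
    """
    cols = list(table.feature_names) + (["affinity"] if table.has_affinity else [])
    stream.write("id," + ",".join(cols) + "\n")
    for cid, row in table.frame.iterrows():
        cells = []
        for col in cols:
            v = row[col]
            if col != "affinity" and float(v).is_integer():
                cells.append(str(int(v)))
            elif col == "affinity":
                cells.append(repr(float(v)))
            else:
                cells.append(f"{v:.6g}")
        stream.write(f"{cid}," + ",".join(cells) + "\n")
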