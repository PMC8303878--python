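"""Per-frame structural metrics.

Conventions:

* internal length unit is nm; SASA and residue distances are *reported* in
  angstrom-based units to match the usual tabulation of such quantities;
* RMSD is mass-unweighted and always follows an optimal least-squares rigid
  superposition (Kabsch, proper rotation enforced via the determinant
  correction); masses enter only the centre of mass and radius of gyration;
* the fraction of native contacts (FNC, often written as phi) uses a hard
  cutoff in the reference structure and a tolerance factor for formation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import biotite.structure as struc
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .core import Frame
from .errors import (
    DegenerateFitError,
    NotComputableError,
    StructureMismatchError,
    UndefinedFncError,
    ValidationError,
)

__all__ = [
    "ContactSet",
    "superpose",
    "rmsd",
    "lsq_rmsd_to_reference",
    "pairwise_lsq_rmsd",
    "native_contacts",
    "fraction_native_contacts",
    "radius_of_gyration",
    "sasa",
    "helix_content",
    "residue_distance",
    "lowess_smooth",
]

# Van der Waals radii in angstrom used for SASA
DEFAULT_VDW_RADII_A = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}

# alpha-helical (phi, psi) window in degrees and minimum run length
HELIX_PHI_RANGE = (-100.0, -30.0)
HELIX_PSI_RANGE = (-80.0, -5.0)
HELIX_MIN_RUN = 4


# ---------------------------------------------------------------------------
# superposition / RMSD


def _resolve_selection(frame: Frame, selection) -> np.ndarray:
    if selection is None:
        return np.arange(frame.n_atoms)
    sel = np.asarray(selection)
    if sel.dtype == bool:
        sel = np.flatnonzero(sel)
    return sel.astype(np.intp)


def _check_fit_geometry(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateFitError("superposition needs at least 3 atoms")
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-10 * max(s[0], 1e-30):
        raise DegenerateFitError("selection is collinear; rotation is not unique")


def superpose(mobile: Frame, reference: Frame, selection=None):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd_nm)`` such that
    ``rotation @ x + translation`` maps mobile coordinates onto the
    reference. The rotation is proper (det = +1, Kabsch determinant
    correction).
    """
    sel_m = _resolve_selection(mobile, selection)
    sel_r = _resolve_selection(reference, selection)
    if len(sel_m) != len(sel_r):
        raise StructureMismatchError("selections have different atom counts")
    P = mobile.coords[sel_m]
    Q = reference.coords[sel_r]
    _check_fit_geometry(P)
    _check_fit_geometry(Q)
    com_p = P.mean(axis=0)
    com_q = Q.mean(axis=0)
    Pc = P - com_p
    Qc = Q - com_q
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    n = P.shape[0]
    msd = ((Pc**2).sum() + (Qc**2).sum() - 2.0 * (S[0] + S[1] + d * S[2])) / n
    value = float(np.sqrt(max(msd, 0.0)))
    translation = com_q - R @ com_p
    return R, translation, value


def _pair_rmsd_value(P: np.ndarray, Q: np.ndarray) -> float:
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    S = np.linalg.svd(H, compute_uv=False)
    d = np.sign(np.linalg.det(H))
    n = P.shape[0]
    msd = ((Pc**2).sum() + (Qc**2).sum() - 2.0 * (S[0] + S[1] + d * S[2])) / n
    return float(np.sqrt(max(msd, 0.0)))


def rmsd(a: Frame, b: Frame, selection=None) -> float:
    """Least-squares-fit RMSD between two frames, in nm (symmetric).

    Unlike :func:`superpose`, this accepts collinear selections: the optimal
    rotation is then not unique, but the minimum RMSD value still is.
    """
    sel_a = _resolve_selection(a, selection)
    sel_b = _resolve_selection(b, selection)
    if len(sel_a) != len(sel_b):
        raise StructureMismatchError("selections have different atom counts")
    if len(sel_a) < 3:
        raise DegenerateFitError("superposition needs at least 3 atoms")
    return _pair_rmsd_value(a.coords[sel_a], b.coords[sel_b])


def _centered_with_norms(coords: np.ndarray):
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=1, keepdims=True)
    norms = np.einsum("fij,fij->f", centered, centered)
    return centered, norms


def lsq_rmsd_to_reference(coords: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Fit RMSD (nm) of each frame in ``coords`` (F, n, 3) to one reference."""
    centered, norms = _centered_with_norms(coords)
    ref_c = ref - ref.mean(axis=0)
    g_ref = float((ref_c**2).sum())
    H = np.einsum("fni,nj->fij", centered, ref_c)
    S = np.linalg.svd(H, compute_uv=False)
    sign = np.sign(np.linalg.det(H))
    n = coords.shape[1]
    msd = (norms + g_ref - 2.0 * (S[:, 0] + S[:, 1] + sign * S[:, 2])) / n
    return np.sqrt(np.clip(msd, 0.0, None))


def pairwise_lsq_rmsd(coords: np.ndarray, block_rows: int | None = None) -> np.ndarray:
    """All-against-all fit RMSD matrix (nm) over frames (F, n, 3).

    Uses a batched 3x3-SVD Kabsch evaluation; rows are processed in blocks
    to bound memory (the cross-correlation tensor is O(block * F * 9)).
    """
    centered, norms = _centered_with_norms(coords)
    F, n, _ = centered.shape
    if block_rows is None:
        block_rows = max(1, int(2.5e7 // max(F * 9, 1)))
    out = np.empty((F, F))
    for start in range(0, F, block_rows):
        stop = min(start + block_rows, F)
        H = np.einsum("bni,fnj->bfij", centered[start:stop], centered)
        S = np.linalg.svd(H, compute_uv=False)
        sign = np.sign(np.linalg.det(H))
        msd = (
            norms[start:stop, None]
            + norms[None, :]
            - 2.0 * (S[..., 0] + S[..., 1] + sign * S[..., 2])
        ) / n
        out[start:stop] = np.sqrt(np.clip(msd, 0.0, None))
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# native contacts


@dataclass
class ContactSet:
    """Native-contact pair list derived from one reference structure.

    ``pairs`` holds atom indices into the reference frame; members belong to
    residues at least ``min_sequence_separation`` apart (pairs across chains
    always qualify). ``reference_distances`` are the distances (nm) in the
    reference, all <= ``cutoff``.
    """

    pairs: np.ndarray  # (m, 2) int
    reference_distances: np.ndarray  # (m,) nm
    cutoff: float  # nm
    min_sequence_separation: int

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=np.intp).reshape(-1, 2)
        self.reference_distances = np.asarray(self.reference_distances, dtype=float)
        if len(self.pairs) != len(self.reference_distances):
            raise ValidationError("pairs and reference_distances lengths differ")
        if len(self.pairs):
            keys = {tuple(p) for p in self.pairs}
            if len(keys) != len(self.pairs):
                raise ValidationError("duplicate contact pairs")
            if np.any(self.reference_distances > self.cutoff + 1e-12):
                raise ValidationError("reference distance exceeds cutoff")

    def __len__(self) -> int:
        return len(self.pairs)


def _default_contact_selection(frame: Frame) -> np.ndarray:
    ca = np.flatnonzero(frame.topology.atom_names == "CA")
    return ca if len(ca) else np.arange(frame.n_atoms)


def native_contacts(
    reference: Frame,
    cutoff: float = 0.8,
    min_sequence_separation: int = 4,
    selection=None,
) -> ContactSet:
    """Enumerate native contacts in the reference structure.

    A contact is a pair of selected atoms (default: CA/bead atoms) whose
    residues are >= ``min_sequence_separation`` apart in sequence (or on
    different chains) and whose distance is <= ``cutoff`` nm. Pairs are
    returned in lexicographic index order.
    """
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    sel = (
        _default_contact_selection(reference)
        if selection is None
        else _resolve_selection(reference, selection)
    )
    if len(sel) == 0:
        return ContactSet(
            np.empty((0, 2), dtype=np.intp),
            np.empty(0),
            cutoff,
            min_sequence_separation,
        )
    coords = reference.coords[sel]
    res_ids = reference.topology.res_ids[sel]
    chains = reference.topology.chain_ids[sel]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    sep_ok = np.abs(res_ids[:, None] - res_ids[None, :]) >= min_sequence_separation
    sep_ok |= chains[:, None] != chains[None, :]
    upper = np.triu(np.ones_like(sep_ok, dtype=bool), k=1)
    mask = upper & sep_ok & (dist <= cutoff)
    ii, jj = np.nonzero(mask)
    pairs = np.stack([sel[ii], sel[jj]], axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return ContactSet(pairs[order], dist[ii, jj][order], cutoff, min_sequence_separation)


def fraction_native_contacts(
    frame: Frame, contacts: ContactSet, tolerance_factor: float = 1.2
) -> float:
    """Fraction phi in [0, 1] of native contacts formed in ``frame``.

    A contact counts as formed when its distance is
    <= ``tolerance_factor * cutoff``; by construction the reference frame
    itself scores 1.
    """
    if len(contacts) == 0:
        raise UndefinedFncError(
            "fraction of native contacts is undefined for an empty contact set"
        )
    a = frame.coords[contacts.pairs[:, 0]]
    b = frame.coords[contacts.pairs[:, 1]]
    d = np.sqrt(((a - b) ** 2).sum(-1))
    return float(np.mean(d <= tolerance_factor * contacts.cutoff))


def fnc_over_frames(
    coords: np.ndarray, contacts: ContactSet, tolerance_factor: float = 1.2
) -> np.ndarray:
    """Vectorized FNC for a coordinate stack (F, n, 3)."""
    if len(contacts) == 0:
        raise UndefinedFncError(
            "fraction of native contacts is undefined for an empty contact set"
        )
    a = coords[:, contacts.pairs[:, 0], :]
    b = coords[:, contacts.pairs[:, 1], :]
    d = np.sqrt(((a - b) ** 2).sum(-1))
    return (d <= tolerance_factor * contacts.cutoff).mean(axis=1)


# ---------------------------------------------------------------------------
# scalar descriptors


def radius_of_gyration(frame: Frame, selection=None) -> float:
    """Mass-weighted radius of gyration, nm."""
    sel = _resolve_selection(frame, selection)
    coords = frame.coords[sel]
    masses = frame.topology.effective_masses()[sel]
    com = np.average(coords, axis=0, weights=masses)
    sq = ((coords - com) ** 2).sum(-1)
    return float(np.sqrt(np.average(sq, weights=masses)))


def sasa(
    frame: Frame,
    probe_radius: float = 0.14,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> float:
    """Shrake-Rupley solvent-accessible surface area, reported in angstrom^2.

    ``probe_radius`` is in nm (default 0.14 nm ~ water); per-element van der
    Waals radii come from ``DEFAULT_VDW_RADII_A`` unless overridden (angstrom).
    """
    table = DEFAULT_VDW_RADII_A if radii is None else radii
    elements = frame.topology.elements
    unknown = sorted({str(e) for e in elements} - set(table))
    if unknown:
        raise ValidationError(f"no van der Waals radius for element(s): {unknown}")
    atom_radii = np.array([table[str(e)] for e in elements])
    # exactly coincident equal-radius atoms fully occlude one another, but the
    # surface-point inclusion test is strict on the boundary: collapse exact
    # duplicates so they contribute a single sphere
    key = np.concatenate([frame.coords, atom_radii[:, None]], axis=1)
    _, keep = np.unique(key, axis=0, return_index=True)
    keep = np.sort(keep)
    atom_radii = atom_radii[keep]
    array = struc.AtomArray(len(keep))
    array.coord = frame.coords[keep] * 10.0
    array.chain_id = frame.topology.chain_ids[keep]
    array.res_id = frame.topology.res_ids[keep]
    array.res_name = frame.topology.res_names[keep]
    array.atom_name = frame.topology.atom_names[keep]
    array.element = frame.topology.elements[keep]
    per_atom = struc.sasa(
        array,
        probe_radius=probe_radius * 10.0,
        point_number=n_points,
        vdw_radii=atom_radii,
        ignore_ions=False,
    )
    return float(np.nansum(per_atom))


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _backbone_dihedrals(frame: Frame) -> np.ndarray:
    """(phi, psi) per residue from N/CA/C atoms; NaN where undefined."""
    top = frame.topology
    keys = top.residue_keys()
    index: dict[tuple[str, int], dict[str, int]] = {k: {} for k in keys}
    for i, (c, r, name) in enumerate(zip(top.chain_ids, top.res_ids, top.atom_names)):
        index[(str(c), int(r))][str(name)] = i
    needed = {"N", "CA", "C"}
    if any(not needed <= set(atoms) for atoms in index.values()):
        raise NotComputableError(
            "helix content needs backbone N/CA/C atoms or planted dihedral metadata"
        )
    out = np.full((len(keys), 2), np.nan)
    X = frame.coords
    for i, key in enumerate(keys):
        atoms = index[key]
        if i > 0 and keys[i - 1][0] == key[0]:
            prev_c = X[index[keys[i - 1]]["C"]]
            out[i, 0] = _dihedral(prev_c, X[atoms["N"]], X[atoms["CA"]], X[atoms["C"]])
        if i + 1 < len(keys) and keys[i + 1][0] == key[0]:
            next_n = X[index[keys[i + 1]]["N"]]
            out[i, 1] = _dihedral(X[atoms["N"]], X[atoms["CA"]], X[atoms["C"]], next_n)
    return out


def helix_content(frame: Frame) -> float:
    """Percent of residues in alpha-helical (phi, psi) runs of length >= 4.

    Uses planted per-residue dihedral metadata when present (bead models),
    otherwise computes backbone dihedrals from N/CA/C atoms.
    """
    dihedrals = frame.dihedrals
    if dihedrals is None:
        dihedrals = _backbone_dihedrals(frame)
    phi, psi = dihedrals[:, 0], dihedrals[:, 1]
    with np.errstate(invalid="ignore"):
        in_window = (
            (phi >= HELIX_PHI_RANGE[0])
            & (phi <= HELIX_PHI_RANGE[1])
            & (psi >= HELIX_PSI_RANGE[0])
            & (psi <= HELIX_PSI_RANGE[1])
        )
    helical = np.zeros(len(in_window), dtype=bool)
    run_start = None
    padded = np.concatenate([in_window, [False]])
    for i, flag in enumerate(padded):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start >= HELIX_MIN_RUN:
                helical[run_start:i] = True
            run_start = None
    return float(100.0 * helical.mean())


def residue_distance(
    frame: Frame,
    res_a: int,
    res_b: int,
    chain_a: str | None = None,
    chain_b: str | None = None,
    mode: str = "CA",
) -> float:
    """Distance between two residues, reported in angstrom.

    ``mode='CA'`` (default) measures CA-to-CA (bead-to-bead);
    ``mode='closest'`` takes the minimum over all heavy-atom pairs.
    """

    def _atoms(res_id: int, chain: str | None) -> np.ndarray:
        top = frame.topology
        mask = top.res_ids == res_id
        if chain is not None:
            mask &= top.chain_ids == chain
        if mode == "CA":
            ca = mask & (top.atom_names == "CA")
            mask = ca if ca.any() else mask
        else:
            mask &= top.elements != "H"
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise ValidationError(f"residue {res_id} (chain {chain}) not found")
        return idx

    ia = _atoms(res_a, chain_a)
    ib = _atoms(res_b, chain_b)
    if mode == "CA":
        d = np.linalg.norm(frame.coords[ia[0]] - frame.coords[ib[0]])
    else:
        diff = frame.coords[ia][:, None, :] - frame.coords[ib][None, :, :]
        d = np.sqrt((diff**2).sum(-1)).min()
    return float(d * 10.0)


def lowess_smooth(series, frac: float = 0.1, x=None) -> np.ndarray:
    """LOWESS (locally weighted linear regression) smoothing of a series."""
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or len(y) < 3:
        raise ValidationError("lowess needs a 1-D series of at least 3 points")
    if not 0.0 < frac <= 1.0:
        raise ValidationError("frac must lie in (0, 1]")
    xs = np.arange(len(y), dtype=float) if x is None else np.asarray(x, dtype=float)
    return _sm_lowess(y, xs, frac=frac, return_sorted=False)
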