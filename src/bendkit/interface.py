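"""Interface characterisation: surface areas, contacts and steric clashes.

Solvent-accessible surface area (SASA) is computed with the Shrake–Rupley
quadrature: each heavy atom carries a sphere of radius ``r_vdw + probe``
sampled on a deterministic golden-spiral point set, and the accessible
area is the fraction of points not buried inside any neighbour's sphere.
Buried surface area (BSA) of a complex is then
``SASA(A) + SASA(B) − SASA(A∪B)``.  Contacts are residue pairs whose
minimum heavy-atom distance falls below a cutoff (5 Å by default), and the
lattice-graft operation superposes a complex onto a chosen subunit of a
protofilament model to ask whether the binder would sterically clash with
neighbouring tubulin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .annotation import AnnotatedModel, get_element_calphas
from .errors import ConfigurationError, GeometryError
from .model import StructureModel, select_atoms
from .superpose import apply_transform, kabsch_fit

DEFAULT_PROBE_RADIUS = 1.4  # Å, water probe
DEFAULT_N_SPHERE_POINTS = 960
DEFAULT_CONTACT_CUTOFF = 5.0  # Å
DEFAULT_CLASH_CUTOFF = 2.2  # Å heavy-atom


@dataclass
class SASAResult:
    per_atom_area: np.ndarray  # Å², parallel to the atom labels
    labels: list[tuple[str, int, str]]  # (chain, seq_id, atom name)
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom_area.sum())


@dataclass
class Contact:
    chain_a: str
    seq_id_a: int
    comp_a: str
    chain_b: str
    seq_id_b: int
    comp_b: str
    min_distance: float
    sse_a: Optional[str] = None  # SSE containing the partner-a residue, if tubulin
    sse_b: Optional[str] = None


@dataclass
class InterfaceReport:
    partner_a_chains: list[str]
    partner_b_chains: list[str]
    bsa_total: float = 0.0
    sasa_a: float = 0.0
    sasa_b: float = 0.0
    sasa_complex: float = 0.0
    contacts: list[Contact] = field(default_factory=list)
    clash_count: int = 0


# ---------------------------------------------------------------------------
# Shrake–Rupley quadrature


def golden_spiral_points(n: int) -> np.ndarray:
    """*n* deterministic, nearly uniform points on the unit sphere."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa_from_arrays(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
) -> np.ndarray:
    """Per-atom accessible areas (Å²) for explicit coordinates and radii."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n_atoms = len(coords)
    if n_atoms == 0:
        return np.zeros(0)
    sphere = golden_spiral_points(n_sphere_points)
    ext = radii + probe_radius
    tree = cKDTree(coords)
    max_ext = ext.max()
    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        neighbours = [
            j for j in tree.query_ball_point(coords[i], ext[i] + max_ext)
            if j != i and np.linalg.norm(coords[j] - coords[i]) < ext[i] + ext[j]
        ]
        pts = coords[i] + ext[i] * sphere
        if neighbours:
            buried = np.zeros(n_sphere_points, dtype=bool)
            for j in neighbours:
                d2 = np.sum((pts - coords[j]) ** 2, axis=1)
                buried |= d2 < ext[j] ** 2
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * ext[i] ** 2
    return areas


def _collect_atoms(
    model: StructureModel,
    chain_ids: Optional[Sequence[str]],
    include_hetero: bool,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int, str]]]:
    coords, radii, labels = [], [], []
    for cid, res, atom in model.iter_atoms(chain_ids, heavy_only=True):
        if res.is_water:
            continue
        if not include_hetero and not res.is_protein:
            continue
        if atom.vdw_radius is None:
            raise ConfigurationError(
                f"no van der Waals radius for element {atom.element!r} "
                f"({cid}/{res.seq_id}/{atom.name})"
            )
        coords.append(atom.coord)
        radii.append(atom.vdw_radius)
        labels.append((cid, res.seq_id, atom.name))
    if not coords:
        return np.empty((0, 3)), np.empty(0), labels
    return np.vstack(coords), np.asarray(radii), labels


def shrake_rupley_sasa(
    model: StructureModel,
    chain_ids: Optional[Sequence[str]] = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
    include_hetero: bool = False,
) -> SASAResult:
    """Shrake–Rupley SASA of (a chain subset of) a model.

    Heavy atoms only; waters always excluded; hetero ligands excluded
    unless ``include_hetero=True``.  The quadrature point set is
    deterministic, so results are bit-reproducible.
    """
    coords, radii, labels = _collect_atoms(model, chain_ids, include_hetero)
    areas = sasa_from_arrays(coords, radii, probe_radius, n_sphere_points)
    return SASAResult(
        per_atom_area=areas,
        labels=labels,
        probe_radius=probe_radius,
        n_sphere_points=n_sphere_points,
    )


# ---------------------------------------------------------------------------
# Buried surface area


def buried_surface_area(
    model: StructureModel,
    partner_a: Sequence[str],
    partner_b: Sequence[str],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
    include_hetero: bool = False,
) -> InterfaceReport:
    """Surface area buried between two disjoint chain groups.

    ``bsa_total = SASA(A alone) + SASA(B alone) − SASA(A∪B)``, all three
    terms with identical parameters.  Small negative values from quadrature
    noise are floored at 0.
    """
    a, b = list(partner_a), list(partner_b)
    if not a or not b:
        raise ValueError("both partners must be non-empty")
    if set(a) & set(b):
        raise ValueError(f"partners overlap: {sorted(set(a) & set(b))}")
    kwargs = dict(
        probe_radius=probe_radius,
        n_sphere_points=n_sphere_points,
        include_hetero=include_hetero,
    )
    sasa_a = shrake_rupley_sasa(model, a, **kwargs).total
    sasa_b = shrake_rupley_sasa(model, b, **kwargs).total
    sasa_ab = shrake_rupley_sasa(model, a + b, **kwargs).total
    bsa = sasa_a + sasa_b - sasa_ab
    if bsa < -1.0:
        raise GeometryError(f"BSA {bsa:.2f} Å² below numerical floor")
    return InterfaceReport(
        partner_a_chains=a,
        partner_b_chains=b,
        bsa_total=max(bsa, 0.0),
        sasa_a=sasa_a,
        sasa_b=sasa_b,
        sasa_complex=sasa_ab,
    )


# ---------------------------------------------------------------------------
# Contacts


def _sse_of_position(annotated: AnnotatedModel, chain_id: str, seq_id: int
                     ) -> Optional[str]:
    role = annotated.role_of(chain_id)
    subunit = {"alpha_tubulin": "alpha", "beta_tubulin": "beta"}.get(role)
    if subunit is None or chain_id not in annotated.maps:
        return None
    canon = annotated.maps[chain_id].author_to_canonical().get(seq_id)
    if canon is None:
        return None
    for el in annotated.registry.elements:
        if el.subunit == subunit and el.start <= canon <= el.end:
            return el.name
    return None


def contact_residues(
    model: StructureModel,
    partner_a: Sequence[str],
    partner_b: Sequence[str],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    annotated: Optional[AnnotatedModel] = None,
) -> list[Contact]:
    """Residue pairs whose minimum heavy-atom distance is below *cutoff*.

    When an :class:`AnnotatedModel` is supplied, tubulin residues are
    additionally attributed to the registry SSE containing their canonical
    position (``sse_a`` / ``sse_b``).
    """
    if set(partner_a) & set(partner_b):
        raise ValueError("partners overlap")

    def atoms_of(chains):
        out = []
        for cid in chains:
            for res in model.chains[cid]:
                if res.is_water:
                    continue
                for atom in res.atoms:
                    if atom.is_hydrogen:
                        continue
                    out.append((cid, res, atom.coord))
        return out

    atoms_a, atoms_b = atoms_of(partner_a), atoms_of(partner_b)
    if not atoms_a or not atoms_b:
        return []
    coords_b = np.array([c for _, _, c in atoms_b])
    tree = cKDTree(coords_b)
    best: dict[tuple, float] = {}
    meta: dict[tuple, tuple] = {}
    for cid_a, res_a, coord in atoms_a:
        for j in tree.query_ball_point(coord, cutoff):
            cid_b, res_b, coord_b = atoms_b[j]
            d = float(np.linalg.norm(coord - coord_b))
            if d >= cutoff:
                continue
            key = (cid_a, res_a.seq_id, cid_b, res_b.seq_id)
            if d < best.get(key, np.inf):
                best[key] = d
                meta[key] = (res_a.comp_id, res_b.comp_id)
    contacts = []
    for key in sorted(best):
        cid_a, sid_a, cid_b, sid_b = key
        comp_a, comp_b = meta[key]
        contacts.append(
            Contact(
                chain_a=cid_a,
                seq_id_a=sid_a,
                comp_a=comp_a,
                chain_b=cid_b,
                seq_id_b=sid_b,
                comp_b=comp_b,
                min_distance=best[key],
                sse_a=_sse_of_position(annotated, cid_a, sid_a) if annotated else None,
                sse_b=_sse_of_position(annotated, cid_b, sid_b) if annotated else None,
            )
        )
    return contacts


# ---------------------------------------------------------------------------
# Lattice graft


def lattice_graft_clash(
    complex_annotated: AnnotatedModel,
    binder_chain: str,
    complex_alpha_chain: str,
    lattice_annotated: AnnotatedModel,
    target_alpha_chain: str,
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
) -> InterfaceReport:
    """Graft a binder onto a lattice subunit and count steric clashes.

    The complex α-tubulin is superposed onto the chosen lattice α subunit
    using the N-terminal-domain SSE Cα atoms; the same transform carries
    the binder atoms onto the lattice, and every transformed binder heavy
    atom closer than *clash_cutoff* to any lattice heavy atom is counted
    as a clash.
    """
    if target_alpha_chain not in lattice_annotated.maps:
        raise ValueError(f"lattice has no mapped α chain {target_alpha_chain!r}")
    if complex_alpha_chain not in complex_annotated.maps:
        raise ValueError(f"complex has no mapped α chain {complex_alpha_chain!r}")

    def domain_cas(annotated, chain_id):
        coords, used, _ = get_element_calphas(
            annotated.model,
            annotated.maps[chain_id],
            annotated.registry,
            subunit="alpha",
            domain="n_terminal",
        )
        return dict(zip(used, coords))

    src = domain_cas(complex_annotated, complex_alpha_chain)
    dst = domain_cas(lattice_annotated, target_alpha_chain)
    common = sorted(set(src) & set(dst))
    if len(common) < 3:
        raise GeometryError("too few common α N-terminal-domain positions for graft")
    fit = kabsch_fit(
        np.vstack([src[p] for p in common]), np.vstack([dst[p] for p in common])
    )

    binder_coords, _ = select_atoms(
        complex_annotated.model, chain_ids=[binder_chain], heavy_only=True
    )
    grafted = apply_transform(binder_coords, fit.transform)
    lattice_coords, _ = select_atoms(lattice_annotated.model, heavy_only=True)
    tree = cKDTree(lattice_coords)
    pairs = tree.query_ball_point(grafted, clash_cutoff)
    clash_count = int(sum(len(p) for p in pairs))
    return InterfaceReport(
        partner_a_chains=[binder_chain],
        partner_b_chains=lattice_annotated.model.chain_ids(),
        clash_count=clash_count,
    )
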