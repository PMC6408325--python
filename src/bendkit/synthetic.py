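"""Synthetic structures and isotherms with known ground truth.

Every input class the pipeline consumes can be generated here without
downloading coordinates: ideal α-helices for shift metrics, two-chain
"heterodimers" carrying the bundled tubulin reference sequences with a
known applied inter-subunit rotation, sphere systems with analytically
known surface area, a toy protofilament lattice for graft/clash logic,
and seeded one-site ITC isotherms.  Generators are pure functions of
their parameters (and seed), so the same call is bit-reproducible.
"""

from __future__ import annotations

import string
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .annotation import SSERegistry, load_correspondence_table, load_reference_sequences
from .model import ONE_TO_THREE, AtomRecord, ResidueRecord, StructureModel
from .superpose import RigidTransform
from .thermo import BindingParameters, ITCGeometry, TitrationSeries, simulate_itc

#: Spacing of one αβ-dimer repeat along a protofilament axis, Å (approximate
#: tubulin value; only relative geometry matters for clash logic).
DIMER_REPEAT_A = 81.0

#: Offset of the β subunit from the α subunit within one synthetic dimer, Å.
_MONOMER_OFFSET = np.array([0.0, 0.0, 40.5])


def _residue(seq_id: int, aa: str, ca: np.ndarray, with_cb: bool = True) -> ResidueRecord:
    atoms = [AtomRecord(name="CA", element="C", coord=ca)]
    if with_cb and aa != "G":
        atoms.append(AtomRecord(name="CB", element="C", coord=ca + (1.0, 0.8, 0.6)))
    return ResidueRecord(seq_id=seq_id, comp_id=ONE_TO_THREE.get(aa, "ALA"), atoms=atoms)


def make_ideal_helix(
    n_res: int, rise: float = 1.5, twist: float = 100.0, radius: float = 2.3
) -> StructureModel:
    """Cα-only poly-alanine ideal helix (defaults: α-helix geometry).

    Consecutive Cα atoms have a constant rise along z and a constant twist
    about z, so every Cα–Cα distance is identical.
    """
    if n_res < 4:
        raise ValueError(f"need at least 4 residues for a helix, got {n_res}")
    residues = []
    for i in range(n_res):
        theta = np.radians(twist) * i
        ca = np.array([radius * np.cos(theta), radius * np.sin(theta), rise * i])
        residues.append(_residue(i + 1, "A", ca, with_cb=False))
    return StructureModel(id=f"helix{n_res}", chains={"A": residues},
                          source_format="synthetic")


def _scaffold(pos: int) -> np.ndarray:
    """Deterministic compact non-degenerate curve for canonical position *pos*."""
    p = float(pos)
    return np.array(
        [
            16.0 * np.cos(0.25 * p) + 5.0 * np.cos(0.9 * p),
            16.0 * np.sin(0.25 * p) + 5.0 * np.sin(1.1 * p),
            14.0 * np.sin(0.05 * p),
        ]
    )


def _alpha_chain(offset: np.ndarray = np.zeros(3)) -> list[ResidueRecord]:
    alpha_ref, _ = load_reference_sequences()
    return [
        _residue(i + 1, aa, _scaffold(i + 1) + offset)
        for i, aa in enumerate(alpha_ref)
    ]


def _beta_chain(transform: RigidTransform) -> list[ResidueRecord]:
    """β chain whose corresponded positions are an exact rigid copy of α's."""
    _, beta_ref = load_reference_sequences()
    beta_to_alpha = {b: a for a, b in load_correspondence_table()}
    residues = []
    for i, aa in enumerate(beta_ref):
        bpos = i + 1
        apos = beta_to_alpha.get(bpos, bpos)  # uncorresponded: nearby filler
        ca = transform.rotation @ _scaffold(apos) + transform.translation
        residues.append(_residue(bpos, aa, ca))
    return residues


def dimer_transform(angle_deg: float, offset: np.ndarray = _MONOMER_OFFSET
                    ) -> RigidTransform:
    """The rigid motion applied to build the β subunit of a bent dimer."""
    rot = Rotation.from_rotvec(np.radians(angle_deg) * np.array([1.0, 0.0, 0.0]))
    return RigidTransform(rotation=rot.as_matrix(), translation=np.asarray(offset,
                                                                           dtype=float))


def make_bent_dimer(
    angle_deg: float,
    registry: Optional[SSERegistry] = None,
    chain_ids: tuple[str, str] = ("A", "B"),
    offset: np.ndarray = _MONOMER_OFFSET,
    with_binder: bool = False,
    binder_site: str = "lateral",
) -> StructureModel:
    """Two-chain heterodimer with a known inter-subunit rotation.

    Chain A carries the bundled α-tubulin reference sequence on a fixed
    scaffold; chain B carries the β reference with coordinates that are an
    exact rigid copy (rotation ``angle_deg`` about x, then a longitudinal
    offset) of the α scaffold at the α↔β corresponded positions.  The
    inter-subunit bend angle measured on N-terminal-domain SSEs therefore
    equals *angle_deg* by construction.

    With ``with_binder=True`` a 100-residue binder chain is appended in
    contact (< 5 Å) with the α chain: ``binder_site="lateral"`` places it
    on the outward (+x) face, ``"longitudinal"`` on the −z face that a
    neighbouring dimer would occupy along a protofilament.
    """
    if not 0.0 <= angle_deg <= 180.0:
        raise ValueError(f"angle must be in [0, 180], got {angle_deg}")
    del registry  # scaffold covers all registry ranges by construction
    transform = dimer_transform(angle_deg, offset)
    cid_a, cid_b = chain_ids
    chains = {cid_a: _alpha_chain(), cid_b: _beta_chain(transform)}
    model = StructureModel(id=f"dimer{angle_deg:g}", chains=dict(sorted(chains.items())),
                           source_format="synthetic")
    if with_binder:
        model.chains["X"] = _binder_chain(model, cid_a, site=binder_site)
    return model


def _binder_chain(model: StructureModel, near_chain: str, n_res: int = 100,
                  site: str = "lateral") -> list[ResidueRecord]:
    # a helical rod anchored 4.3 Å off the chosen face of the α chain,
    # extending away from the dimer so it touches but never penetrates it
    coords = np.array(
        [a.coord for r in model.chains[near_chain] for a in r.atoms]
    )
    if site == "lateral":
        anchor = coords[np.argmax(coords[:, 0])]
        direction = np.array([1.0, 0.0, 0.0])
    elif site == "longitudinal":
        anchor = coords[np.argmin(coords[:, 2])]
        direction = np.array([0.0, 0.0, -1.0])
    else:
        raise ValueError(f"unknown binder_site {site!r}")
    perp1 = np.array([0.0, 1.0, 0.0]) if site == "longitudinal" else np.array(
        [0.0, 0.0, 1.0])
    perp2 = np.cross(direction, perp1)
    residues = []
    seq = ("KELAAREL" * 13)[:n_res]
    for i, aa in enumerate(seq):
        theta = 1.7 * i
        ca = (
            anchor
            + (3.5 + 1.4 * i) * direction
            + 2.5 * np.cos(theta) * perp1
            + 2.5 * np.sin(theta) * perp2
        )
        residues.append(_residue(i + 1, aa, ca))
    return residues


def make_sphere_system(
    centers: Sequence[Sequence[float]], radii: Sequence[float]
) -> StructureModel:
    """Dummy atoms with explicit van der Waals radii for SASA oracles."""
    centers = np.asarray(centers, dtype=float)
    if len(centers) != len(radii):
        raise ValueError("centers and radii must have equal length")
    residues = [
        ResidueRecord(
            seq_id=i + 1,
            comp_id="ALA",
            atoms=[
                AtomRecord(name="CA", element="C", coord=c, vdw_radius=float(r))
            ],
        )
        for i, (c, r) in enumerate(zip(centers, radii))
    ]
    return StructureModel(id="spheres", chains={"A": residues},
                          source_format="synthetic")


def make_toy_lattice(n_dimers: int, spacing: float = DIMER_REPEAT_A) -> StructureModel:
    """Straight protofilament of head-to-tail αβ-dimers along z.

    Chains alternate α, β, α, β, ... with ids A, B, C, ...; dimer *i* is the
    straight (0°) dimer translated by ``i × spacing`` along the axis.
    """
    if n_dimers < 2:
        raise ValueError(f"need at least 2 dimers, got {n_dimers}")
    if 2 * n_dimers > len(string.ascii_uppercase):
        raise ValueError("too many dimers for single-letter chain ids")
    chains: dict[str, list[ResidueRecord]] = {}
    for i in range(n_dimers):
        shift = np.array([0.0, 0.0, spacing * i])
        cid_a = string.ascii_uppercase[2 * i]
        cid_b = string.ascii_uppercase[2 * i + 1]
        chains[cid_a] = _alpha_chain(offset=shift)
        transform = dimer_transform(0.0, _MONOMER_OFFSET + shift)
        chains[cid_b] = _beta_chain(transform)
    return StructureModel(id=f"lattice{n_dimers}", chains=chains,
                          source_format="synthetic")


def make_itc_dataset(
    params: BindingParameters,
    geometry: Optional[ITCGeometry] = None,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> TitrationSeries:
    """Seeded one-site isotherm under the standard titration geometry."""
    if geometry is None:
        geometry = ITCGeometry.standard()
    return simulate_itc(params, geometry, noise_sd=noise_sd, seed=seed)
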