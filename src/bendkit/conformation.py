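"""Conformational statistics of tubulin heterodimers.

The central quantity is the inter-subunit bend (curvature) angle: the
magnitude of the rotation relating the α- and β-subunit frames within one
heterodimer, obtained by superposing the Cα atoms of the α N-terminal-domain
secondary-structure elements onto their β equivalents.  Straight,
microtubule-like tubulin measures ~0–1°; curved soluble tubulin ≥ ~10°.
Also provided: a multi-entry bend-angle survey, the H7 helix-shift metric
(how far the central H7 helix moves between two structures after aligning
their N-terminal domains), and the pairwise RMSD matrix between the copies
of a complex in one asymmetric unit.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    AnnotatedModel,
    ChainRole,
    SSERegistry,
    get_element_calphas,
    load_correspondence_table,
)
from .errors import AnnotationError, GeometryError
from .model import StructureModel, select_atoms
from .superpose import RigidTransform, apply_transform, kabsch_fit

#: Minimum α↔β corresponding Cα positions for a reportable bend angle.
MIN_BEND_POSITIONS = 50

#: Maximum α–β Cα-centroid distance for two chains to form one dimer, Å.
PAIRING_CUTOFF = 50.0

BINDER_ATTACH_CUTOFF = 5.0  # Å


@dataclass
class HeterodimerPair:
    """One αβ-tubulin heterodimer plus any binder chains attached to it."""

    alpha_chain_id: str
    beta_chain_id: str
    binder_chain_ids: list[str] = field(default_factory=list)


@dataclass
class BendAngleResult:
    pair: HeterodimerPair
    angle_deg: float
    n_positions_used: int
    fit_rmsd: float


@dataclass
class HelixShiftResult:
    reference_id: str
    query_id: str
    element: str
    shift_A: float
    alignment_rmsd: float


@dataclass
class SurveyResult:
    """Per-dimer bend angles plus per-entry means, Table-style."""

    table: pd.DataFrame  # entry_id, alpha_chain, beta_chain, angle_deg, ...
    entry_means: pd.DataFrame  # entry_id, mean_angle_deg, n_dimers
    skipped: list[tuple[str, str]]  # (entry_id, reason)


def transform_model(model: StructureModel, transform: RigidTransform) -> StructureModel:
    """A copy of *model* with every atom rigidly moved."""
    out = copy.deepcopy(model)
    for residues in out.chains.values():
        for res in residues:
            for atom in res.atoms:
                atom.coord = transform.rotation @ atom.coord + transform.translation
    return out


# ---------------------------------------------------------------------------
# Pairing


def _ca_centroid(model: StructureModel, chain_id: str) -> np.ndarray:
    coords, _ = select_atoms(model, chain_ids=[chain_id], atom_names=["CA"])
    if len(coords) == 0:
        raise GeometryError(f"chain {chain_id}: no Cα atoms")
    return coords.mean(axis=0)


def _min_distance(model: StructureModel, cid_a: str, chain_ids_b: Sequence[str]) -> float:
    from scipy.spatial import cKDTree

    ca, _ = select_atoms(model, chain_ids=[cid_a])
    cb, _ = select_atoms(model, chain_ids=list(chain_ids_b))
    if len(ca) == 0 or len(cb) == 0:
        return np.inf
    d, _ = cKDTree(cb).query(ca, k=1)
    return float(d.min())


def pair_heterodimers(
    model: StructureModel, roles: Sequence[ChainRole]
) -> tuple[list[HeterodimerPair], list[str]]:
    """Group chains into αβ heterodimers with attached binders.

    Each α chain (in chain-id order) is paired with the nearest unpaired β
    chain by Cα centroid distance, within 50 Å.  Binder chains attach to
    the pair whose tubulin atoms they contact within 5 Å.  Unpairable
    chains are reported as warnings, not errors.
    """
    alphas = sorted(r.chain_id for r in roles if r.role == "alpha_tubulin")
    betas = sorted(r.chain_id for r in roles if r.role == "beta_tubulin")
    binders = sorted(r.chain_id for r in roles if r.role == "binder")
    warnings: list[str] = []
    pairs: list[HeterodimerPair] = []
    free_betas = list(betas)
    for cid_a in alphas:
        ca = _ca_centroid(model, cid_a)
        best, best_d = None, np.inf
        for cid_b in free_betas:
            d = float(np.linalg.norm(ca - _ca_centroid(model, cid_b)))
            if d < best_d:
                best, best_d = cid_b, d
        if best is None or best_d > PAIRING_CUTOFF:
            warnings.append(f"alpha chain {cid_a}: no β partner within "
                            f"{PAIRING_CUTOFF} Å")
            continue
        free_betas.remove(best)
        pairs.append(HeterodimerPair(alpha_chain_id=cid_a, beta_chain_id=best))
    for cid_b in free_betas:
        warnings.append(f"beta chain {cid_b}: unpaired")
    for cid_x in binders:
        attached = False
        for pair in pairs:
            d = _min_distance(model, cid_x,
                              [pair.alpha_chain_id, pair.beta_chain_id])
            if d < BINDER_ATTACH_CUTOFF:
                pair.binder_chain_ids.append(cid_x)
                attached = True
                break
        if not attached:
            warnings.append(f"binder chain {cid_x}: contacts no heterodimer")
    return pairs, warnings


# ---------------------------------------------------------------------------
# Bend angle


def _bend_coordinate_pairs(
    annotated: AnnotatedModel, pair: HeterodimerPair
) -> tuple[np.ndarray, np.ndarray]:
    """Matched (α, β) Cα coordinates on N-terminal-domain SSE positions."""
    registry = annotated.registry
    map_a = annotated.maps[pair.alpha_chain_id]
    map_b = annotated.maps[pair.beta_chain_id]
    alpha_sse = set(registry.positions(registry.in_domain("alpha", "n_terminal")))
    corr = [(a, b) for a, b in load_correspondence_table() if a in alpha_sse]

    ca_by_canon_a = _calpha_by_canonical(annotated.model, map_a)
    ca_by_canon_b = _calpha_by_canonical(annotated.model, map_b)
    coords_a, coords_b = [], []
    for a, b in corr:
        xa, xb = ca_by_canon_a.get(a), ca_by_canon_b.get(b)
        if xa is None or xb is None:
            continue
        coords_a.append(xa)
        coords_b.append(xb)
    if len(coords_a) < MIN_BEND_POSITIONS:
        raise GeometryError(
            f"only {len(coords_a)} α↔β corresponding Cα positions resolved "
            f"(need ≥{MIN_BEND_POSITIONS})"
        )
    return np.vstack(coords_a), np.vstack(coords_b)


def _calpha_by_canonical(model: StructureModel, residue_map) -> dict[int, np.ndarray]:
    by_author = {r.seq_id: r for r in model.chains[residue_map.chain_id] if r.is_protein}
    out = {}
    for author, canon in residue_map.pairs:
        res = by_author.get(author)
        ca = res.get_atom("CA") if res is not None else None
        if ca is not None:
            out[canon] = ca.coord
    return out


def intersubunit_bend_angle(
    annotated: AnnotatedModel, pair: HeterodimerPair
) -> BendAngleResult:
    """Bend angle of one heterodimer, in degrees.

    Superposes the α-subunit Cα atoms of the N-terminal-domain helices and
    strands onto the corresponding β-subunit positions (bundled α↔β
    correspondence, restricted to positions resolved in both chains) and
    reports the rotation magnitude of the fit.  The value is invariant
    under any global rigid motion of the model.
    """
    coords_a, coords_b = _bend_coordinate_pairs(annotated, pair)
    fit = kabsch_fit(coords_a, coords_b)
    return BendAngleResult(
        pair=pair,
        angle_deg=fit.rotation_angle_deg,
        n_positions_used=fit.n_points,
        fit_rmsd=fit.rmsd,
    )


def analyze_model(
    model: StructureModel, registry: Optional[SSERegistry] = None
) -> tuple[AnnotatedModel, list[HeterodimerPair], list[str]]:
    """Annotate a model and group its chains into heterodimers."""
    annotated = AnnotatedModel.annotate(model, registry)
    pairs, warnings = pair_heterodimers(model, annotated.roles)
    return annotated, pairs, warnings


def bend_angle_survey(
    models: Sequence[StructureModel], registry: Optional[SSERegistry] = None
) -> SurveyResult:
    """Bend angles across entries: one row per heterodimer plus entry means.

    Entries that fail annotation are collected in ``skipped`` with the
    failure reason rather than silently dropped.  Rows are ordered by
    ascending per-entry mean angle.
    """
    registry = registry or SSERegistry.default()
    rows = []
    skipped: list[tuple[str, str]] = []
    for model in models:
        try:
            annotated, pairs, _ = analyze_model(model, registry)
            if not pairs:
                raise AnnotationError("no heterodimer could be paired")
            for pair in pairs:
                res = intersubunit_bend_angle(annotated, pair)
                rows.append(
                    {
                        "entry_id": model.id,
                        "alpha_chain": pair.alpha_chain_id,
                        "beta_chain": pair.beta_chain_id,
                        "angle_deg": res.angle_deg,
                        "n_positions": res.n_positions_used,
                        "fit_rmsd": res.fit_rmsd,
                    }
                )
        except Exception as exc:  # annotation/geometry failures become skips
            skipped.append((model.id, str(exc)))
    table = pd.DataFrame(
        rows,
        columns=["entry_id", "alpha_chain", "beta_chain", "angle_deg",
                 "n_positions", "fit_rmsd"],
    )
    if len(table):
        means = (
            table.groupby("entry_id", sort=False)["angle_deg"]
            .agg(mean_angle_deg="mean", n_dimers="size")
            .reset_index()
            .sort_values("mean_angle_deg", kind="mergesort")
            .reset_index(drop=True)
        )
        order = {e: i for i, e in enumerate(means["entry_id"])}
        table = table.sort_values(
            by=["entry_id", "alpha_chain"],
            key=lambda col: col.map(order) if col.name == "entry_id" else col,
            kind="mergesort",
        ).reset_index(drop=True)
    else:
        means = pd.DataFrame(columns=["entry_id", "mean_angle_deg", "n_dimers"])
    return SurveyResult(table=table, entry_means=means, skipped=skipped)


# ---------------------------------------------------------------------------
# H7 shift


def helix_shift(
    reference: AnnotatedModel,
    ref_pair: HeterodimerPair,
    query: AnnotatedModel,
    query_pair: HeterodimerPair,
    element: str = "H7",
) -> HelixShiftResult:
    """Displacement of a named α-subunit helix between two structures.

    The query α subunit is superposed onto the reference α subunit on the
    Cα atoms of the N-terminal-domain SSEs (common canonical positions);
    the shift is then the distance between the two element Cα centroids —
    the "translation needed to superimpose" the helices.
    """
    registry = reference.registry
    ref_map = reference.maps[ref_pair.alpha_chain_id]
    q_map = query.maps[query_pair.alpha_chain_id]
    ref_ca = _calpha_by_canonical(reference.model, ref_map)
    q_ca = _calpha_by_canonical(query.model, q_map)

    dom_pos = registry.positions(registry.in_domain("alpha", "n_terminal"))
    common_dom = [p for p in dom_pos if p in ref_ca and p in q_ca]
    if len(common_dom) < 3:
        raise GeometryError("too few common N-terminal-domain positions")
    fit = kabsch_fit(
        np.vstack([q_ca[p] for p in common_dom]),
        np.vstack([ref_ca[p] for p in common_dom]),
    )

    el = registry.get("alpha", element)
    common_el = [p for p in el.positions() if p in ref_ca and p in q_ca]
    if not common_el:
        raise GeometryError(f"element {element}: no common resolved positions")
    ref_centroid = np.vstack([ref_ca[p] for p in common_el]).mean(axis=0)
    q_el = apply_transform(np.vstack([q_ca[p] for p in common_el]), fit.transform)
    shift = float(np.linalg.norm(q_el.mean(axis=0) - ref_centroid))
    return HelixShiftResult(
        reference_id=reference.model.id,
        query_id=query.model.id,
        element=element,
        shift_A=shift,
        alignment_rmsd=fit.rmsd,
    )


# ---------------------------------------------------------------------------
# ASU-copy RMSD matrix


def pairwise_complex_rmsd(
    annotated: AnnotatedModel, pairs: Sequence[HeterodimerPair]
) -> tuple[np.ndarray, int]:
    """Symmetric RMSD matrix between the complexes of one asymmetric unit.

    Each complex is its tubulin heterodimer plus attached binder chains.
    The comparison runs over the common resolved Cα set: the intersection
    of canonical tubulin positions across copies, plus binder residues
    matched by author numbering.  Entry (i, j) is the Kabsch-fit RMSD
    between copies i and j; the diagonal is zero.
    """
    if len(pairs) < 2:
        raise GeometryError("pairwise complex RMSD needs at least 2 complexes")
    keyed: list[dict] = []
    for pair in pairs:
        coords: dict = {}
        for sub, cid in (("alpha", pair.alpha_chain_id), ("beta", pair.beta_chain_id)):
            for canon, xyz in _calpha_by_canonical(
                annotated.model, annotated.maps[cid]
            ).items():
                coords[(sub, canon)] = xyz
        for k, cid in enumerate(sorted(pair.binder_chain_ids)):
            for res in annotated.model.chains[cid]:
                ca = res.get_atom("CA")
                if ca is not None:
                    coords[("binder", k, res.seq_id)] = ca.coord
        keyed.append(coords)
    common = set(keyed[0])
    for coords in keyed[1:]:
        common &= set(coords)
    keys = sorted(common, key=repr)
    if len(keys) < 3:
        raise GeometryError("fewer than 3 common Cα positions across complexes")
    mats = [np.vstack([coords[k] for k in keys]) for coords in keyed]
    n = len(pairs)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = kabsch_fit(mats[i], mats[j]).rmsd
    return out, len(keys)
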