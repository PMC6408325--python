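"""Tubulin chain annotation: roles, canonical numbering and SSE registry.

The bend-angle and interface metrics are defined on named tubulin
secondary-structure elements (H7, T7 loop, H8, S9, ...) in a canonical
structure-based residue numbering.  This module identifies which chains of
a model are α-tubulin, β-tubulin or binder, maps author residue numbers
onto canonical positions by global alignment against bundled reference
sequences, and resolves element/domain selections to Cα coordinate sets.

The registry of element ranges and the reference sequences are plain-text
data files shipped with the package and can be substituted by the user;
all ranges are treated as provisional to roughly ±2 residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial import cKDTree

from .errors import AnnotationError, GeometryError
from .model import StructureModel, select_atoms

_KMER_K = 4  # long enough that low-complexity chains score ~0, short enough
# that ~90%-identical tubulin isotypes stay above the 0.6 threshold
IDENTITY_THRESHOLD = 0.6
BINDER_LENGTH_RANGE = (80, 300)
BINDER_CONTACT_CUTOFF = 5.0  # Å


def _read_fasta_text(text: str) -> str:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    return "".join(ln for ln in lines if not ln.startswith(">"))


def _data_text(name: str) -> str:
    return resources.files("bendkit.data").joinpath(name).read_text()


def load_reference_sequences() -> tuple[str, str]:
    """Return the bundled (α-tubulin, β-tubulin) reference sequences."""
    return (
        _read_fasta_text(_data_text("alpha_tubulin_ref.fasta")),
        _read_fasta_text(_data_text("beta_tubulin_ref.fasta")),
    )


# ---------------------------------------------------------------------------
# Registry


@dataclass(frozen=True)
class SSEDefinition:
    """A named tubulin secondary-structure element on canonical numbering."""

    name: str
    subunit: str  # "alpha" | "beta"
    start: int
    end: int
    kind: str  # "helix" | "strand" | "loop"

    def positions(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class DomainPartition:
    """Canonical tripartite tubulin domain boundaries (inclusive)."""

    n_terminal: tuple[int, int] = (1, 205)
    intermediate: tuple[int, int] = (206, 381)
    c_terminal: tuple[int, int] = (382, 440)

    def interval(self, domain: str) -> tuple[int, int]:
        try:
            return getattr(self, domain)
        except AttributeError:
            raise AnnotationError(f"unknown domain {domain!r}") from None


@dataclass
class SSERegistry:
    """Lookup table of tubulin SSE ranges plus the domain partition."""

    elements: list[SSEDefinition] = field(default_factory=list)
    domains: DomainPartition = field(default_factory=DomainPartition)

    @classmethod
    def from_file(cls, path, domains: Optional[DomainPartition] = None) -> "SSERegistry":
        with open(path) as handle:
            return cls._parse(handle.read(), domains)

    @classmethod
    def default(cls) -> "SSERegistry":
        return cls._parse(_data_text("sse_registry.tsv"), None)

    @classmethod
    def _parse(cls, text: str, domains: Optional[DomainPartition]) -> "SSERegistry":
        elements = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            subunit, name, kind, start, end = line.split("\t")
            elements.append(
                SSEDefinition(name=name, subunit=subunit, kind=kind,
                              start=int(start), end=int(end))
            )
        return cls(elements=elements, domains=domains or DomainPartition())

    def get(self, subunit: str, name: str) -> SSEDefinition:
        for el in self.elements:
            if el.subunit == subunit and el.name == name:
                return el
        raise AnnotationError(f"no element {name!r} for subunit {subunit!r}")

    def in_domain(
        self,
        subunit: str,
        domain: str,
        kinds: Iterable[str] = ("helix", "strand"),
    ) -> list[SSEDefinition]:
        """Elements of the given kinds lying inside a domain interval."""
        lo, hi = self.domains.interval(domain)
        kinds = set(kinds)
        return [
            el
            for el in self.elements
            if el.subunit == subunit and el.kind in kinds
            and el.start >= lo and el.end <= hi
        ]

    def positions(self, elements: Sequence[SSEDefinition]) -> list[int]:
        out: list[int] = []
        for el in elements:
            out.extend(el.positions())
        return sorted(set(out))


# ---------------------------------------------------------------------------
# Chain classification


@dataclass
class ChainRole:
    chain_id: str
    role: str  # alpha_tubulin | beta_tubulin | binder | other
    identity_score: float


def _kmer_set(seq: str, k: int = _KMER_K) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _kmer_score(seq: str, ref_kmers: set[str], k: int = _KMER_K) -> float:
    """Fraction of the chain's k-mers found in the reference k-mer set."""
    if len(seq) < k:
        return 0.0
    kmers = [seq[i : i + k] for i in range(len(seq) - k + 1)]
    return sum(km in ref_kmers for km in kmers) / len(kmers)


def _min_interchain_distance(model: StructureModel, cid_a: str, cid_b: str) -> float:
    ca, _ = select_atoms(model, chain_ids=[cid_a], heavy_only=True)
    cb, _ = select_atoms(model, chain_ids=[cid_b], heavy_only=True)
    if len(ca) == 0 or len(cb) == 0:
        return np.inf
    dists, _ = cKDTree(cb).query(ca, k=1)
    return float(dists.min())


def classify_chains(
    model: StructureModel,
    threshold: float = IDENTITY_THRESHOLD,
    require_tubulin: bool = False,
) -> list[ChainRole]:
    """Assign every protein chain a role: α-tubulin, β-tubulin, binder or other.

    Roles are called by alignment-free k-mer similarity against the two
    bundled tubulin reference sequences.  Chains matching neither reference
    are called ``binder`` when they are 80–300 residues long and lie within
    5 Å of a tubulin chain, else ``other``.  Classification is independent
    of chain order.
    """
    alpha_ref, beta_ref = load_reference_sequences()
    alpha_kmers, beta_kmers = _kmer_set(alpha_ref), _kmer_set(beta_ref)

    roles: list[ChainRole] = []
    tubulin_ids: list[str] = []
    pending: list[tuple[str, int]] = []  # (chain_id, length) awaiting binder test
    for cid in model.protein_chain_ids():
        seq = model.chain_sequence(cid)
        score_a = _kmer_score(seq, alpha_kmers)
        score_b = _kmer_score(seq, beta_kmers)
        if max(score_a, score_b) >= threshold:
            role = "alpha_tubulin" if score_a >= score_b else "beta_tubulin"
            roles.append(ChainRole(cid, role, max(score_a, score_b)))
            tubulin_ids.append(cid)
        else:
            roles.append(ChainRole(cid, "other", max(score_a, score_b)))
            pending.append((cid, len(seq)))

    if not tubulin_ids:
        if require_tubulin:
            scores = {r.chain_id: round(r.identity_score, 3) for r in roles}
            raise AnnotationError(f"no tubulin chain found; scores: {scores}")
        return sorted(roles, key=lambda r: r.chain_id)

    lo, hi = BINDER_LENGTH_RANGE
    for cid, length in pending:
        if lo <= length <= hi and any(
            _min_interchain_distance(model, cid, tid) < BINDER_CONTACT_CUTOFF
            for tid in tubulin_ids
        ):
            for r in roles:
                if r.chain_id == cid:
                    r.role = "binder"
    return sorted(roles, key=lambda r: r.chain_id)


# ---------------------------------------------------------------------------
# Residue mapping


@dataclass
class ResidueMap:
    """One-to-one map between author residue numbers and canonical positions."""

    chain_id: str
    pairs: list[tuple[int, int]]  # (author seq_id, canonical position)
    identity: float = 1.0

    def author_to_canonical(self) -> dict[int, int]:
        return {a: c for a, c in self.pairs}

    def canonical_to_author(self) -> dict[int, int]:
        return {c: a for a, c in self.pairs}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.end_gap_score = 0.0  # end gaps free: chains are often truncated
    aligner.mode = "global"
    return aligner


def _align_pairs(ref: str, query: str) -> tuple[list[tuple[int, int]], float]:
    """Aligned (ref 1-based, query index) pairs and fraction identity."""
    aligner = _make_aligner()
    aln = aligner.align(ref.replace("X", "A"), query.replace("X", "A"))[0]
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (rs, re_), (qs, qe) in zip(*aln.aligned):
        for off in range(re_ - rs):
            ri, qi = int(rs) + off, int(qs) + off
            pairs.append((ri + 1, qi))
            if ref[ri] == query[qi]:
                matches += 1
    identity = matches / len(pairs) if pairs else 0.0
    return pairs, identity


def build_residue_map(
    model: StructureModel,
    chain_role: ChainRole,
    threshold: float = IDENTITY_THRESHOLD,
) -> ResidueMap:
    """Map a tubulin chain's author numbering onto canonical positions.

    A global alignment of the chain sequence to the bundled reference for
    its subunit defines the canonical position of each residue; canonical
    positions missing from the chain (disordered residues) are simply
    absent from the map.
    """
    if chain_role.role not in ("alpha_tubulin", "beta_tubulin"):
        raise AnnotationError(
            f"chain {chain_role.chain_id}: residue maps are defined for tubulin "
            f"chains only (role={chain_role.role})"
        )
    alpha_ref, beta_ref = load_reference_sequences()
    ref = alpha_ref if chain_role.role == "alpha_tubulin" else beta_ref
    residues = [
        r for r in model.chains[chain_role.chain_id] if r.is_protein
    ]
    seq = "".join(r.one_letter for r in residues)
    aligned, identity = _align_pairs(ref, seq)
    if identity < threshold:
        raise AnnotationError(
            f"chain {chain_role.chain_id}: alignment identity {identity:.2f} "
            f"below threshold {threshold}"
        )
    pairs = [(residues[qi].seq_id, canon) for canon, qi in aligned]
    return ResidueMap(chain_id=chain_role.chain_id, pairs=pairs, identity=identity)


# ---------------------------------------------------------------------------
# α↔β correspondence


def build_correspondence_table() -> list[tuple[int, int]]:
    """(α canonical, β canonical) pairs from aligning the two references."""
    alpha_ref, beta_ref = load_reference_sequences()
    aligned, _ = _align_pairs(alpha_ref, beta_ref)
    return [(a, qi + 1) for a, qi in aligned]


def load_correspondence_table() -> list[tuple[int, int]]:
    """The shipped α↔β canonical-position correspondence."""
    pairs = []
    for line in _data_text("alpha_beta_correspondence.tsv").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.split("\t")
        pairs.append((int(a), int(b)))
    return pairs


# ---------------------------------------------------------------------------
# Annotated model bundle


@dataclass
class AnnotatedModel:
    """A model together with chain roles and tubulin residue maps."""

    model: StructureModel
    roles: list[ChainRole]
    maps: dict[str, ResidueMap]
    registry: SSERegistry

    @classmethod
    def annotate(
        cls, model: StructureModel, registry: Optional[SSERegistry] = None
    ) -> "AnnotatedModel":
        registry = registry or SSERegistry.default()
        roles = classify_chains(model, require_tubulin=True)
        maps = {
            r.chain_id: build_residue_map(model, r)
            for r in roles
            if r.role in ("alpha_tubulin", "beta_tubulin")
        }
        return cls(model=model, roles=roles, maps=maps, registry=registry)

    def role_of(self, chain_id: str) -> str:
        for r in self.roles:
            if r.chain_id == chain_id:
                return r.role
        raise AnnotationError(f"no role recorded for chain {chain_id!r}")

    def chains_with_role(self, role: str) -> list[str]:
        return [r.chain_id for r in self.roles if r.role == role]


# ---------------------------------------------------------------------------
# Element Cα extraction


def get_element_calphas(
    model: StructureModel,
    residue_map: ResidueMap,
    registry: SSERegistry,
    subunit: str,
    names: Optional[Sequence[str]] = None,
    domain: Optional[str] = None,
) -> tuple[np.ndarray, list[int], list[int]]:
    """Cα coordinates of the requested SSEs, in canonical-position order.

    Exactly one of *names* (explicit element names) or *domain*
    (all helix/strand elements of a domain) must be given.  Returns the
    coordinate array, the canonical positions used, and the canonical
    positions that were requested but unresolved in the chain.

    Raises :class:`GeometryError` when fewer than 3 positions resolve.
    """
    if (names is None) == (domain is None):
        raise AnnotationError("give exactly one of names= or domain=")
    if names is not None:
        elements = [registry.get(subunit, n) for n in names]
    else:
        elements = registry.in_domain(subunit, domain)
    wanted = registry.positions(elements)

    canon_to_author = residue_map.canonical_to_author()
    by_author = {
        r.seq_id: r for r in model.chains[residue_map.chain_id] if r.is_protein
    }
    coords, used, missing = [], [], []
    for pos in wanted:
        author = canon_to_author.get(pos)
        res = by_author.get(author) if author is not None else None
        ca = res.get_atom("CA") if res is not None else None
        if ca is None:
            missing.append(pos)
            continue
        coords.append(ca.coord)
        used.append(pos)
    if len(used) < 3:
        raise GeometryError(
            f"chain {residue_map.chain_id}: only {len(used)} Cα positions resolve "
            f"for the requested elements; superposition impossible"
        )
    return np.vstack(coords), used, missing
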