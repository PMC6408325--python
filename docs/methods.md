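# Methods

## Bend-angle model

An αβ-tubulin heterodimer is treated as two quasi-rigid subunits.  The
curvature ("bend") angle is defined as the magnitude of the rotation that
superposes the α subunit's N-terminal-domain secondary-structure elements
(helices and strands only; loops excluded) onto the equivalent β-subunit
positions.  The fit is the classical Kabsch solution: SVD of the Cα
cross-covariance with the determinant correction, so a reflection is
never returned; the scalar angle is `arccos((tr R − 1)/2)` and the
rotation axis is deliberately not reported.  The angle is invariant under
any global rigid motion of the model (conjugation invariance of the trace)
and is reported per heterodimer; multi-copy entries additionally get a
per-entry mean.

α↔β equivalence is a fixed position table obtained by globally aligning
the two bundled reference sequences (BLOSUM62, gap open −11 / extend −1,
free end gaps) and shipped as data
(`src/bendkit/data/alpha_beta_correspondence.tsv`); only positions aligned
in both subunits and resolved in both chains enter the fit, with a
minimum of 50 such positions for a reportable angle — a guard against
heavily disordered chains.

**Assumptions and caveats.**  The secondary-structure registry
(`sse_registry.tsv`) uses the classical structure-based tubulin numbering
with the tripartite domain partition N-terminal 1–205, intermediate
206–381, C-terminal 382–440, and H7 = 224–243, T7 = 244–251, H8 =
252–260, S8 = 312–316, H10 = 320–330, H10–S9 = 331–349, S9 = 350–356,
H1–S2 = 38–46.  Element boundaries in the literature differ by a residue
or two between authors; the registry is therefore a replaceable data file
and every boundary should be treated as provisional to roughly
±2 residues.  Equivalent ranges are used for both subunits, which the
structure-based numbering is designed to permit.

## Chain annotation

Roles are called by alignment-free k-mer containment (k = 4) against the
bundled α and β reference sequences with an acceptance threshold of 0.6:
tubulin paralogs and isotypes score well above it, unrelated chains near
zero, and k = 4 keeps low-complexity chains (e.g. poly-glycine) from
scoring spuriously.  Chains matching neither reference are called
*binder* when they are 80–300 residues long and lie within 5 Å of a
tubulin chain, else *other*.  Canonical numbering then comes from a
global alignment of each tubulin chain to its reference; residues absent
from the chain are simply absent from the map.  The bundled references
are mammalian-brain-type α/β tubulin sequences and may differ from any
given isotype at scattered positions; they are replaceable data files,
and every internal consumer uses whatever references are installed.

## Surface areas, contacts, clashes

SASA uses the Shrake–Rupley construction: each heavy atom carries a
sphere of radius `r_vdw + r_probe` sampled at `n` points placed by the
deterministic golden-spiral rule, and a point is buried if it falls
inside any neighbour's extended sphere.  Defaults: probe 1.4 Å, 960
points (quadrature error well under 0.5 % against the analytic
single-sphere and two-sphere spherical-cap closed forms), Bondi-style
radii bundled in `model.VDW_RADII` (C 1.70, N 1.55, O 1.52, S 1.80 Å, ...).
Waters are always excluded; hetero ligands (GTP/GDP, ions) are excluded
by default with an `include_hetero` toggle, since published buried-area
figures rarely state the convention.  BSA is
`SASA(A) + SASA(B) − SASA(A∪B)` with identical parameters in all three
terms; tiny negatives from quadrature noise are floored at zero.

Contacts are residue pairs with minimum heavy-atom distance strictly
below the cutoff (5 Å default), reported with that distance and, when an
annotated model is supplied, with the registry element containing each
tubulin residue.  The lattice graft superposes a complex's α subunit onto
a chosen lattice α subunit on N-terminal-domain SSE Cα atoms, carries the
binder atoms with the same transform, and counts heavy-atom pairs under
2.2 Å against any lattice chain.  The 2.2 Å cutoff is deliberately strict
(well under summed van der Waals radii): the question asked is "is this
pose physically impossible?", so only unambiguous overlap is counted.

## One-site binding model

The 1:1 equilibrium is solved in closed form: the complex concentration
is the physical root of `C² − (T + A + K_D)C + TA = 0`, evaluated as
`2TA / (b + √(b² − 4TA))` with `b = T + A + K_D` for numerical stability,
so mass conservation is exact to machine precision.  *Assembly-competent
tubulin* is the free macromolecule concentration from this root.

ITC heats follow the one-site (Wiseman) model.  The cell is tracked as a
concentration ladder over injections: with the displaced-volume
convention (default, matching perfusion-cell instruments) an injection of
volume `dv` into cell volume `V₀` scales existing concentrations by
`1 − dv/V₀` before the aliquot mixes in; a naive growing-volume
alternative is provided by toggle.  The heat of injection *i* is
`q_i = ΔH·V₀·(B_i − f_i·B_{i−1})` in μcal, where `B` is the bound-site
concentration from the exact quadratic with site concentration `n·[M]`.
Fitting is nonlinear least squares over `(n, log₁₀ K_D, ΔH)` in μcal
space (numerically simplest; a per-mole-of-injectant conversion utility
is provided), with standard errors from the Jacobian at the optimum and a
warning when the Wiseman c-value `n·[M]₀/K_D` leaves [1, 1000].  Derived
state functions use `ΔG = RT ln K_D` with R = 1.9872×10⁻³
kcal mol⁻¹ K⁻¹ and `TΔS = ΔH − ΔG`; the default temperature is 293.15 K.
No baseline/heat-of-dilution term is fitted by default (synthetic data
has none; real data should be blank-subtracted first).

Default titration geometry: 19 × 2 μL injections of 160 μM titrant into
a 0.24 mL cell at 15 μM macromolecule — a standard small-cell protein
titration reaching a molar ratio of ~1.7, giving c ≈ 160 for a 95 nM
binder.  Monte-Carlo recovery tests add Gaussian noise of 1 % of the peak
heat per injection, a typical integration noise for modern instruments.

## Synthetic data

Generators are pure functions of their parameters and seed.  The bent
dimer places the α reference sequence on a fixed compact non-degenerate
curve and builds the β chain as an exact rigid copy (rotation about a
fixed axis plus a 40.5 Å longitudinal offset) at the α↔β corresponded
positions, so the measured bend angle equals the constructed one by
construction and the whole annotation path (k-mer roles, alignment maps,
registry lookups) is exercised rather than mocked.  The toy protofilament
stacks straight dimers at an 81 Å repeat — the approximate tubulin dimer
spacing; only relative geometry matters for clash logic.  Binder chains
can be attached on the lateral (+x) or longitudinal (−z) face; only the
latter produces graft clashes, mirroring the assembly-blocking geometry.

What the fixtures do *not* emulate: real side-chain packing, B-factors,
crystallographic disorder, isotype mixtures, or ITC baseline drift.
Passing synthetic tests therefore demonstrates correctness of the
geometry and thermodynamics machinery, not robustness to every artefact
of experimental data — that is what the (user-enabled) deposited-structure
regression is for.

## Numerical choices

- Kabsch degeneracy: second singular value of the covariance < 1e-10 →
  error (collinear or coincident points).
- Altloc policy: highest occupancy wins, ties broken by altloc letter
  order; multi-model files contribute the first model only; hydrogens are
  excluded from all geometry.
- Alignment identity threshold 0.6 for residue maps; below it the map is
  refused rather than silently sparse.
- Fit parameterisation in `log₁₀ K_D` with bounds `n ∈ [10⁻³, 10]`,
  `K_D ∈ [10⁻¹⁵, 1] M`; tolerances 1e-14 so the noise-free round trip is
  exact to < 1e-6 relative error.
- Survey ordering uses a stable sort on the per-entry mean so tied means
  preserve input order.

## Known limitations

- Bend angles depend mildly on the registry element boundaries; absolute
  values should be quoted with the registry in hand, and cross-study
  comparisons are safest as rank order.
- SASA ignores ligands by default; buried-area comparisons against
  figures computed with ligands included can differ by a few percent.
- The one-site model assumes a single class of independent sites; no
  sequential or multi-site schemes are provided.
- No crystallographic symmetry expansion: an "asymmetric unit" analysis
  sees exactly the chains present in the file.
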