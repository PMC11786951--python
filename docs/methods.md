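# Methods

This note documents the models, numerical choices and limitations
behind each stage of the pipeline, and what the synthetic-data tests do
and do not establish about real structures.

## Structure input

PDB files are parsed with gemmi. Cofactor stripping removes every
HETATM record, waters included, so descriptors see the bare protein.
Alternate locations are resolved to the highest-occupancy conformer
(ties broken by altloc label order, the PDB convention). Hydrogens are
ignored: the X-ray structures this workflow targets typically lack
them, and all radii below are heavy-atom van der Waals radii
(C 1.70, N 1.55, O 1.52, S/P 1.80, halogens per element, 1.70 for
unknown elements — fixed table, frozen for reproducibility). All
coordinates are Å; nothing converts units.

The hydrophobic-atom rule is deliberately coarse and deterministic:
carbon and sulfur are apolar, everything else polar. A residue-aware
scale would change hydrophobicity values but not the pipeline's
structure; the element rule keeps the descriptor a pure function of
the structure.

## Cavity detection

The detector voxelizes the bounding box (default spacing 0.8 Å, margin
wide enough that every boundary cell is solvent). Two occupancy masks
are built: cells inside any van der Waals sphere ("protein") and cells
inside any sphere inflated by the probe radius (default 1.4 Å). The
complement of the inflated mask is probe-center space; a 6-connected
flood fill from the box boundary splits it into bulk and trapped probe
positions. Rolling the probe (an Euclidean-distance dilation by the
probe radius) over bulk positions gives the solvent-covered region;
rolling it over trapped positions gives the cavity. This is a
morphological opening, so a cavity whose mouth is narrower than the
probe stays closed — the "reachable only through a constricted mouth"
case — while thin crevices on an open surface, where no probe fits at
all, belong to neither solvent nor cavity and generate no spurious
pockets. Connected cavity components (6-neighborhood) below
`min_volume` (default 100 Å³, a small fragment-sized pocket) are
discarded; the rest are returned largest first. Pocket volume is
exactly cell count × spacing³.

Consequence worth knowing: a wide-open concave groove that the probe
can enter is *not* reported as a pocket. The detector finds enclosed
or mouth-constricted cavities, which is the regime the descriptors
(buriedness in particular) are designed around.

Surface points are centers of cavity cells 6-adjacent to a protein
cell. The shell is every residue with an atom within 3.5 Å of any
surface point.

## SASA and buriedness

SASA uses Shrake–Rupley with a deterministic 960-point Fibonacci
sphere per atom. Buriedness is

    1 − SASA(shell atoms in the full structure) / SASA(shell atoms isolated)

clamped to [0, 1]. The in-context term counts a surface sample point
only if the probe centered there is connected to bulk solvent (lookup
in the detector's flood-filled bulk region, dilated by one cell to
absorb rounding at the solvent boundary). Plain Shrake–Rupley tests
only local sphere overlap, so it would report the sealed interior of a
closed cavity as "accessible" and a fully enclosed lining could never
reach buriedness 1; the bulk-connectivity condition restores the
physical meaning of *solvent*-accessible and makes buriedness respond
monotonically as a cavity mouth opens. The isolated-shell term uses
plain Shrake–Rupley (an isolated shell has no sealed interior).
The buriedness ratio is read as shell-atom-SASA-based; the alternative
pocket-surface reading is noted as ambiguous in the underlying
description of the descriptor and was not adopted.

## Hydrophobicity, site points, enclosure, polarity scores

Hydrophobicity: each pocket surface point is attributed to its nearest
shell atom within 4.5 Å (surface cells sit within roughly one van der
Waals radius plus one cell diagonal of the lining, so the cutoff is
not binding in practice); the descriptor is the fraction of attributed
points whose atom is apolar.

Site points resample the cavity on a 1.0 Å lattice (occupied-bin
count; whether a real site-point set equals grid cells is treated as a
tunable, and the scoring formulas cap n at 100 anyway). Enclosure
casts 64 deterministic Fibonacci-lattice rays from each site point
(subsampled to at most 128 site points, evenly); a ray is blocked if
any sample at 0.4 Å steps within 8 Å lies inside an atom. Enclosure is
the mean blocked fraction. The 8 Å cutoff means a very large enclosed
cavity (chords longer than 8 Å) scores below 1 even when sealed; the
limit "fully enclosed → 1" holds for binding-site-sized cavities.

Hydrophilic and hydrophobic scores are exponential-falloff densities:
for each site point, Σ exp(−d/2 Å) over polar (resp. apolar) shell
atoms, averaged over site points and divided by a frozen constant
(11.96) measured once on a fully polar-lined closed reference cavity
of 6 Å inner radius — so that reference cavity scores ≈ 1, matching
the convention that a tight-binding site's polarity scores average
1.0. Balance is their ratio (defined when the hydrophilic score is
positive).

## Scoring formulas

The DLID density form standardizes (log₁₀ volume, buriedness,
hydrophobicity) with z-scores of the reference set and counts
neighbors in a Euclidean ball of radius 1.0 (configurable) in that
space. Both DLID logarithms are base 10 (the field's convention; the
1.71 offsets of the density and regression forms are implemented as
independent constants). An empty neighborhood raises and callers fall
back to the regression form; a neighborhood with no DLLC member
returns −∞ with a warning rather than silently failing.

SiteScore/Dscore default to the √n′ site-size term: the literal
linear-n weights give values near 7 for a typical 100-site-point
pocket, inconsistent with the documented ≈ 1.0 calibration of good
sites; √100 = 10 restores that scale. The literal form is kept behind
`mode="literal"` because it is how the weighted sums are sometimes
printed. Hydrophilicity is capped at 1.0 in SiteScore only; Dscore
leaves it uncapped (that is what lets it separate charged
ligand-binding sites from druggable ones). Thresholds: DLID druggable
strictly above 0.5; SiteScore druggable at or above 0.80.

## Ranking and docking triage

Min–max normalization requires at least two values and a nonconstant
column. The composite is the plain sum of the three normalized method
scores; ranking is descending with alphabetical tie-break (real tables
have no ties; determinism requires a rule). Exclusions are
configuration — a list of target ids with a free-text reason — not
hard-coded biology. Published-table comparisons use ±0.002 (composites
recomputed from 3-decimal printed values) and ±0.001 (renormalized
DScore column), i.e. printed-rounding tolerances.

Docking thresholding is inclusive (score ≤ −20 kcal/mol). No printed
score equals −20 exactly, so the choice is observationally neutral on
the packaged tables; it is documented here because raw tables could
contain boundary values. Molecule ids are canonicalized (strip
whitespace and underscores, casefold) before any comparison, because
published identifiers are typographically inconsistent; a
representative original spelling is retained for display. Duplicate
(target, molecule) rows collapse to the most negative score with a
warning.

## Synthetic data

`make_cavity_structure` builds concentric quasi-uniform atom layers
(Fibonacci lattices, 1.6 Å lateral spacing, 1.6 Å radial gap — dense
enough that a 1.4 Å probe cannot leak between atoms) around an empty
sphere; the mouth is a spherical cap of given solid-angle fraction
removed from all layers. The default shell is three layers (4.8 Å)
so the cavity lining is occluded from outside by a full atom layer.
Lining composition assigns exactly the requested fraction of carbon
atoms (positions shuffled by the seed). Each atom is its own residue,
which makes shell-residue tests exact.

The buriedness-vs-aperture sweep uses apertures 0.024–0.034. The
window follows from the geometry (hole radius ≈ R sinθ − r_vdw):
below ≈ 0.021 the mouth is still sealed at van der Waals contact and
buriedness saturates at 1; above ≈ 0.035 the probe passes the
inner-layer hole and the flood fill no longer traps a cavity.

Score-table and docking-table generators draw uniformly over the
observed ranges of the three methods (DLID best-pocket scores in
[−1.5, 2.1], DScore in [0.38, 1.24], SPIDER possibility in
[0.085, 0.089]) and plant structure exactly: hit tails below −20 at a
fixed fraction, and shared molecules inserted into two targets'
top-10 with scores below every background score. All generators are
pure functions of their seed.

What the synthetic structures do *not* emulate: real packing density
and element composition, side-chain geometry, multiple chains,
crystallographic artifacts, and open druggable grooves. Passing the
cavity tests shows the detector and descriptors behave correctly on
controlled geometry; it does not certify agreement with any particular
proprietary pocket finder's numbers on real proteins (the packaged
published tables are treated as fixtures, not regeneration targets).

## Problem sizes and runtime

Defaults keep everything desk-scale: synthetic cavities are ~1300
atoms on grids of ~10⁵ cells (a detection plus full descriptors runs
in a few seconds), SASA uses 960 points/atom, enclosure ≤ 128 site
points × 64 rays × 20 samples. The full test suite runs in about a
minute; the acceptance script in ~20 s.

## Known limitations

- Open (probe-enterable) pockets are not detected; see above.
- Enclosure saturates below 1 for cavities larger than the 8 Å ray
  cutoff.
- The polarity-score normalization constant is calibrated on one
  reference geometry; absolute hydrophilic/hydrophobic scores on very
  different geometries are comparable only in order of magnitude.
- Buriedness of a manually constructed pocket without grid context
  falls back to plain Shrake–Rupley for the in-context term (no bulk
  filter), which can overstate accessibility of sealed linings.
- SPIDER possibilities are ingested at printed precision; the module
  never recomputes them.
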