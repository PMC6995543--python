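# Methods

This note records the models implemented by `earlyfold`, the numerical
choices behind them, what the synthetic generators do and do not emulate,
and the known limitations.

## Backbone geometry

Torsions use the IUPAC convention (cis = 0°, trans = 180°; sign checked
against biotite's `dihedral`), reported in degrees in (−180, 180].
φ(i) is the torsion C(i−1)–N(i)–CA(i)–C(i) and ψ(i) is
N(i)–CA(i)–C(i)–N(i+1); an angle is undefined wherever a needed atom is
missing or residue numbering is discontinuous. The aperture angle V
between adjacent peptide-bond planes is the angle between the normals of
the CA–C–N planes of consecutive peptide bonds, folded into [0°, 180°]
(the curvature relationship carries no sign).

**Radius of curvature.** The literature behind the elliptical path never
prints a formula for the five-residue radius of curvature, so the package
defines one that is exact in the two idealized regimes the quantity is
meant to capture. The five CA positions are projected onto a plane and
fitted with an algebraic least-squares circle (Kåsa). Candidate
projection axes are the three principal axes of the point cloud plus the
smallest singular direction of the three second-difference vectors — for
a uniform-step helix the second differences are exactly perpendicular to
the cylinder axis, and for a planar arc they span the plane. The
projection with the smallest circle residual wins. The result is exact
for points on a planar circle and for CA points on an ideal helix
(cylinder radius recovered to machine precision), and is invariant under
rigid motion. Collinear traces return +∞, and such fragments are dropped
from the ln R fit (ln R is the natural logarithm).

## The elliptical early-stage path

`derive_ellipse` realizes the path derivation end to end: every
pentapeptide contributes (ln R, V) and its central (φ, ψ); a quadratic
ln R = aV² + bV + c is fitted by least squares; fragments within a
configurable residual band of the fit are the "relaxed" ones; and their
(φ, ψ) points receive a direct least-squares conic fit constrained to an
ellipse (Halir–Flusser formulation of the Fitzgibbon method). Fits whose
conic is not an ellipse, or with fewer than 50 usable points, are
rejected.

**Default ellipse.** The original publications do not print the ellipse
constants, so the package refuses to hard-code them. The default spec is
*derived at run time* from a synthetic calibration corpus: 60 chains of
50 residues whose torsions are jittered (σ = 3°) around a canonical path
through the main Ramachandran basins — an ellipse centered at (0, 0) with
semi-axes (130°, 70°) tilted 120°, which passes near the right-handed
helix (≈ −60°, −35°), the β region (≈ −65°, 112°) and the left-handed
helix. The calibration seed is fixed, so the derived default is
reproducible; real-data studies should derive their own spec from their
own corpus.

**t angle and codes.** t is measured clockwise (in the standard
Ramachandran axes) from the anchor, which defaults to the ellipse point
of maximal φ — in the lower-right quadrant (φ > 0, ψ < 0) for
Ramachandran-like tilts; the constructor enforces the quadrant.
Projection minimizes Euclidean distance in degrees on the unwrapped
(φ, ψ) plane (inputs are wrapped into (−180, 180] first; the ellipse is
interior to that square, so no torus metric is needed). The nearest
point is found by a 0.5° coarse parametric scan that brackets every local
minimum of the distance, each refined by bounded scalar minimization
(xatol 1e-12); this is slower than a bare Newton iteration but has no
convergence failures at any eccentricity, and it matches a 0.001°
dense-scan oracle to better than 1e-3°. Exact-center ties break to the
smaller t. Codes come from the integer interval table (A 0–50, B 51–85,
C 86–110, D 111–150, E 151–193, F 194–225, G 226–359); real-valued t is
floored first, making the intervals half-open [from, to+1) in real t, so
the printed integer table is preserved verbatim. The t histogram has
exactly 360 one-degree bins. Local maxima of the (circularly smoothed,
default window 5) histogram are reported with a prominence floor of 2% of
the dynamic range so counting noise on flat baselines does not create
spurious peaks; boundaries are proposed at the minima between adjacent
maxima.

## Fuzzy-oil-drop model

The theoretical density T is a centric 3D Gaussian: effective positions
(CA atoms; incomplete residues are skipped and excluded from N) are
centered and rotated to principal axes, and each axis takes
σ = max|coordinate|/3 (the three-sigma convention of the FOD literature);
axes with no spread contribute nothing. The observed density O sums
(H_i + H_j)·g(r_ij/c) over partners within c = 9 Å, self term included,
where g(x) = 1 − (7x² − 9x⁴ + 5x⁶ − x⁸)/2 is the Levitt sigmoid contact
polynomial (g(0) = 1, g(1) = 0). Both densities normalize to 1, and both
are invariant under rigid motion of the structure.

RD = D(O‖T) / (D(O‖T) + D(O‖R)) with R the uniform density 1/N;
divergences are computed in bits, and RD is invariant to the logarithm
base. RD < 0.5 classifies the domain as compliant. The intrinsic scale
is a required configuration point; the packaged default is Kyte–Doolittle
min–max scaled to [0, 1] and is a documented stand-in — every planted
test uses the synthetic rank scale (0/19 … 19/19 over the alphabet), so
no result in this package depends on the default.

**Trimming.** Noncompliant domains are shredded iteratively: each
iteration recomputes T (Gaussian re-centred, re-oriented and re-scaled on
the retained subset) and O, then removes the residue with the largest
|T − O| (ties to the lowest index; a signed variant using O − T is
available as `trim_metric="signed"` since the source description does not
fix the sign). Full recomputation keeps every iteration a well-formed
FOD evaluation. The loop stops when RD < 0.5; if the retained set would
drop below 5 residues first, every position is labelled noncompliant and
a never-compliant flag is raised. Maximal runs of ≥ 4 equal labels feed
the window corpora.

## Contingency tables and the screen

Windows are 4 residues; windows containing an undefined code or an X
residue are dropped, and in noncompliant-origin domains a window must lie
entirely inside one qualifying status run. Tables are sparse with fixed
logical capacity 160,000 × 2,401 (lexicographic rank over the 20-letter
and 7-letter alphabets). The smaller-total table is always the one
scaled up, by the exact size ratio, with real-valued counts (re-rounding
would break the invariance of Pearson r under positive scaling).

The correlation is Pearson's product-moment coefficient — consistent with
the 1.96 normal critical value via the large-n z approximation of the
Pearson t test, z = r√(n−2)/√(1−r²), compared two-sided to 1.96 at
α = 0.05 (|r| = 1 is significant by convention). By default r runs over
all canonical cells of a column (n = 2401) or row (n = 160,000) for keys
occupied in at least one table, keeping n fixed as the critical-value
approximation assumes; `cells="joint_nonzero"` restricts to cells nonzero
in both tables for sensitivity analyses. No multiple-testing correction
is applied, matching the original analysis. Undefined correlations
(constant vectors) are flagged, never significant.

## Synthetic data: what it emulates, and what it does not

`sample_torsions` draws from a Gaussian mixture over Ramachandran basins
(right-handed helix 0.40, β 0.30, polyproline II 0.20, left-handed helix
0.10 by default); noise is Gaussian per angle, not von Mises — adequate
away from the ±180° seam. `build_backbone` extends a chain from ideal
internal coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; angles
111.2°/116.2°/121.7°; ω = 180°); the round trip through
`compute_dihedrals` reproduces torsions to ~1e-13°, and is the standing
cross-validation of both modules.

`make_fod_case` builds globular CA clouds (anisotropic Gaussian,
σ = (7, 6, 5) Å, giving a 60-residue cloud the radius of gyration of a
small domain and a dense 9 Å contact network) and rank-matches (or
anti-matches) intrinsic hydrophobicity to the centric Gaussian density.
`make_trim_case` inverts the hydrophobicity rank of the k = 14 most
central residues, chosen so the anomaly actually drives RD above 0.5 and
trimming engages. `make_planted_corpus` gives every tetrapeptide a dense
Dirichlet(0.5) profile over all 2,401 code states; signal tetrapeptides
use a rank-reversed profile in the noncompliant class, which makes the
population correlation negative (Chebyshev's sum inequality: anti-sorted
pairing pushes Σp·q below 1/n). Dense profiles matter: two *sparse*
nonnegative count vectors cannot be significantly anti-correlated over
all cells, because any support overlap contributes positively and the
means are nearly zero. Corpus defaults (3,200 compliant / 800
noncompliant domains of 20 windows each, 50 null + 3 signal
tetrapeptides) give each tetrapeptide roughly 1,200 / 300 windows per
class — enough to resolve the planted contrast through multinomial
sampling noise — and keep the compliant set about four times the
noncompliant one, the imbalance the scaling step exists for.

None of the generators emulate real side chains, solvation, experimental
artifacts (occupancy, altlocs, B-factors), or the sequence–structure
coupling of real proteins: passing the planted tests demonstrates that
the statistical machinery recovers a contrast *that is present*, not that
real proteomes contain one.

## Problem sizes and defaults

| parameter | default | meaning |
|---|---|---|
| interaction cutoff c | 9 Å | contact kernel support |
| RD threshold | 0.5 | compliant / noncompliant boundary |
| minimum status run | 4 | residues with equal labels |
| window length | 4 | tetrapeptide |
| α / critical value | 0.05 / 1.96 | two-sided large-sample test |
| minimum domain length | 5 | pentapeptide geometry |
| ellipse residual band | 1.0 (ln R units) | relaxed-fragment filter |

The acceptance script evaluates the screen over 10 corpus seeds and the
FOD separation over 50 paired cases at n = 60, the sizes at which the
planted effects are comfortably resolvable on a single CPU.

## Known limitations

- mmCIF, CATH/SCOP lookups and redundancy clustering are out of scope;
  domain boundaries come from an explicit range TSV.
- Only CA-mode effective positions exist (the residue records are
  backbone-only), so side-chain-centroid FOD variants are unavailable.
- The default ellipse is calibrated on synthetic torsions, not on a
  structure database; treat it as a demonstration spec.
- Whether the original analyses computed correlations over all cells or
  only occupied cells is not documented; both are supported and the
  default (all cells) is stated above.
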