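# Methods

`nicoord` analyses how nickel ions are coordinated by protein residues. It
takes metal-bound structures (PDB format), finds every Ni site, quality-
controls it crystallographically, describes the coordinating residues as a
*chelate loop* with positional spacing, classifies the coordination
geometry, tabulates spacing statistics as a probability table, and mines
PROSITE-style nickel-binding signatures from family alignments. This note
records the model, the parameters that matter, and the design choices made
where reasonable alternatives existed.

## First shell and donor census

The first shell is every atom within an inclusive distance cutoff of the
metal (default **3.0 Å**, the standard interaction radius for metal ions in
protein crystal structures). Shell atoms are partitioned into:

* **protein donors** — polymer atoms;
* **hetero donors** — non-water HETATM atoms;
* **solvent** — water oxygens (residue names HOH/WAT/DOD);
* **carbon contacts** — any carbon inside the shell.

Carbons are recorded but never counted as donors: a His CE1 frequently
falls inside 3 Å purely because the coordinating ε-nitrogen drags it in.
The **coordination number (cn)** is the count of non-carbon, non-hydrogen
atoms across the first three lists. Hydrogens are parsed but excluded from
the census by default (`include_hydrogens` to override): crystallographic
H placement is model-dependent, so a sub-2 Å H–Ni contact says more about
the riding model than about coordination chemistry.

Neighbour search uses a k-d tree; the test suite checks it against an
independent all-pairs brute-force scan, membership-exact on 200 random
structures.

## Chelate loops, spacing and size

The chelate loop is the ordered set of protein residues (on the *analysis
chain* — the chain contributing the most protein donor atoms, ties broken
alphabetically) donating at least one non-carbon atom. It is written as a
one-letter pattern (`HDH`) with spacing in `n / n+k / m` notation: the
first donor is `n`, later donors are offsets from it, and any offset above
100 residues collapses to `m` (such donors are brought in by tertiary
folding, not by local sequence geometry). Chelate size is the inclusive
span `last − first + 1`; this convention makes the number of one-donor
chelates equal the number of size-1 chelates, which is how the two
censuses agree. Donors on other chains stay in the site and count toward
cn but are excluded from the pattern — residue arithmetic is only
meaningful within one chain.

## Validation filters

Two filters, both idempotent:

1. **Residue quality** — a coordinating residue is flagged when any donor
   atom has B ≤ 2.0 Å² (implausibly rigid) or occupancy outside
   [0.5, 1.0] (partially occupied conformations make the modelled
   coordination unreliable); one flagged residue excludes the structure.
2. **Deviation outlier** — the metal's B-factor should track its
   environment; structures with |B(metal) − mean B(residues)| ≥ 7.0 Å²
   are excluded. The mean is over all atoms of the coordinating residues
   (flag to restrict to donor atoms). The threshold is in Å² — the same
   units as B — and the comparison is inclusive.

The surviving set is summarised by the Pearson r (R² is reported
alongside, since either convention appears in the literature) between
metal and mean-residue B-factors. Group comparisons use Kruskal–Wallis
with mid-ranks and tie correction (scipy); the degenerate all-identical
input returns H = 0, p = 1 rather than erroring.

## Geometry classification

For *d* donor atoms the classifier computes all C(d, 2) metal-centred
angles and compares the sorted multiset against ideal templates (linear;
trigonal planar/pyramidal; tetrahedral, square planar, see-saw; square
pyramidal, trigonal bipyramidal; octahedral) by RMSD; the smallest RMSD
wins. Choices:

* the see-saw reference is the standard disphenoidal one (trans axial
  pair at 180°, axial–equatorial ≈ 90°, equatorial–equatorial ≈ 120°); an
  all-cis ≈ 90° variant is also scanned and the better RMSD is used, still
  labelled see-saw;
* five-donor sites always compete square pyramidal against trigonal
  bipyramidal so the classifier is falsifiable rather than reproducing a
  foregone conclusion;
* bidentate residues contribute every donor atom to the angle set (an
  Glu bidentate in a 5-residue chelate can therefore produce an
  octahedron);
* `distorted` flags an angular RMSD above **15°**. Noise studies on ideal
  templates put clean assignments far below this (σ = 0.05 Å of
  coordinate noise at a 2.1 Å bond ≈ 2° of angular noise), so the flag
  separates template-consistent distortion from genuinely irregular
  sites. More than six donor atoms is labelled irregular outright.

Classification is invariant under rotation, translation and uniform
scaling (angles only), which the tests verify.

## Backbone dihedrals and Ramachandran regions

φ = C(i−1)–N–CA–C and ψ = N–CA–C–N(i+1), computed by the atan2 torsion
formula, range (−180°, 180°]; chain-terminal residues get an undefined
marker. Region windows: **A** (right-handed helix) φ ∈ [−180, 0),
ψ ∈ [−120, 60); **B** (sheet) φ ∈ [−180, 0) with ψ ≥ 60 or ψ < −120 —
the sheet window wraps through ±180, which is the only self-consistent
reading of a "60 to −240" span; **E** (left-handed helix) φ ∈ [90, 100],
ψ ∈ [−20, 80]; **CD** (partially allowed) φ ∈ [−180, −40], ψ ∈ [−40, 0).
The windows overlap; assignment precedence is A, B, E, CD. Per-donor
secondary structure letters are H (region A), S (region B), T (anything
else).

## Probability and position tables

Within each chelate loop, every ordered donor pair (a at p, b at p + k)
with 1 ≤ k ≤ 10 increments count(a, b, k); loops wider than the window
contribute only their qualifying sub-pairs. Ten residues is the designable
window: coordination numbers top out near 8, and a chelating peptide
longer than that stops being a local motif. Probabilities divide by the
single global total of counted occurrences (not per-row), so the table
answers "which pair-at-spacing is most common overall". The position table
is the support of the count map: cell (a, k) lists every b with a nonzero
count — it is derived strictly from counted pairs, never hand-curated.

Pair spacing sets are rendered as PROSITE patterns: spacing 1 → `a-b`,
single spacing k → `a-X(k−1)-b`, a run of consecutive spacings →
`a-X(lo−1,hi−1)-b`, non-contiguous sets one pattern per run.

## PROSITE scanner

A full local pattern matcher (the published analysis used a web scanning
service): literals, `[ABC]` sets, `{ABC}` exclusions, `X`/`X(m)`/`X(m,n)`
wildcards, `<`/`>` anchors. All match spans are reported, overlapping ones
included, and every wildcard length is tried — one start can yield several
spans. An `X` in the *sequence* (unknown residue) matches only a pattern
wildcard, and exclusion elements do not match it either. The tests hold
the scanner against an independent regex-translation oracle (all-substring
fullmatch) on 1,000 random pattern/sequence pairs.

## Signatures from alignments

Redundancy reduction is greedy longest-first clustering at 90 % identity;
identity is matches / max(length) under a global alignment scoring 1 per
identity and nothing else, which makes the measure deterministic and
order-stable. A column is **conserved** when its modal residue occurs in
more than half the sequences; gaps never conserve a column.

Extraction scans maximal runs of columns without a gap majority and emits
one candidate per run: conserved columns become literals, unconserved ones
become collapsed `X(k)` wildcards. A column with no majority residue may
become a bracket set, but only when 2–3 residues that are *each*
individually frequent (≥ 0.2) *jointly* cover more than 0.75 of the
column. The joint-majority rule alone misfires badly at realistic depths —
with 8–10 sequences, almost any random column has three residues summing
past 0.5, and the resulting spurious constraints destroy sensitivity — so
the coverage bar is deliberately higher than the conservation bar.
Published signature sets include hand-built brackets of up to 7 residues;
the cap is configurable but defaults to 3.

A candidate is flagged *structure-supported* when it contains a donor pair
(a, k, b) with nonzero probability in the structural spacing table — the
cross-check between sequence conservation and coordination statistics.
Validation scans family members and a background set; sensitivity is the
family hit rate and specificity is one minus the background hit rate. A
family alignment generated with per-column conservation c < 1 contains
rows that do not carry the complete motif; no motif-specific pattern can
match those rows, so sensitivity is measured against the motif-carrying
members (the generator's truth record identifies them) while specificity
uses the full background.

Conserved/semi-conserved *substitution classes* are not modelled beyond
the bracket-set mechanism; no residue-class table is defined here.

## Synthetic data: what it emulates, what it does not

* **Ideal sites** place donor atoms exactly on template directions
  (default bond length 2.1 Å, the typical Ni–N/O distance) with optional
  Gaussian coordinate noise, and embed each donor in a residue stub whose
  backbone sits ≥ 4 Å out. They emulate coordination geometry, B-factor
  and occupancy bookkeeping — not rotamer chemistry, second shells, or
  crystal packing. Passing geometry tests therefore shows the classifier
  is correct on its own terms, not that real sites are noise-free.
* **Toy chelate tables** are exact pre-images of a requested
  (a, b, k) count census; each occurrence is realised as a two-donor loop
  so re-counting reproduces the census identically.
* **Planted-motif alignments** draw every row from a background
  distribution (uniform by default; a hydrophilic-enriched preset
  reflects the polar environment of nickel sites) and overwrite motif
  columns with the motif residue at probability = conservation,
  independently per row and column. Real alignments have phylogenetic
  correlation between rows; these do not, so background conservation is
  *rarer* here than in real families — extraction thresholds validated on
  these fixtures are necessary, not sufficient, for real data.

All generators are pure functions of their specs (fixed seed → identical
output).

## Numerical choices and problem sizes

* Cutoff comparisons are inclusive (≤ 3.0 Å, ≥ 7.0 Å², B ≤ 2.0 Å²).
* Alternate locations: the highest-occupancy conformer is kept, ties
  broken by the alphabetically first altloc id.
* PDB round-trip precision: coordinates to 3 decimals, B/occupancy to 2
  (format columns); tests assert at exactly this precision.
* Torsions are reported in (−180°, 180°], with −180 mapped to +180.
* Angle computations clip cosines into [−1, 1] before arccos.
* Test/acceptance problem sizes: 100 replicates per template for noisy
  geometry recovery, 200 random 50-atom structures for the shell oracle,
  1,000 random pattern/sequence pairs plus a 10,000-sequence background
  for the scanner, depth-10/length-60 families with 1,000 background
  sequences for signatures. These sizes give stable percentages while
  keeping the whole suite in seconds.

## Known limitations

* mmCIF and NMR multi-model files are out of scope; one model per file.
* No second-shell or bond-valence analysis; metal identity is taken from
  the element field, never inferred from geometry.
* Secondary structure comes from φ/ψ windows only, not hydrogen-bond
  (DSSP-style) assignment.
* MI values are exported for plotting elsewhere; no logo rendering.
* The greedy clustering representative depends on the documented visit
  order; it is a deterministic stand-in for heavier redundancy-reduction
  services, not a re-implementation of them.
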