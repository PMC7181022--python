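# Methods

## Features

Five per-residue quantities are measured for the 18 standard amino-acid
types that carry a χ1 torsion (Gly and Ala have no χ1 and are excluded
throughout).  Torsions are IUPAC signed dihedrals mapped into [0°, 360°) by
adding 360° to negative values; a value that rounds to exactly 360° wraps
to 0°.  φ needs the previous residue's C and ψ the next residue's N, so
both are unavailable at chain termini and across chain breaks; consecutive
residues whose C–N distance exceeds 2.5 Å are treated as a break.  χ1 is
N–CA–CB–X with X = CG for most types, CG1 for Ile/Val, OG for Ser, OG1 for
Thr, SG for Cys.

The two distances are Euclidean distances from CA to atomic-mass-weighted
centroids of heavy atoms only (hydrogens, rarely present in deposited
structures, are ignored): d_sidechain over all sidechain heavy atoms (CB
outward; for Pro the CB–CD ring atoms are included even though the ring
fuses to the backbone), and d_block over the residue's distal block.  The
block table ships as a plain-text config (`data/blocks.txt`) mapping each
type to its outermost rigid atom group — e.g. Leu {CG, CD1, CD2}, Cys
{SG}, Phe the aromatic ring — so alternative partitions can be tried
without code changes.  Residues with any unmeasurable feature are flagged
and excluded from fitting and scoring rather than partially scored.

## Model

Per (residue type, feature) a fixed-width histogram is fitted: 10° bins
over [0°, 360°) for the three angles (36 bins) and 0.1 Å bins over
[0, 10] Å for the two distances, plus one overflow bin that collects any
longer distance.  Counts receive add-one (Laplace) smoothing in every bin,
then are divided by the maximum so the modal bin is exactly 1; lookups
therefore lie in (0, 1] and scores are finite everywhere.  The score is
the sum over the five features of log(1/npdf), natural log by default
(base configurable); a residue scores 0 iff every feature is modal, and
the score increases strictly as any feature's npdf decreases.  The outlier
rule is strict: HBOS > 10 (a score of exactly 10 is not an outlier).  Bin
widths, distance domain and log base are exposed in `BinningConfig`; the
threshold is a parameter of `detect_outliers` and the CLI.

Models serialize to versioned JSON with decimal-faithful floats, so a
save/load round trip reproduces scores bit-for-bit and retraining on the
same inputs is byte-identical (no timestamps in the file).

## Dataset profiles

Score distributions are summarized as probability histograms with bin
width 0.1, normalized so the area under the curve is 1 — heights are
count/(n·width), making curves comparable across datasets of different
sizes.  The domain is [0, ⌈max score⌉] so no score is dropped.  The peak
is the modal bin (ties break toward the lowest bin center); both the
density height and the per-bin probability mass (height × width) are
reported, since "peak probability" is naturally read as the latter.
Tail fractions use the same strict inequality as the outlier rule.
Per-type outlier rates are 1000 × outliers/total over scored residues of
the type; unscored residues appear in neither numerator nor denominator.

## Secondary structure

The 8-state assignment implements the Kabsch–Sander dictionary algorithm
internally so the package needs no external binary: amide hydrogens are
rebuilt 1 Å from N along the preceding C=O direction; an H-bond exists
where the electrostatic energy 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH −
1/r_CN) is below −0.5 kcal/mol, with each donor keeping its two
lowest-energy acceptors; n-turns (n = 3, 4, 5), minimal helices from two
consecutive n-turns, parallel/antiparallel bridges, ladders (E for ≥ 2
consecutive bridges, B for isolated ones), hydrogen-bonded turns T and
bends S (CA-direction change > 70°) follow, with assignment priority
H, E, B, G, I, T, S.  β-bulge merging of ladders and the newer PP-helix
state are not implemented; on the clean fixtures used for validation this
does not matter, and the test bar is ≥ 95% per-residue agreement with
reference labels generated once from an independent implementation
(mdtraj's DSSP port), which is also cross-checked live in the suite.
Breakdown tables count outliers per type and state, with percentage
columns for coil (-), T, S, helix (G+H+I) and sheet (E+B), plus a derived
loop percentage (coil+T+S); percentages are rounded to two decimals, so a
row's three group percentages sum to 100 within 0.02.

## Validation-report cross-tabs

wwPDB validation XML is parsed per modeled residue; criteria are the
rama/rota attributes plus annotation child elements.  Any number of clash
records collapses to the single "clashes" criterion; omega and chirality
annotations count as separate criteria; unknown tags are preserved as
"other:<tag>".  Color follows the distinct-criterion count: 0 green,
1 yellow, 2 orange, ≥ 3 red.  The cross-tab reports, per type, the rate of
HBOS outliers that are nevertheless green, over residues joinable by
(chain, residue number, insertion code); residues absent from the report
are excluded and surfaced in a coverage count, and a join that matches
nothing raises (it almost always means a numbering-convention mismatch).

## Structure input

Parsing stands on gemmi (PDB and mmCIF; the two formats yield identical
residue/atom inventories for the same entry).  Only polymer amino acids
are kept; Mse and a few other modified residues map to their parent type;
waters, ligands and nucleotides are dropped.  Alternate locations resolve
to the highest-occupancy conformer, altloc "A" on ties.  Resolution comes
from the file metadata (refinement/EM-reconstruction fields in mmCIF,
REMARK 2 in PDB); resolution filters use half-open intervals (lo, hi] so
adjacent ranges like 1.5–2.0 / 2.0–2.5 Å never double-count a boundary
entry, and entries without resolution metadata are excluded and reported.
Within-entry duplicate chains (non-crystallographic symmetry copies) are
dropped when global sequence identity with a retained chain is ≥ 95%,
identity being exact matches over alignment columns under a unit-match,
small-gap-penalty global alignment (Biopython's PairwiseAligner); chains
are scanned in chain-ID order, so the alphabetically first copy is kept.

## Synthetic data

The generator provides every test input.  `build_peptide` constructs
peptides by internal-to-Cartesian (NeRF) placement from an embedded
Engh–Huber-style ideal-geometry table (L-configuration verified by CIP
assignment), at arbitrary prescribed φ/ψ/χ1 — the basis of the
build-then-measure round-trip oracles (recovered torsions agree with the
prescription to 1e-6°).  Fixtures include an α-helical 12-mer (φ = 303°,
ψ = 313°), a 14-mer antiparallel β-hairpin with a type I′ turn, and a
Gly-Leu-Ser tripeptide.

`sample_features` draws feature vectors from per-type generative models:
von Mises mixtures for angles (circular distributions respect the 0/360
wrap; naive Gaussians would not), truncated Gaussians for distances.  The
default spec covers six residue types with three-rotamer χ1 mixtures,
α/β/left-handed backbone mixtures, and centroid distances around the
values typical for each type (e.g. Leu d_sidechain 2.58 ± 0.10 Å, d_block
3.10 ± 0.12 Å).  `inject_outliers` displaces an exact fraction of records
in at least two features each — angles into the lowest-density 5% of the
mixture, distances to mean ± 8 sd — and returns truth labels.  The
recovery experiment (n = 50,000, 1% injected outliers, threshold at the
clean 99th percentile) is the package's end-to-end guarantee: sensitivity
≥ 0.95 and ROC AUC ≥ 0.99.

What the generator does **not** emulate: correlations between features
(real φ/ψ/χ1 are coupled), between-type frequency imbalance, experimental
coordinate error, and the full PDB-wide marginal shapes.  Passing tests
therefore demonstrate correctness of the measurement, fitting, scoring and
profiling machinery and the detectability of grossly rare conformations —
not that any particular real cohort will reproduce a given outlier rate.
Published cohort-level fractions (e.g. the tail fraction of a large
high-resolution X-ray set) additionally depend on the original training
corpus and on binning/log-base choices that are not on record, so they are
out of reach of a self-contained build; the breakdown-table arithmetic of
the published count table, by contrast, is reproduced exactly.

## Numerical choices

Collinear torsion quadruples raise a geometry error rather than returning
an arbitrary value.  Distances of exactly the domain edge (10 Å) fall in
the overflow bin; angle lookups wrap modulo 360 so 360.0 hits the 0° bin.
Histogram tie-breaks (peak location) go to the lowest bin center.  Score
sums run in fixed feature order (φ, ψ, χ1, d_sidechain, d_block), so
results are reproducible to the bit.  Problem sizes in the test suite and
acceptance script (50,000-record recovery runs, 10,000-quadruple torsion
checks, 10^6-sample flatness checks) were chosen so the statistical bounds
asserted have comfortable margins while the whole suite stays fast.

## Known limitations

* The distal-block table pins Leu (CG-CD1-CD2) from the published worked
  example; the other 17 entries are this package's own partition choice
  and may differ from other block definitions in the literature, which
  shifts d_block numerically (hence the table is config-replaceable).
* The DSSP implementation omits β-bulges and chain-break label variants,
  which real, irregular structures would exercise; agreement there should
  be checked against a reference DSSP via the cross-check parser.
* Omega/chirality criterion counting in validation reports follows this
  package's reading (each its own criterion); other tools may group them
  differently.
* The scorer treats features as independent (by construction of the score);
  jointly unusual but marginally common conformations score low.
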