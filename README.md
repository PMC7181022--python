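# hbosprof

Histogram-based outlier score (HBOS) profiling of protein atomic structures.

As more atomic models are built into cryo-EM density maps, per-residue
geometric validation beyond the standard deposition checks has become
important: a sidechain can satisfy bond-length, clash and rotamer criteria
and still sit in a conformation that is vanishingly rare among
high-resolution structures.  `hbosprof` scores every residue by how popular
its local geometry is in a reference population, and summarizes whole
datasets of structures so that cohorts (e.g. X-ray structures in different
resolution ranges, or cryo-EM depositions from different years) can be
compared.  It is aimed at structural biologists and methods developers who
want a lightweight, transparent quality profile next to the wwPDB
validation report.

## The score

For each residue that carries a χ1 torsion (all 20 standard amino acids
except Gly and Ala — 18 types), five features are measured:

* φ, ψ — backbone torsions C(i−1)–N–CA–C and N–CA–C–N(i+1),
* χ1 — first sidechain torsion N–CA–CB–X (X = CG, or CG1/OG/OG1/SG by type),
* d_sidechain — distance from CA to the mass centroid of the heavy
  sidechain atoms,
* d_block — distance from CA to the mass centroid of the sidechain's
  *distal block*, its outermost rigid atom group (for Leu, the CG–CD1–CD2
  triangle).

Angles use the 0°–360° convention so histogram bins never straddle a sign
flip.  On a reference set, a fixed-width histogram is fitted per (residue
type *j*, feature *i*) and rescaled so its modal bin is 1 — the normalized
density function npdf<sub>i,j</sub>.  A residue scores

```
HBOS_j(v1..v5) = Σ_{i=1..5} log( 1 / npdf_{i,j}(v_i) )
```

a naive-Bayes-style sum: 0 when every feature is modal, large when any
feature is rare.  A residue with HBOS > 10 is treated as an outlier.
Dataset profiles are area-normalized score histograms (bin 0.1), per-type
outlier rates per 1000 residues of the same type, breakdowns of outliers
over the 8-state secondary-structure classes (assigned with an internal
Kabsch–Sander implementation), and cross-tabs against wwPDB validation
reports ("green" residues are those with zero deposition-pipeline outlier
criteria; the interesting cases are green residues that HBOS still flags).

## Worked example

Score a synthetic reference population and profile it:

```python
from hbosprof import (default_generative_spec, sample_features, fit_model,
                      score_records, probability_histogram, find_peak,
                      fraction_above)

spec = default_generative_spec()
records = sample_features(spec, 20000, seed=7)      # clean feature vectors
model = fit_model(records)                          # per-(type, feature) npdfs
results = score_records(model, records)
scores = [r.total for r in results]

peak = find_peak(probability_histogram(scores))
print(f"peak HBOS bin center: {peak.center:.2f}  per-bin probability: {peak.mass:.4f}")
print(f"fraction of residues with HBOS > 10: {100*fraction_above(scores, 10):.3f}%")
print(f"outliers (HBOS > 10): {sum(r.outlier for r in results)} of {len(results)}")
```

prints

```
peak HBOS bin center: 2.45  per-bin probability: 0.0280
fraction of residues with HBOS > 10: 0.180%
outliers (HBOS > 10): 36 of 20000
```

The peak of the area-normalized histogram says which score is most popular
in the population and how popular it is (2.8% of residues per 0.1-wide
bin); the tail fraction above 10 is the dataset's outlier rate.  Scoring a
population against its own histograms yields a small but nonzero tail —
residues whose feature combination is jointly rare.

The same pipeline runs from the shell on PDB/mmCIF files:

```
hbosprof fixtures -o fixtures/            # synthetic ideal-geometry peptides
hbosprof train fixtures/ -o model.json
hbosprof score structure.pdb -m model.json -o scores.tsv
hbosprof profile scores.tsv -o profile/ --structures structure.pdb
```

`profile/` then contains the probability histogram, per-type outlier rates,
and the secondary-structure breakdown of outliers as TSV.

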