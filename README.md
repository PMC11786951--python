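# druggability

Structure-based target triage for drug repurposing: detect binding
pockets on protein structures, score their druggability, fuse scores
from several prediction methods into a composite target ranking, and
post-process docking score tables.

The package was built around the druggability assessment of
inflammation-related drug targets (largely classical complement-pathway
proteins and associated GPCRs such as DRD2 and GABA-A receptor), but
every stage is generic: any PDB structure, any per-target score table,
any docking result table.

## What it computes

**Pocket detection.** A grid-based cavity finder: the structure is
voxelized (0.8 Å), atoms are inflated by the 1.4 Å water probe, and
probe-center space is flood-filled from the box boundary. Probe
positions that fit inside the structure but cannot reach the boundary
are trapped; the cavity is the free space they cover. A pocket's
*shell* is the set of residues within 3.5 Å of any pocket surface
point.

**Pocket descriptors and druggability scores.**

- *Drug-like density* (DLID), in its density form

  DLID = log₁₀(DLLC neighbors / total neighbors) + 1.71

  counting reference pockets with similar (log₁₀ volume, buriedness,
  hydrophobicity) that contain a drug-like ligand (DLLC), and its
  regression surrogate

  DLID = −8.70 + 1.71 log₁₀ V + 3.94 b + 2.27 h

  where V is pocket volume (Å³), b buriedness (the fraction of the
  shell's solvent-accessible surface area lost in context relative to
  the shell in isolation) and h hydrophobicity (fraction of the pocket
  surface in contact with apolar shell atoms). A pocket with DLID > 0.5
  is called druggable.

- *SiteMap-style scores* over site-point count n (capped at 100),
  enclosure e and hydrophilic score p:

  SiteScore = 0.0733 √n′ + 0.6688 e − 0.20 min(p, 1)
  Dscore = 0.094 √n′ + 0.60 e − 0.324 p (p uncapped)

  SiteScore ≥ 0.80 distinguishes drug-binding from non-drug-binding
  sites. The √n′ default matches the calibration that a typical
  tight-binding site scores ≈ 1.0; the literal linear-n form is
  available as `mode="literal"`.

**Target ranking.** Per target, the best pocket score per method (plus
an ingested sequence-based SPIDER possibility — an external predictor
whose scores are inputs, never computed here). Targets missing any
method are dropped, each method column is min–max normalized,
x′ = (x − min)/(max − min), the three normalized scores are summed into
a composite in [0, 3], and targets are ranked (configurable exclusion
list for, e.g., early complement-pathway members whose inhibition would
be broadly immunosuppressive).

**Docking triage.** Binding scores at or below −20 kcal/mol count as
likely binders; per-target hit counts, top-10 tables, best hits, and
the molecules appearing in more than one target's selected set.

The published summary tables of the motivating target set — pocket
descriptors, SiteMap metrics, normalized composites, and the five
per-target docking tables — ship as packaged CSV fixtures
(`load_fixture("table1")` … `"table8"`), checksum-pinned.

## Worked example

Generate a synthetic cavity structure (a hollow pseudo-atom sphere with
a 6 Å cavity, half hydrophobic lining) and analyze it:

```sh
$ druggability synth cavity --seed 3 --out .
wrote cavity_seed3.pdb (1301 atoms)
$ druggability pockets --pdb cavity_seed3.pdb --out pockets.csv
1 pocket(s) written to pockets.csv
```

`pockets.csv` then contains one row per detected pocket:

```
pocket,volume,buriedness,hydrophobicity,n,e,p,balance,dlid,site_score,dscore,...
1,842.75,1.0,0.481,855,0.837,0.467,0.895,1.335,1.199,1.291,True,True
```

i.e. one sealed cavity of 842.75 Å³ (the analytic cavity volume is
905 Å³; the grid volume sits within discretization error), fully buried
(1.0), 48% of its surface in contact with apolar atoms, 855 site
points, enclosure 0.84 — hence DLID 1.34 (> 0.5, druggable) and
SiteScore 1.20 (≥ 0.80, druggable).

Ranking the packaged normalized score table and excluding the three
early-pathway complement proteins:

```sh
$ druggability rank --scores scores.csv --exclude C1QB,C1R,C3 --top 5
 1. DRD2       composite=2.463
 2. C4B        composite=2.442
 3. GABA-A R   composite=2.393
 4. C9         composite=2.018
 5. C5AR1      composite=1.889
```

which reproduces the published top-5 docking candidate set for this
target list.

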