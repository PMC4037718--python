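# flspace — the fragrance-like chemical space toolkit

Fragrance molecules are small, volatile, lipophilic organics: almost always
carbon/hydrogen/oxygen/sulfur only, with very few polar groups. `flspace`
implements a complete toolkit for exploring this corner of chemical space on
any SMILES/SDF collection:

* **MQN descriptors** — the 42 Molecular Quantum Numbers, integer counts of
  atoms (`c f cl br i s p`, acyclic/cyclic N and O, `hac`), bonds on the
  kekulized graph (`asb/adb/atb`, `csb/cdb/ctb`, rotatable bonds `rbc`),
  polarity features (H-bond acceptor/donor atoms and sites, formal charges
  at pH 7.4) and topology (node degrees split acyclic/cyclic, SSSR ring
  sizes `r3 … rg10`, fused-ring atoms/bonds `afr/bfr`). Molecules are
  ionized at pH 7.4 by a substructure rule table before counting.
* **Fragrance-likeness (FL) filter** — HAC ≤ 21, heavy elements ⊆ {C, O, S},
  O + S ≤ 3, H-bond donors ≤ 1; plus database property profiles (HAC,
  heteroatoms, clogP, ring-topology classes).
* **Exact similarity search** — city-block distance
  CBD(a, b) = Σᵢ |aᵢ − bᵢ| over MQN space, with a sum-hash index: entries
  are bucketed by Σᵢ aᵢ, and since |Σa − Σb| ≤ CBD(a, b) a range query with
  boundary `d_max` only inspects buckets within `d_max` of the query sum —
  exact results at a fraction of the scan cost. Searches support database
  bit masks, an isomer lock (same Hill formula) and H-bond donor/acceptor
  count locks.
* **Chemical-space maps** — covariance PCA of a reference MQN matrix
  (size-dominated PC1), refit-free projection of any set onto the
  (PC1, PC2) plane, rasterization to a 1000×1000 pixel grid, HSL colour
  coding (hue blue→cyan→green→yellow→red→magenta with increasing property
  mean, saturation fading with the within-pixel SD) and per-pixel "average
  molecules" (member closest to the pixel's mean MQN vector).
* **Ligand-based virtual screening (LBVS)** — family curation
  (promiscuity/FL/size rules), per-space medoid references, dilution into a
  background database, CBD ranking in four descriptor spaces (MQN, a
  1024-bit path fingerprint `Sfp`, the circular `ECfp4`, molecular weight),
  ROC/AUC with tie-aware Mann–Whitney scoring, and recovery-at-fraction
  tables.
* **Fixtures** — a curated set of classic fragrance molecules with
  documented Hill-formula checksums, and seed-deterministic generators for
  fragrance-like decoy libraries and structural-analog families.

The library is organised as scikit-learn-style estimators
(`MQNCalculator`, `FragranceLikeFilter`, `FingerprintEncoder`,
`MQNNeighborIndex`, `ChemicalSpacePCA`) with functional wrappers, plus a
`flspace` command line.

## Worked example

```python
from flspace import fixtures, build_index

curated = fixtures.curated_fragrances()
library = fixtures.generate_decoys(2000, seed=7) + curated.records
index = build_index(library)

hits = index.range_search(
    curated.record("menthone"), d_max=12, lock_hbd=True, lock_hba=True
)
print(len(hits), hits[:3])
```

prints

```
20 [('menthone', 0), ('carvone_minus', 4), ('carvone_plus', 4)]
```

menthone itself comes back at distance 0 (hit no. 1), the two carvone
enantiomers — also monocyclic C10 terpenoid ketones — at distance 4, and
17 further neighbours within CBD ≤ 12 that preserve menthone's H-bond
donor count (0) and acceptor count (1): exactly the
functional-group-preserving analog set the locks are designed to retrieve.
A quick enrichment run on the same library:

```python
from flspace import run_enrichment
from flspace.fixtures import generate_analog_family

family = generate_analog_family(
    curated.molecules["menthone"], 15, seed=3, name="menthoids"
).as_fragrance_family()
result = run_enrichment(family, library, "MQN")
print(round(result.auc, 1), result.recovery[0.01])
```

```
99.7 73.33333333333333
```

an AUC of 99.7% and 73% of the planted menthone analogs recovered within
the top 1% of the ranked library.

## Command line

```bash
flspace fixtures --decoys 10000 --seed 42 --out decoys.smi
flspace filter --in decoys.smi --out decoys.fl.smi --report report.json
flspace mqn --in decoys.fl.smi --out mqn.tsv
flspace index --in decoys.fl.smi --out lib.flx
flspace search --index lib.flx --query "CC1CCC(C(C)C)C(=O)C1" --dmax 12 \
    --lock-hbd --lock-hba --out hits.tsv
flspace map fit --in decoys.fl.smi --out pca.json
flspace map render --model pca.json --in decoys.fl.smi --property hac \
    --png map.png --tsv map.tsv
flspace lbvs --families fams.json --background decoys.fl.smi \
    --space MQN,Sfp,ECfp4,MW --out enrichment.tsv
```

Every command writes a `*.manifest.json` (arguments, package and toolkit
versions, input checksums) next to its outputs.
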