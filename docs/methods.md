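# Methods

This note documents the models, conventions and numerical choices behind
`flspace`, in the order a computation flows through the package.

## Molecule handling

Input molecules (SMILES files or V2000 SDF) are parsed with RDKit, reduced
to their **largest organic fragment** (salts and mixtures carry no meaning
in the fragrance-like space, which consists of single neutral organics;
ties in fragment size break on carbon content, then canonical SMILES) and
canonicalized with stereochemistry retained. Deduplication compares
stereo-aware canonical SMILES, so enantiomer pairs — which can smell
completely different — survive as distinct records; `ignore_stereo=True`
collapses them instead. Hill formulas put carbon first, hydrogen second and
all other elements alphabetically; carbon-free molecules are fully
alphabetical.

## Ionization at pH 7.4

All descriptor computation operates on a physiologically ionized graph,
produced by an ordered substructure rule table:

| group | rule | effect |
|---|---|---|
| carboxylic, sulfonic, sulfinic acids | pKa ≪ 7.4 | O–H → O⁻ |
| phosphonic/phosphate O–H | pKa ≤ ~7 | every acidic O–H → O⁻ |
| guanidines, amidines | conjugate acid pKa ≫ 7.4 | =N protonated |
| aliphatic amines (1°/2°/3°, non-amide, non-aromatic-attached) | pKa > 7.4 | N → N⁺H |
| alcohols, phenols, thiols, amides, anilines, pyridines | pKa outside window | unchanged |

Rules are mutually exclusive per atom (an atom charged by an earlier rule
is never re-matched), heavy-atom composition is never altered, and
molecules without ionizable groups pass through unchanged. The table is a
deliberate discretization — no continuous pKa model, no tautomer
enumeration. For the CHOS molecules of the fragrance-like space only the
acid rules ever fire; the nitrogen rules matter when the toolkit is run on
unfiltered databases. P-oxyacids lose every matched acidic O–H (at
physiological pH the second phosphate deprotonation, pKa ≈ 7.2, is about
half complete; a count model must round one way and the doubly charged
form keeps the rule per-O–H local).

## The 42 MQN descriptors

Fixed order: `c f cl br i s p an cn ao co hac | asb adb atb csb cdb ctb
rbc | hba hbd hbam hbdm pos neg | asv adv atv aqv cdv ctv cqv r3 r4 r5 r6
r7 r8 r9 rg10 afr bfr`.

Conventions, chosen where the descriptor family's published definitions
leave room and frozen here:

* **Kekulization before bond counting.** MQN has no aromatic-bond class, so
  aromatic systems are kekulized first; benzene deterministically counts
  `csb=3, cdb=3`. A non-kekulizable aromatic system is an explicit error.
* **Ring basis.** Ring sizes (`r3…rg10`) and fused-ring counts
  (`afr`/`bfr` = atoms/bonds in ≥ 2 rings) use the toolkit's deterministic
  smallest-set-of-smallest-rings, sized exactly at the circuit rank
  (bonds − atoms + components). This guarantees the conservation law
  Σ ring counts = circuit rank. Note that *symmetrized* SSSR variants
  (which RDKit's own MQN implementation uses) include extra symmetric rings
  on cages like the pinane skeleton and break that law; the two
  implementations agree on all ring counts whenever the bases coincide,
  which the test suite checks.
* **Node classes.** Heavy-atom degree only (H excluded), split by ring
  membership: acyclic degree 1–4 → `asv adv atv aqv`, cyclic degree 2–4 →
  `cdv ctv cqv`. Isolated heavy atoms fall in no class; degree > 4 is an
  error naming the offending atom.
* **Rotatable bonds** (`rbc`): acyclic single bonds between two heavy atoms
  of heavy-degree ≥ 2, excluding bonds whose end sits on a triple bond
  (rotation about a linear axis is unobservable).
* **H-bond counts.** Acceptor atoms: N and O except pyrrole-type N (lone
  pair in the aromatic sextet), amide N and positively charged atoms.
  Donor atoms: N or O bearing ≥ 1 H. Sulfur is neither (a switch exposes
  the thiol-as-donor alternative in the FL filter). Sites: `hbdm` = total
  hydrogens on donor atoms; `hbam` = lone-pair allowance per acceptor
  (neutral O 2, anionic O 3, N 1). These site conventions are documented
  stand-ins — the original descriptor set defers them to prior work — and
  are isolated in one function each, so published-value divergence is
  possible and easy to localize.
* **Charges** (`pos`/`neg`): counts of positively/negatively charged
  *atoms* after ionization, not charged groups.

Five conservation laws hold for every molecule and are enforced in tests
and in the acceptance script: N and O totals split exactly into
acyclic + cyclic; bond-class counts sum to the heavy–heavy bond count;
ring counts sum to the circuit rank; node-class counts sum to the
non-isolated heavy atoms; all 42 entries are non-negative integers.

## Fragrance-likeness

Four rules, all evaluated (no short-circuit) so a verdict lists every
violated rule: HAC ≤ 21; heavy elements ⊆ {C, O, S}; O + S ≤ 3; H-bond
donors ≤ 1, with the donor convention shared with the MQN block so filter
and descriptors can never disagree. Property profiles report normalized
histograms of HAC, heteroatom count (all non-carbon heavy atoms, so the
profile is meaningful on unfiltered databases), Wildman–Crippen clogP
(atom-contribution method; used in profiles only, never for filtering) and
the SSSR-count topology classes acyclic/mono/bi/polycyclic.

## Descriptor spaces and distances

Four spaces, all scored by city-block distance (CBD): MQN (42-d integer);
`Sfp`, a Daylight-type path fingerprint — linear paths of 1–7 bonds hashed
by the toolkit into 1024 bits, plus deterministically hashed length-0
(typed-atom) paths so single-atom molecules are representable; `ECfp4`,
the circular fingerprint of bond diameter 4 (radius 2) folded to 1024
bits; and MW, the molecular weight of the ionized form in Da. On binary
fingerprints CBD equals the Hamming distance. Fingerprint bit patterns are
exact only per toolkit version; tests therefore assert structural
properties and oracle equivalences, not frozen bit sets.

## The sum-hash index

Entries are stored in buckets keyed by the MQN sum. The L1 projection
bound |Σa − Σb| ≤ CBD(a, b) means a query with boundary `d_max` can only
have hits in buckets within `d_max` of its own sum, so range search scans
just those buckets and is provably exact — the test suite checks hit-set
equality against a full linear scan under every constraint combination.
Constraints: a wanted bit mask over ≤ 64 registered databases (hit if
`entry_mask AND wanted ≠ 0`, matching OR-combination of database choices),
an isomer lock (Hill-formula equality, applied *within* the distance
boundary), and H-bond donor/acceptor count locks. Results sort by
(distance, id); an indexed query molecule returns itself at distance 0.
kNN search wraps range search with an expanding boundary (doubling from 4)
and falls back to an unbounded scan once the bucket span is exhausted, so
it equals the first k rows of a fully sorted scan. Serialization is a JSON
header (registry, version) plus a TSV entry table — diffable and portable.

## Chemical-space maps

The map PCA is a covariance PCA of the centered, **unscaled** MQN matrix:
the 42 counts share a natural scale, and unscaled counts produce the
characteristic size-dominated first component (a `--standardize` flag
gives the correlation-PCA alternative). Sign convention: any component
whose loading sum is negative is flipped, so a size-like PC1 has positive
loadings throughout. At least three components are kept. Fitting requires
≥ 3 rows and ≥ 2 distinct rows; rank-1 data are legitimate (variance
fraction 1 on PC1).

Other sets are projected with the reference means and loadings — never
refitted — onto axis ranges derived from the reference projections,
expanded by 1% (0.5% per side); out-of-range points clamp to border
pixels. Pixel assignment is `floor` of the linear rescale onto the grid
(1000×1000 by default). Colour is HSL: hue interpolates linearly along
blue(240°)–cyan(180°)–green(120°)–yellow(60°)–red(0°)–magenta(−60°) over
the occupied-pixel mean range (orange ≈ 30° lies on the yellow–red leg),
saturation is `max(0, 1 − sd/sd95)` with `sd95` the 95th percentile of
positive pixel SDs (single-member pixels are fully saturated), lightness
is fixed at 0.5. The exact hue/saturation formulas are this package's
choices within the qualitative scheme. Each pixel's *average molecule* is
the member with minimal CBD to the pixel's component-wise mean MQN vector,
ties to the lowest id.

## Virtual-screening protocol

Curation of raw `{family: [SMILES]}` input applies, in order: removal of
molecules listed in more than 5 families (promiscuous odorants carry no
family signal), removal of non-FL molecules, an optional HAC cap (13 is
the natural choice when screening against libraries enumerated up to 13
heavy atoms), then dropping families below 10 members.

The reference compound of a family is its **per-space medoid** — arg-min
of the summed distance to all other members, ties to the lowest id, with
float-noise ties from summation order (relevant for MW sums) treated as
exact ties. The reference is excluded from the actives and from the ranked
list: including it would inflate every metric identically, so exclusion is
the conservative reading (a flag restores inclusion). Background entries
that duplicate a family structure are removed before dilution.

Candidates are ranked by ascending CBD to the reference. AUC is the
Mann–Whitney probability (in percent) that an active ranks above a decoy
with ties counted half — computed via average ranks and verified against
an O(n²) pairwise oracle in tests; ROC curves step tie groups diagonally.
Recovery at screened fraction f counts actives within the top
`max(1, floor(f·N))` candidates of the (distance, id)-sorted list; the id
order makes cutoff ties deterministic. Integer MQN distances tie often,
which is why every tie policy here is explicit.

## Synthetic data

The package ships no external databases. Two generators emulate the study
conditions instead:

* **Decoy libraries** (`generate_decoys`): random CHOS molecules from a
  fragment grammar — an all-carbon skeleton (random tree, 55% chance of a
  3–7-ring, occasional second ring closure), 0–2 double bonds, 0–3 O/S
  substitutions (80% O) with an at-most-one-terminal-OH budget — then
  sanitized, canonicalized and deduplicated. Defaults HAC 5–21 with
  `fl_bias` on, under which every emitted molecule passes the FL filter
  (the FL-subset composition the library stands in for). Generation is
  deterministic per seed. What this emulates: the size, heteroatom and
  topology envelope of a fragrance-like database subset. What it does not:
  the synthetic-accessibility and commercial-availability structure of
  real catalogues, or real databases' duplicate/stereochemistry artefacts
  — so passing tests demonstrate algorithmic correctness and
  qualitative behaviour, not literal reproduction of any published
  database statistic.
* **Analog families** (`generate_analog_family`): 1–2 random edit moves
  per analog from a seed molecule (methyl addition/deletion/transposition,
  ring expansion, carbonyl↔alcohol swaps), kept only if FL, unique and
  connected; the maximum MQN-CBD to the seed is reported. Families built
  this way are much tighter in MQN space than random decoy samples — the
  planted signal the screening tests recover.

## Problem sizes and determinism

The shipped test suite and acceptance script use a 10,000-molecule decoy
library, 100 queries × 3 distance boundaries × 8 constraint combinations
for index/oracle equivalence, 10,000 random triples for the triangle
inequality, 50 randomized instances for the AUC oracle, ten 15-member
analog families diluted 1:10,000 for planted-signal recovery, and a
1,000-molecule map for pixel-level checks — sizes at which every check
runs in seconds to a couple of minutes on one CPU while exercising the
same code paths as million-molecule runs. All randomness flows from
explicit seeds; `scripts/acceptance.py` derives every sub-seed from its
`--seed` argument.

## Known limitations

* H-bond *site* counts and the rotatable-bond rule are documented
  conventions, not canonical definitions; absolute MQN values may differ
  from other implementations in those five components (`rbc`, `hba`,
  `hbd`, `hbam`, `hbdm`) and in ring counts on symmetric cages (see ring
  basis above).
* The ionization table is rule-based; molecules with unusual pKa shifts
  (vinylogous acids, strained amines) are handled by the nearest rule.
* The index targets desk-scale libraries (10⁴–10⁷ entries in memory);
  there is no sharding or approximate mode.
* Generated decoys/analogs support correctness and qualitative-behaviour
  claims only; no odour activity is implied for any generated structure.
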