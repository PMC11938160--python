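# Methods

## Glycan representation and classification

An N-glycan is a rooted tree of monosaccharide nodes over the closed
alphabet N (HexNAc), H (Hex), F (fucose/dHex), S (Neu5Ac), G (Neu5Gc).
Serialization uses a nested-parenthesis grammar, `node := SYMBOL
('(' node ')')*`, with siblings ordered lexicographically by their own
serialization; this canonical form is unique per topology and is the glycan
identifier throughout the package. Parsing accepts non-canonical sibling
orders and canonicalises. Linkage positions and anomericity are *not*
represented: two branches differing only in linkage (e.g. Lewis x vs
Lewis a) collapse to one topology, which is also why a single `NHF` branch
class covers both Lewis isomers.

Classification first locates the invariant N-glycan core by walking
reducing-end GlcNAc → second GlcNAc → central (β) mannose → up to two arm
mannoses; a structure in which this walk is ambiguous raises a
classification error rather than guessing. Modules are then read off the
anatomy:

* **Core** (4 classes): fucoses on the reducing-end GlcNAc ⇒
  core-fucosylated; a GlcNAc on the central mannose ⇒ bisected; both ⇒
  bisected-core-fucosylated; else typical. Exhaustive and exclusive by
  construction.
* **Antennae**: the HexNAc-initiated children of the arm mannoses. The
  bisecting GlcNAc sits on the central mannose and is therefore never
  counted. Oligo-mannose glycans have zero antennae by convention (branch
  counting applies to antennary glycans only).
* **Subtype** (3 classes): oligo-mannose iff the arms carry only Hex and
  the composition has no F/S/G (the Man3–Man9 series; Man3/Man4
  paucimannose structures fall in this class, a documented convention);
  hybrid iff at least one Hex-extended arm coexists with at least one
  antenna; complex otherwise (all arm extensions are antennae). The
  degenerate case of mannosidic arms plus decorations but no antenna is
  classed hybrid; the library generator never emits it.
* **Branches**: each antenna subtree is matched *exactly* (canonical-string
  equality) against the branch taxonomy templates. Because templates are
  complete antenna topologies and duplicates are rejected at load time, at
  most one template can match and the longest-match/lexicographic
  tie-break rule is vacuously deterministic. Unmatched antennae are
  reported as `unclassified-branch` with a warning — never dropped.

### Branch taxonomy

The default table ships 17 branch classes as a replaceable TSV
(`code`, `template`, `sialyl_category`, `sialic_type`): sole HexNAc `N`;
LacNAc `NH`; alpha-Gal `NHH`; a polyLacNAc repeat `NHNH`; Lewis `NHF`;
terminal-sialylated LacNAc `NHS`/`NHG`; sialyl-Lewis `NHFS`/`NHFG`;
antenna-sialylated LacNAc `N(S)H`/`N(G)H`; bi-sialylated LacNAc
`N(S)HS`/`N(G)HG`; and the LacdiNAc series `N2`, `N2S`, `N2G`, `N2F`
(GalNAcβ-GlcNAc backbone, bare / sialylated / fucosylated). The eight
non-LacdiNAc sialylated entries form the 4-category × 2-sialic-acid grid
(sialyl-Lewis, terminal-, antenna-, bi-sialyl LacNAc, each with Neu5Ac or
Neu5Gc) used for sialylated-branch landscape tables. A branch carrying
mixed Neu5Ac *and* Neu5Gc on one antenna matches no default template and
surfaces as `unclassified-branch`, which is the intended conservative
behaviour.

Records carrying only a composition (structure `unknown`) get a reduced,
explicitly lower-confidence annotation: oligo-mannose is decidable from
composition alone (N2, H3–H9, no decorations); everything else is labelled
complex with fucose position unknown. These annotations are flagged
`composition-only` so downstream tables can exclude them.

## Identification-level handling

Coordinates are 1-based residue indices everywhere (glycosite = the Asn,
phosphosite = the S/T/Y). The sequon scanner reports every N-X-S/T window
with X ≠ P, labelling N-X-T vs N-X-S; ambiguity codes never satisfy the
Asn or S/T slots, and the middle slot excludes only literal proline.

The identification filters reproduce a two-tier confidence scheme:
*peptide-level* records pass peptide FDR ≤ 0.01, ≥ 5 b/y ions and ≥ 2
oxonium ions among the top-10 fragment ions; the nested *glycan-level*
subset additionally passes glycan FDR ≤ 0.01. FDRs are consumed from the
search output, never computed; absent FDR columns default to 0 with a loud
warning so toy fixtures run. Counts are reported at PSM, unique-IGP,
glycosite and glycoprotein granularity. A unique IGP is the triple
(protein, glycosite, glycan), the glycan being the canonical structure
string with composition fallback; peptides seen with several site/glycan
combinations yield one record per pair (macro-heterogeneity is
represented, not collapsed).

## Quantification

* **Within-set normalization** multiplies each channel by
  (mean column sum)/(column sum), equalising channel sums to 1e-9 relative
  tolerance — the loading-correction fixed point leaves already-balanced
  matrices unchanged.
* **Cross-omic scaling**: the *proteome's* within-set factors are applied
  verbatim to the glyco and phospho matrices. This is the single coupling
  point between omes: a loading artefact estimated on the unenriched
  proteome is removed from the enriched sub-proteomes, whose own column
  sums are confounded by enrichment efficiency.
* **Aggregation**: PSMs collapse to unique IGPs by per-channel median;
  the PSM count is kept as row metadata.
* **Differential test**: FC = median(aged)/median(young) on normalised
  intensities; p from a two-tailed unpaired t-test on log2 intensities
  (Student by default, Welch and linear-scale switches available — the
  log2 default reflects the multiplicative noise of reporter ions).
  Calls: up iff FC > 1.5 ∧ p < 0.05; down iff FC < 0.67 ∧ p < 0.05. No
  multiple-testing correction by default (raw p, matching the cutoff
  convention); Benjamini–Hochberg gating is available behind `bh=True`.
* **Degenerate inputs**: fold changes come from the *raw* group medians —
  a zero young-group median makes the ratio undefined and the record is
  flagged and excluded from calls. For the log-scale test only, zero
  intensities are imputed as half the row's minimum positive value (a
  matrix-wide floor only for all-zero rows). A feature-wise floor is used
  deliberately: with base abundances spanning orders of magnitude, a
  matrix-wide floor sits far below a bright feature's own scale and
  inflates its log-scale variance enough to mask real effects. Constant
  rows produce NaN t statistics; their p is defined as 1 (null).

Group-swap antisymmetry (FC → 1/FC, p unchanged) and scale invariance
after normalization hold by construction and are property-tested.

## Attribution

For each differential IGP, the carrier protein is looked up in the global
proteome results: if |log2 FC_protein| ≥ log2 1.5 *and* p_protein < 0.05
the IGP is attributed to the protein-expression level, otherwise to the
glycosylation level; proteins absent from the proteome leave the IGP
unattributed (always reported as a third bucket). The p-requirement on the
protein is switchable (`require_protein_p=False` reduces the gate to the
fold-change criterion alone, for symmetry with analyses that gate proteins
on FC only). The normalized glycosylation ratio FC_IGP/FC_protein
satisfies the exact identity normalized × protein = IGP (tolerance
1e-12). Raising the gate is monotone: records can only move from
protein-level to glycosylation-level. Glycoprotein-level percentages count
a protein as protein-level if *any* of its differential IGPs is. The same
machinery applies to phosphopeptide-vs-protein comparisons unchanged.

## Landscape statistics

Two denominators are used deliberately and carried in the outputs:
proportion tables count **unique IGPs** per group (a group being "all" or
one annotation category, membership many-to-many with GO semantics);
changed-fraction tables count **modified glycosites** (protein, site)
per feature value, with an up/down split. For partitioning axes (subtype,
core, fucosylation, sialylation, antenna count) proportions sum to 1 per
group (tolerance 1e-9); the branch axis is multiset-valued and exempt.
Rankings order glycans by the number of distinct glycosites carrying them,
ties broken on the canonical glycan string, so they are
permutation-invariant; oligo-mannose rows are removable by flag and the
same ranking applies to the changed subset. "Solely core-/solely
antenna-fucosylated" and "solely Neu5Ac-/Neu5Gc-modified" glycoprotein
classes aggregate all of a protein's glycan annotations before labelling.

## Synthetic studies

The generator emulates the full study design end to end: 10-plex TMT
with five young and five aged pooled channels (126–128C young,
129N–131 aged); glycoproteins carrying geometric numbers of sites (capped
at 33) and glycoforms per site (capped at 8); glycans drawn from a library
spanning all subtypes, cores, the full 17-code branch taxonomy, antenna
counts 1–6, Man5–Man9 and the prevalent sialylated bi-antennary
compositions; log-normal base abundances (log2 mean 20, sd 2 — arbitrary
instrument units); per-channel loading factors (log2 sd 0.25) shared by
all three sub-proteomes so global scaling can remove them; reporter noise
sigma = log2(1 + CV) with CV = 10 % (pooling three animals per channel is
modelled only as this reduced CV — the pipeline never sees animals);
2 % missing-at-random dropout; and 6 % of PSMs planted to fail exactly one
identification filter. FASTA sequences are filler residues (no N/P/S/T)
with a valid sequon written at every declared glycosite, so the emitted
sites are exactly the scanner's hits.

Effects are class-level, mirroring class-level findings rather than
per-gene biology: by default 10 % of glycoproteins gain a 2-fold
protein-expression effect (propagated to their IGPs and phosphopeptides),
sialylated IGPs gain 2-fold, LacdiNAc IGPs lose to 0.5-fold, and
core-fucosylated IGPs split into 1.8-fold up and 0.55-fold down halves.
Each IGP receives at most one effect (first matching spec wins; IGPs of
protein-effect proteins are excluded from glycosylation-level effects), so
every IGP has a single well-defined true source: null, protein-level or
glycosylation-level. All randomness flows from one seed; outputs are
byte-identical per seed (fixed row order, `%.6g` float formatting).

What the generator does **not** emulate: spectra and search-engine
behaviour (FDR estimation, misidentification, chimeric spectra), isotope
impurity between TMT channels, batch effects beyond one loading vector,
peptide-level missingness structure (dropout is uniform, not
intensity-dependent), correlated glycoforms at one site, and real
annotation biology (categories are assigned at random). Passing recovery
tests therefore demonstrates the correctness of the analysis logic under
the stated noise model, not performance on real instrument data.

## Problem sizes and verification

The default simulation uses 200 proteins (~140 glycoproteins, ~430 unique
IGPs, ~950 PSMs) — enough for stable two-digit recovery metrics while a
full pipeline run stays around two seconds. Calibration checks use 5,000
simulated null features (the p < 0.05 fraction is binomially bounded
within 0.05 ± 0.01) and 3,000 features for the 4-fold power anchor
(≥ 99 % called). On the default study the differential stage recovers
planted changes with sensitivity ≈ 0.96 and precision ≈ 1.0, and
attribution labels ≈ 100 % of truly-changed, quantified IGPs correctly;
recovery is measured over IGPs that survive the identification filters,
since IGPs whose every PSM was planted to fail identification never reach
quantification and measure the (out-of-scope) search step instead. All of
these numbers are recomputed, never stored, by `scripts/acceptance.py` and
the test suite.

## Known limitations

* Topology-only structures: no linkage/anomericity, no Lewis x/a or
  2,3-/2,6-sialyl discrimination; glycan mass is never computed.
* O-glycans and site-occupancy stoichiometry are out of scope.
* The branch taxonomy is finite and exact-match; genuinely novel antennae
  surface as `unclassified-branch` rather than nearest-neighbour guesses.
* The differential model assumes independent features; no shrinkage or
  covariate modelling (no isotope-impurity correction, no batch terms).
* Composition-only records receive heuristic subtype labels and should be
  excluded from structure-sensitive conclusions.
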