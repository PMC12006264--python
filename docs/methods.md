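# Methods

This note documents the models, conventions, defaults and numerical
choices behind orthostruct, and what the synthetic benchmark does and
does not establish about real data.

## Coordinate conventions

Residue numbering and alignment columns are 1-based; region intervals
are 1-based inclusive. All distances are Ångström, angles degrees.
Column→residue maps use 0 as the gap sentinel. Cross-species identity
of any per-residue object (substitution, deviation, bond partner,
contact partner) is its alignment column, so masks and regions are
always computed per species and projected through the species' own
residue↔column map rather than assuming shared numbering.

## Pairwise divergence and the gap rule

For a pair of aligned rows, a column with residues on both sides that
differ is a substitution; a column gapped on exactly one side is an
indel column and counts as a difference; a column gapped on both sides
is excluded. The percentage denominator is the union length (columns
with at least one residue among the pair). This rule is the only one
consistent with pairwise counts that exceed the shorter sequence's
length when the partner carries insertions. Because published
percentages rarely state their denominator, both the denominator
(`union` vs `reference`, i.e. the first row's ungapped length) and
whether indel columns count (`count_indels`) are configurable, and
rounded-to-integer percentages are reported alongside raw values so
comparisons against printed figures are explicit about precision.

## Ancestral substitutions and Miyata scoring

Lineage-specific changes are the column-wise differences between an
ancestral-node row and a descendant row; indel columns become separate
insertion/deletion events and are never biochemically scored (there is
no defined distance for a gap). The Miyata distance between residues
combines side-chain polarity and volume:

    d(a,b) = sqrt((|p_a − p_b|/σ_p)² + (|v_a − v_b|/σ_v)²)

with σ_p, σ_v the population standard deviations (ddof = 0) of the
property across the 20 residues. The embedded property columns are
Grantham's polarity and side-chain volume scales, the physicochemical
columns this distance construction is built on; the 20×20 grid is
recomputed from them at import, and the test suite independently
recomputes it again from the same columns. Raw distances exceed 4 for
extreme pairs (max ≈ 4.22, Gly↔Trp), while reported classes run 0–4;
the class rule is round-half-up capped at 4
(`class = min(4, floor(d + 0.5))`, cap configurable). Unknown residues
('X') yield NaN, never a silent 0, and such records carry class "None".

Counts are stratified by category — total, each functional region
(a record inside two overlapping regions counts once per region), and
ordered/disordered by the lineage's own mask — and compared between
lineages with two-sided Fisher exact tests (probability-mass
convention; the implementation is scipy's, the test oracle an
exhaustive hypergeometric enumeration). The 2×2 table is in-category vs
out-of-category counts against each group's total. Bonferroni family
size m is the number of tests actually performed and is recorded in the
output; degenerate tables (zero margins) are reported untested with a
reason rather than dropped. The ordered/disordered ratio is reported
with an explicit NA when the disordered count is zero.

## Order, disorder and confidence

Two tracks feed the per-residue mask: plDDT (0–100, from the model's
B-factor column per the AlphaFold output convention, lifted from the CA
atom) and a disorder predictor's Z-score of structural order. Defaults:
confident iff plDDT ≥ 70 (standard predictor practice — low-plDDT
regions carry no reliable positional information and in practice mark
intrinsic disorder), ordered iff Z ≥ 3.0. Both cuts are ≥-closed and
configurable. The consensus policy (`adopt_first`, default) lets the
dedicated disorder predictor decide wherever a Z-track exists and falls
back to the plDDT confidence otherwise; `plddt_only` ignores the
Z-track. The mask is a pure function of tracks and thresholds.

## Superposition and the 2 Å classification

Residue pairs come from the study MSA (mutually ungapped columns with
CA on both sides), not from a structure aligner's own pairing, so every
deviation is attributable to a column. The rigid fit is weighted
least-squares via SVD with the determinant-corrected rotation (proper
rotation guaranteed); configurations with covariance rank < 2
(collinear) are rejected. Matchmaker-style refinement iterates
fit → drop pairs deviating more than the 2.0 Å prune cutoff → refit,
stopping when the retained set stabilises, at 100 iterations, or when
pruning would leave fewer than 3 pairs. Deviations are reported for
*all* pairs under the final transform.

The deviation metric is the per-pair CA–CA distance (a per-residue
scalar is required for per-residue classification and colouring);
global RMSD over retained pairs is reported alongside. Classification:
matched below 2.0 Å, different at or above it (the published rule is
silent at exactly 2 Å; this implementation closes the boundary on the
"different" side), and unscored whenever either residue's confidence
state is low — structural calls are only made where both models are
confident. A difference is species-specific when its column is
"different" in every pairing involving the focal species and "matched"
in every pairing among the others; a column unscored anywhere, or
different in two species' pairings, does not qualify.

One caveat worth knowing: a planted displacement contaminates the
unpruned first fit by (k/n)·magnitude (k displaced of n pairs), so
displacements barely above the 2 Å cut are only resolved when the
displaced fraction is small. The fixtures use k/n ≤ 0.025, matching the
regime of a short span in a full-length protein.

## Hydrogen bonds and contacts

Bonds are called from heavy atoms only. The base criterion —
donor–acceptor distance ≤ 3.3 Å, angle at the donor
(antecedent–donor–acceptor) ≥ 90° — reflects typical N/O···O/N
separations (2.9 ± 0.4 Å) in small-molecule crystal-structure surveys;
the relaxations (+0.4 Å, −20°) are then applied on top, giving an
effective 3.7 Å / 70° rule. A single documented monotone criterion was
chosen deliberately: it is exhaustively checkable against a brute-force
donor×acceptor scan, and relaxing either tolerance can only grow the
bond set. Full per-chemistry bond tables are out of scope; sulfur
donors/acceptors are omitted as weak. The donor/acceptor table is the
standard heavy-atom naming (backbone N donates except proline, backbone
O accepts, side chains of R/N/Q/H/K/S/T/W/Y donate, N/D/Q/E/H/S/T/Y
accept). Intra-chain bonds are kept only when the partners' sequence
numbers differ by more than 5; inter-chain bonds are all kept.

Contacts between two chains use the minimum heavy-atom distance
(≤ 4.0 Å default, configurable — a conventional heavy-atom contact
cutoff) gated by predicted aligned error strictly below 5 Å. PAE is not
symmetric; the conservative max of the two directions is used
(configurable). Catalogs are compared across species by the same
category machinery as substitutions; a bond is assigned to a region
when any focal-chain partner's column lies in it, and to
ordered/disordered when all focal-chain partners share the state. The
"total" category is tested as a rate against each species' residue
count.

## The synthetic generator

The generator emulates the study system's *shape*: one ancestral root
(a star phylogeny — lineage analysis only needs ancestor/descendant
pairs, and the root doubles as the node-A analog), four descendant
species, 400 residues, fast-evolving disordered termini (per-site rate
0.15 on spans 1–60 and 341–400) over a slower ordered core (0.05),
Poisson indels (mean 1 deletion and 0.5 insertions per lineage, spans
≤ 3), one species-specific 5-residue 4 Å displacement in the confident
core, and a two-chain complex whose four planted contacts (two of them
serine–serine hydrogen-bond sites) are the only PAE-confident
cross-chain pairs. Deletions are drawn before substitutions so the
truth ledger lists exactly the events an ancestor-vs-descendant column
walk can recover; positions belonging to planted spans and interface
sites are immune to mutation so the planted signals stay alignable.

Backbones are schematic: an ideal α-helix CA trace (1.5 Å rise, 100°
turn, 2.3 Å radius → 3.8 Å CA–CA) or a smoothed random-walk coil, with
N/C/O (and serine CB/OG) placed from local chain geometry. Models are
assembled in a canonical frame and then rigidly transformed as a whole,
so internal geometry — and hence every bond and contact — is identical
across species up to the planted differences and coordinate noise
(σ = 0.05 Å). Displacements are rigid span translations, so the planted
per-residue deviation equals the plan magnitude exactly, making the
2 Å classifier analytically checkable. plDDT/Z tracks are two-level
(90/40 and 8/−2) with boundaries exactly at the disorder spans; PAE is
block-structured (2 Å within ordered blocks and planted interface
pairs, 25 Å elsewhere).

What passing recovery tests therefore shows: the bookkeeping (column
maps, truth-aligned inference, classification, gating) is exact under
known ground truth, at realistic divergence levels. What it does not
show: behaviour on real predictor output — continuous plDDT/PAE ramps,
torsion-space conformational change, genuinely ambiguous alignments, or
disorder that moves between species. Those require the real models,
which are consumed through the same interfaces.

## Problem sizes and determinism

Test and acceptance runs use lengths 120–400 with 2–4 species, sizes at
which every stage (including the O(N²) brute-force oracles) completes
in seconds while keeping ≥ 20 planted events per lineage. Each bundle
is generated from a single seeded NumPy generator; identical seeds give
byte-identical files. The statistical sweep checks the Fisher
implementation against exhaustive enumeration for every 2×2 table with
N ≤ 30.

## Known limitations

* Insertions relative to the ancestor get placeholder coordinates next
  to their predecessor; they never enter superposition pairings (no
  ancestor column) but are physically arbitrary.
* The ordered/disordered assignment of a bond requires all focal-chain
  partners to share a state; mixed bonds are counted in the total only.
* `category_tests` treats counts as independent across categories;
  overlapping regions make the Bonferroni correction conservative.
* The hydrogen-bond criterion is deliberately simpler than per-donor
  chemistry tables; absolute bond counts are therefore not comparable
  to other tools, only differences across species analysed with the
  same criterion are meaningful.
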