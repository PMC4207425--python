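# Methods

## Model

The predictor treats epitope identification as a rigid geometric matching
problem between two residue sets: the antibody binding site *Ab* (supplied
as input — typically Chothia CDR residues; no numbering scheme is computed)
and candidate surface patches *Epi* on the antigen. A candidate contact is
any pair (r_ab, r_ag) ∈ Ab × Epi. Two candidate contacts can be realized
simultaneously by one rigid orientation only if the distance between the
two antibody residues roughly equals the distance between the two antigen
residues; the tolerance is the compatibility cutoff (1 Å default). The
patch score

    Score(Epi) = Σ_n d(n) · PS(T_ab(n), T_ag(n))

sums over candidate contacts n, weighting each by its degree d(n) in the
compatibility graph — the number of *other* contacts it can satisfy
simultaneously, so isolated contacts contribute zero — and by the
Precision Score of its amino-acid pair. The d(n) (rather than d(n)+1)
weighting is deliberate: a contact that is compatible with nothing else
carries no evidence of a consistent rigid match.

Two nodes that share an antibody or an antigen residue are never connected:
one residue cannot occupy two simultaneous contacts in a rigid match. This
is a modelling choice of this package (`allow_shared=True` disables it).

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| contact_cutoff | 4.5 Å | heavy-atom minimum distance defining an inter-molecular contact (strict <) |
| compat_cutoff | 1.0 Å | intramolecular distance-difference tolerance for graph edges (strict <) |
| surface_threshold | 0.07 | relative accessibility above which a residue is surface (strict >) |
| overlap_threshold | 0.30 | shared-residue fraction (w.r.t. the higher-scoring patch) above which a patch is discarded (strict >) |
| max_epitopes | 3 | non-overlapping epitopes reported |
| interface_cutoff | 10 Å | neighbourhood defining native interface regions |
| near_native_cutoff | 10 Å | I_rmsd below which a decoy is close-to-native (strict <) |
| rescore_top_n | 30 | decoys rescored (use 20 for ClusPro-style lists) |

All inequalities are strict, consistently: a residue at exactly 4.5 Å is
not a contact, accessibility exactly 7% is not surface, overlap of exactly
30% is retained, I_rmsd of exactly 10 Å is not close-to-native.

## Accessibility

Relative accessibility = Shrake–Rupley SASA of the residue in the isolated
antigen ÷ a per-type theoretical maximum reference area (Tien et al.-style
values; the reference table is a function argument). The point lattice is a
deterministic 960-point golden spiral, probe radius 1.4 Å, hydrogens
ignored, so results are bit-for-bit reproducible. Fractions can exceed 1
for extended termini. Residue types without a reference value fall back to
the mean of the 20 canonical areas with a warning. The accessibility
backend is a plain function and can be swapped by passing a precomputed
surface set to `predict_epitopes`.

## Patch enumeration

One patch per surface residue: the seed, then every surface residue within
the contact cutoff of the seed, then every surface residue within the
cutoff of any current member — exactly two expansion rounds (a `rounds`
knob exists). Proximity uses the same heavy-atom minimum distance as the
contact definition. Patches from different seeds may coincide; duplicates
are resolved by the overlap filter at ranking time, not at enumeration.
No patch-size cap or normalization is applied.

## Ranking and ties

Patches are sorted by score; equal scores are broken lexicographically on
the seed residue ID (chain, number, insertion code), making the prediction
invariant to residue input order. Greedy selection walks down the sorted
list discarding patches that share strictly more than the overlap threshold
of any already-selected patch's residues, measured relative to the
higher-scoring patch.

## Precision Score estimation

For every decoy among the first `top_m` (default 200) of each training
case, every (site residue, antigen residue) contact pair is tallied under
its (T_ab, T_ag) type cell; the pair counts as correct iff the identical
residue pair (by ID) is a contact of that case's native complex — the
strictest consistent reading of "matched correctly". Tallies are pooled
across cases. PS = (correct + ε)/(total + 2ε) with ε = 1 by default, so a
never-observed cell is an uninformative 0.5; ε = 0 is supported with
0/0 → 0. Estimation is invariant to decoy order beyond the top_m
truncation. Matrices estimated by this package come from its synthetic
generator and are labelled as such; they are not derived from real docking
runs on crystal structures.

## Decoy rescoring

score(d, Ab, Epi) = Σ PS(T_ab, T_ag) over pairs with heavy-atom distance
< 4.5 Å in the decoy, with r_ag restricted to the predicted epitope. Each
pose is scored against each predicted epitope and keeps the maximum; the
top-N list is reordered by that score with ties broken by the source rank,
preserving the docking algorithm's prior when the score is uninformative.
Decoys must be materialized as coordinates (multi-model PDB or a directory
of PDB files); docking-programme transform-table dialects are not parsed —
convert with the docking tool's own `create.pl`-style utility first.

## Interface RMSD

Interface regions are defined on the native complex: residues whose
heavy-atom minimum distance to any residue of the partner is below 10 Å.
The pooled interface atoms of decoy and native are superimposed by
least-squares rotation (SVD/Kabsch via `scipy.spatial.transform.Rotation`)
and the RMSD is computed explicitly on the rotated coordinates (not from
the residual shortcut, which loses precision near zero). The atom set
defaults to backbone (N, Cα, C, O) per common CAPRI practice and is
configurable (`calpha`, `all-heavy`); atoms absent from a residue are
skipped so Cα-only models degrade gracefully.

## Randomized-score control

The control re-runs the ranking with each candidate patch's score replaced
by an independent uniform(0, 1) draw, keeping the overlap filtering, and
evaluates the top patch only; means are over runs (500 by default). With
a seeded generator the control is bit-for-bit reproducible.

## Synthetic data

The generator places antigen residues on a spherical shell (golden-spiral
lattice) so every residue is surface-exposed; each residue is a Cα plus
1–3 pseudo side-chain carbon atoms pointing radially outward. The planted
epitope is a contiguous surface cap; antibody atoms are placed at a
controlled gap (3.5 Å default) above the epitope residues' outermost atoms,
and the construction is verified: generation fails rather than return a
fixture whose extracted native epitope differs from the planted one. Near
decoys are small rigid perturbations of the antibody (verified
I_rmsd < 10 Å); far decoys are proper rotations of the antibody to the far
side of the antigen plus a translation margin large enough that no
superposition brings them under the cutoff (verified), a margin needed
because a near-spherical shell is almost symmetric under half-turns.
Training decoys reproduce each native contact with a planted probability;
a broken contact is relocated onto a non-epitope residue of the same
amino-acid type, so it still tallies in the same matrix cell as an
incorrect observation and the estimated cell value converges to the
planted rate.

What the toys do not emulate: real surface ruggedness, buried residues,
side-chain packing and rotamers, sequence composition statistics, backbone
connectivity, conformational change, or docking-programme pose
distributions. Passing tests therefore demonstrate the correctness of the
geometry, bookkeeping and statistics of the pipeline — not predictive
performance on real antibody–antigen complexes, which requires training
and evaluating on curated structure sets with real docking decoys.

## Problem sizes

The test-suite and acceptance-script fixtures use antigens of 20–60
residues, binding sites of 3–8 residues, epitopes of 3–6 residues, decoy
sets of 10–30 poses (25–50 targets for the enrichment experiments), 500
decoys per training case for rate recovery, 500-run randomized controls
and a 5000-draw uniformity check. These sizes give stable statistics
(binomial standard errors of a few percent) while keeping any single run
in seconds.

## Known limitations

- The patch score is unnormalized; larger patches tend to score
  higher, which matches the region-level intent but makes scores
  comparable only within one antigen.
- The accessibility reference areas and the Cα choice for intramolecular
  distances are conventions; both are configurable, and switching to Cβ or
  another reference table changes absolute scores but rarely the ranking
  on the toys.
- PDB input only (no mmCIF); no hydrogen placement or structure repair.
- Rescoring assumes residue identity is constant across decoys of a
  target and errors out otherwise.
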